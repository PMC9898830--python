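state,potential_reach,budget_low,budget_high,reach_ll,reach_hl,reach_lh,reach_hh,clicks_ll,clicks_hl,clicks_lh,clicks_hh
Alabama,46000,200,1150,1600,4700,4600,13200,50,146,114,330
Alaska,8300,30,170,287,830,831,2400,5,19,16,46
Arizona,78000,450,2180,2700,7800,7800,22500,67,194,158,456
Arkansas,29000,120,660,998,2900,2900,8300,21,61,52,152
California,430000,3440,12430,14900,43000,43000,124200,288,832,718,2100
Colorado,59000,290,1790,2000,5900,5900,16900,56,162,140,405
Connecticut,35000,170,910,1200,3500,3500,10000,26,77,65,188
Delaware,9400,60,240,345,997,940,2700,8,22,17,48
Florida,210000,1520,6460,7300,21000,21000,60600,187,539,435,1300
Georgia,120000,810,3730,4100,12000,12000,34600,98,284,244,704
Hawaii,14000,60,350,476,1400,1400,3900,9,25,25,71
Idaho,19000,100,570,688,2000,1900,5400,20,59,44,127
Illinois,120000,560,3390,4100,12000,1200,34500,120,347,285,823
Indiana,64000,320,1900,2200,6500,6400,18400,64,185,149,431
Iowa,26000,140,800,914,2600,2600,7400,30,88,66,190
Kansas,26000,120,670,926,2700,2600,7400,25,72,57,165
Kentucky,41000,190,1100,1400,4100,4100,11800,50,145,115,331
Louisiana,45000,200,1110,1600,4500,4500,12900,38,110,86,249
Maine,12000,40,260,452,1300,1200,3400,12,35,27,78
Maryland,61000,340,1760,2100,6100,6100,17600,47,136,120,347
Massachusetts,64000,360,1990,2200,6400,6400,18400,57,165,141,406
Michigan,86000,420,2640,3000,8600,8600,24700,86,250,207,599
Minnesota,44000,190,1330,1600,4500,4400,12600,36,104,97,280
Mississippi,31000,130,730,1100,3100,3100,8800,30,88,71,205
Missouri,54000,240,1520,1900,5400,5400,1550,49,142,124,357
Montana,9900,50,300,349,1000,1000,2900,10,28,22,64
Nebraska,18000,80,500,616,1800,1800,5100,19,54,44,127
Nevada,37000,200,1080,1300,3700,3700,10600,32,92,77,222
New Hampshire,11000,60,260,409,1200,1100,3000,12,37,25,73
New Jersey,88000,670,2650,3000,8800,8800,25300,69,198,166,481
New Mexico,26000,120,670,884,2600,2600,7400,25,73,58,167
New York,200000,1370,6300,6900,20000,20000,57700,188,545,435,1300
North Carolina,110000,600,3050,3800,11000,11000,31700,98,283,224,648
North Dakota,6400,30,150,256,740,661,1900,6,19,13,38
Ohio,110000,520,3310,3800,11000,11000,31700,113,327,266,770
Oklahoma,40000,190,1060,1400,4000,4000,11400,41,117,95,274
Oregon,37000,230,1160,1300,3700,3700,10600,35,101,85,246
Pennsylvania,110000,650,3330,3800,11000,11000,31700,93,268,232,670
Rhode Island,11000,60,380,375,1100,1100,3100,11,31,28,82
South Carolina,49000,250,1450,1700,4900,4900,14100,43,124,108,311
South Dakota,6700,30,170,318,918,684,2000,7,22,15,44
Tennessee,67000,310,1790,2300,6800,6700,19200,61,176,148,428
Texas,360000,2240,10610,12400,36000,36000,104000,316,913,751,2200
Utah,40000,260,1290,1400,4000,4000,11500,33,97,84,242
Vermont,5700,30,140,251,726,591,1700,6,20,13,38
Virginia,85000,530,2570,2900,8500,8500,24400,76,221,179,518
Washington,68000,470,2040,2400,6800,6800,19600,51,146,128,369
West Virginia,14000,50,300,495,1400,1400,3900,15,44,37,106
Wisconsin,48000,220,1370,1700,4800,4800,13700,51,147,120,346
Wyoming,5500,30,190,195,564,567,1600,6,18,15,44
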