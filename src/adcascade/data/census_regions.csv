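state,region
Connecticut,Northeast
Maine,Northeast
Massachusetts,Northeast
New Hampshire,Northeast
Rhode Island,Northeast
Vermont,Northeast
New Jersey,Northeast
New York,Northeast
Pennsylvania,Northeast
Illinois,Midwest
Indiana,Midwest
Michigan,Midwest
Ohio,Midwest
Wisconsin,Midwest
Iowa,Midwest
Kansas,Midwest
Minnesota,Midwest
Missouri,Midwest
Nebraska,Midwest
North Dakota,Midwest
South Dakota,Midwest
Delaware,South
Florida,South
Georgia,South
Maryland,South
North Carolina,South
South Carolina,South
Virginia,South
West Virginia,South
Alabama,South
Kentucky,South
Mississippi,South
Tennessee,South
Arkansas,South
Louisiana,South
Oklahoma,South
Texas,South
Arizona,West
Colorado,West
Idaho,West
Montana,West
Nevada,West
New Mexico,West
Utah,West
Wyoming,West
Alaska,West
California,West
Hawaii,West
Oregon,West
Washington,West
Puerto Rico,US dependent areas
US Virgin Islands,US dependent areas
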