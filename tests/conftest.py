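import pytest

import adcascade as ac


@pytest.fixture(scope="session")
def study():
    """Packaged study inputs: (state_rows, national_row, positivity, region_map)."""
    return ac.load_packaged_study()


@pytest.fixture(scope="session")
def constants():
    return ac.StudyConstants()


@pytest.fixture(scope="session")
def state_results(study, constants):
    rows, _, positivity, region_map = study
    results, summary = ac.evaluate_table(
        rows, positivity, region_map, constants, band_width=50.0
    )
    return {r.stratum_id: r for r in results}, summary
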