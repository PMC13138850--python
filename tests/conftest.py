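import pytest

from rgcadapt.synthetic_data import (
    default_population_spec,
    desk_geometry,
    generate_natural_surrogate,
    generate_white_noise,
    make_ground_truth_population,
    simulate_rgc,
)
from rgcadapt.training import FitConfig, compute_sta, fit_ln


@pytest.fixture(scope="session")
def geometry():
    return desk_geometry()


@pytest.fixture(scope="session")
def small_wn(geometry):
    """3 trials x (8 s + 2 s) of binary white noise at desk scale."""
    return generate_white_noise(
        geometry, n_trials=3, train_seconds=8, test_seconds=2, contrast=0.3, seed=101
    )


@pytest.fixture(scope="session")
def small_nm(geometry):
    return generate_natural_surrogate(
        geometry, n_trials=3, train_seconds=8, test_seconds=2, contrast=0.3, seed=102
    )


@pytest.fixture(scope="session")
def cell(geometry):
    """One midget-like ground-truth cell with ensemble-specific filters."""
    return make_ground_truth_population(
        default_population_spec(n_per_type=1), adapt=True, seed=7, geometry=geometry
    )[0]


@pytest.fixture(scope="session")
def resp_wn(cell, small_wn):
    return simulate_rgc(cell, small_wn, seed=201)


@pytest.fixture(scope="session")
def resp_nm(cell, small_nm):
    return simulate_rgc(cell, small_nm, seed=202)


@pytest.fixture(scope="session")
def sta_wn(small_wn, resp_wn):
    return compute_sta(small_wn, resp_wn)


@pytest.fixture(scope="session")
def short_dog_fit(small_wn, resp_wn, sta_wn):
    """A deliberately short DoG fit shared by bookkeeping/contract tests."""
    return fit_ln(
        "dog",
        small_wn,
        resp_wn,
        FitConfig(max_epochs=40, seed=301),
        sta_wn.crop_center,
        sta_wn.polarity,
        sta=sta_wn,
    )
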