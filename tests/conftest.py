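import numpy as np
import pytest

import wolfreports as wr


@pytest.fixture(scope="session")
def land():
    """A small landscape shared across tests (50 x 40 km at 1-km cells)."""
    return wr.generate_landscape(
        wr.LandscapeConfig(width_m=50_000, height_m=40_000, seed=11)
    )


@pytest.fixture(scope="session")
def truth():
    return wr.default_truth()


@pytest.fixture(scope="session")
def reports(land, truth):
    """914 synthetic reports with reporters and valence labels."""
    reps = wr.simulate_reports(land, truth, 914, seed=21)
    reps = wr.assign_reporters(reps, truth.singleton_frac, seed=22)
    return wr.simulate_valence(reps, land, truth, seed=23)


@pytest.fixture(scope="session")
def design(reports, land):
    return wr.build_design(reports, land, ratio=11, seed=31)


@pytest.fixture(scope="session")
def valence_data(reports, land, design):
    """Valenced reports with standardized footprint and zone covariates."""
    val = reports[reports.valence != "neutral"].copy()
    H, S, _, _ = land.covariates_at(val["x"].to_numpy(), val["y"].to_numpy())
    val["H_z"] = (H - design.h_mean) / design.h_sd
    val["S"] = S
    val["negative"] = (val["valence"] == "negative").astype(int)
    return val.reset_index(drop=True)


def make_valence_frame(land, truth, n, seed, design_scale=None):
    """Simulate n valenced reports ready for the valence model."""
    t = wr.GenerativeTruth(
        beta_sin=truth.beta_sin,
        beta_cos=truth.beta_cos,
        gamma=truth.gamma,
        beta_H=truth.beta_H,
        beta_H2=truth.beta_H2,
        valence_grid=truth.valence_grid,
        valence_shape=truth.valence_shape,
        valence_zone=truth.valence_zone,
        neutral_frac=0.0,
    )
    reps = wr.simulate_reports(land, t, n, seed=seed)
    reps = wr.simulate_valence(reps, land, t, seed=seed + 1)
    H, S, _, _ = land.covariates_at(reps["x"].to_numpy(), reps["y"].to_numpy())
    if design_scale is None:
        hz, m, s = wr.zscore(H)
    else:
        m, s = design_scale
        hz = (H - m) / s
    reps["H_z"] = hz
    reps["S"] = S
    reps["negative"] = (reps["valence"] == "negative").astype(int)
    reps.attrs["h_scale"] = (m, s)
    return reps
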