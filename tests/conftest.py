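import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import caflux as cf

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

COHORT_SEED = 1
COHORT_CELLS = 48


@pytest.fixture(scope="session")
def baseline_cfg():
    return cf.preset("baseline")


@pytest.fixture()
def quiet_cfg():
    """Noise-free, EFS-free, single-site config for rendering-fidelity tests."""
    return cf.preset("baseline").replace(noise_sd=0.0, n_sites=1, duration=5.0, efs=None)


@pytest.fixture(scope="session")
def efs_cohort(baseline_cfg):
    """The desk-scale experiment: 48 simulated cells, 20 s at 33 fps,
    nerve-stimulation preset, full pipeline."""
    results = cf.run_cohort(baseline_cfg, COHORT_CELLS, seed=COHORT_SEED)
    metrics = cf.cohort_metrics(results, baseline_cfg)
    return results, metrics


def render_single_event(
    amplitude=0.8, fdhm=189.0, spread=11.1, velocity=71.4, direction=1,
    t_init=1.0, noise_sd=0.0, seed=0, duration=5.0,
):
    """One rendered event on a one-site cell; returns (movie, cell, event)."""
    from caflux.synthetic import EventSpec, GroundTruth, make_cell, render_movie

    cfg = cf.preset("baseline").replace(
        noise_sd=noise_sd, n_sites=1, duration=duration, efs=None
    )
    rng = np.random.default_rng(seed)
    cell = make_cell(cfg, rng)
    ev = EventSpec(
        site_id=0, t_init=t_init, amplitude=amplitude, fdhm=fdhm,
        spread=spread, velocity=velocity, direction=direction,
    )
    gt = GroundTruth(site_positions_um=cell.site_positions_um, events=[ev])
    movie = render_movie(cell, gt, cfg, rng)
    return movie, cell, ev, cfg
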