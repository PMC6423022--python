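"""Shared fixtures: the expensive Monte Carlo benchmarks are session-scoped
so the jamming, blocking and kinetics checks all reuse the same runs."""

from __future__ import annotations

import numpy as np
import pytest

import nanorsa as nr


@pytest.fixture(scope="session")
def flat_surface():
    return nr.make_flat_surface(500.0)


@pytest.fixture(scope="session")
def flat_runs(flat_surface):
    """20 independent depositions on the 500x500 nm flat benchmark."""
    cfg = nr.AdsorptionConfig(seed=7, repeats=20)
    return nr.run_repeats(flat_surface, nr.HSA, cfg)


@pytest.fixture(scope="session")
def flat_jam(flat_runs):
    return nr.jamming_limit(flat_runs)


def _geometry_runs(H, W, target_ratio, seed, repeats):
    d_p = nr.calibrate_dp(H, W, target_ratio)
    surf = nr.make_gaussian_surface(nr.GaussianArraySpec(H, W, d_p), (1, 1))
    cfg = nr.AdsorptionConfig(seed=seed, repeats=repeats)
    return nr.run_repeats(surf, nr.HSA, cfg)


@pytest.fixture(scope="session")
def spike_runs():
    """Gaussian spike H=500, W=40 at the area ratio 2.8 of the reference table."""
    return _geometry_runs(500.0, 40.0, 2.8, seed=11, repeats=12)


@pytest.fixture(scope="session")
def pillar_runs():
    """Gaussian pillar H=200, W=60 at area ratio 1.9."""
    return _geometry_runs(200.0, 60.0, 1.9, seed=13, repeats=12)


@pytest.fixture(scope="session")
def hole_runs():
    """Gaussian hole H=-550, W=60 at area ratio 3.8."""
    return _geometry_runs(-550.0, 60.0, 3.8, seed=17, repeats=12)


@pytest.fixture(scope="session")
def spike_family(spike_runs):
    """Jamming estimates for spikes of widths 40/60/80 nm at H=500 nm."""
    fam = {40.0: nr.jamming_limit(spike_runs)}
    for W, ratio, seed in ((60.0, 3.6, 19), (80.0, 4.2, 23)):
        runs = _geometry_runs(500.0, W, ratio, seed=seed, repeats=6)
        fam[W] = nr.jamming_limit(runs)
    return fam
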