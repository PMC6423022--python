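"""Deposition engine: exclusion rule, determinism, jamming behaviour."""

import math

import numpy as np
import pytest

import nanorsa as nr
from nanorsa.engine import HEX_PACKING_BOUND


class _ScriptedRng:
    """Stands in for a numpy Generator, replaying scripted uniforms."""

    def __init__(self, values):
        self.values = list(values)

    def random(self, size=None):
        v = self.values.pop(0)
        if size is None:
            return v
        return np.full(size, v)


def min_image_min_distance(centers, Lx, Ly):
    n = len(centers)
    best = np.inf
    for i in range(n - 1):
        dx = np.abs(centers[i + 1:, 0] - centers[i, 0])
        dx = np.minimum(dx, Lx - dx)
        dy = np.abs(centers[i + 1:, 1] - centers[i, 1])
        dy = np.minimum(dy, Ly - dy)
        dz = centers[i + 1:, 2] - centers[i, 2]
        best = min(best, float(np.min(dx ** 2 + dy ** 2 + dz ** 2)))
    return math.sqrt(best)


class TestAttemptAdsorption:
    def test_first_attempt_always_accepted(self):
        state = nr.RsaState(nr.make_flat_surface(100.0), nr.HSA)
        ok, reason = nr.attempt_adsorption(state, _ScriptedRng([0.5, 0.5, 0.0]))
        assert ok and reason is None
        assert len(state.deposits) == 1

    @pytest.mark.parametrize("lateral,expected", [(6.9, False), (7.1, True)])
    def test_pair_exclusion_threshold(self, lateral, expected):
        # second anchor at a controlled lateral distance from the first
        surf = nr.make_flat_surface(100.0)
        state = nr.RsaState(surf, nr.HSA)
        assert nr.attempt_adsorption(state, _ScriptedRng([0.3, 0.5, 0.0]))[0]
        x2 = (0.3 * 100.0 + lateral) / 100.0
        ok, reason = nr.attempt_adsorption(state, _ScriptedRng([x2, 0.5, 0.0]))
        assert ok is expected
        assert reason == (None if expected else "overlap")

    def test_penetration_rejection_in_hole(self):
        # a sphere wider than a steep narrow pit cannot sit at its bottom
        spec = nr.GaussianArraySpec(-200.0, 5.0, 60.0)
        surf = nr.make_gaussian_surface(spec)
        state = nr.RsaState(surf, nr.HSA)
        # anchor exactly at the pit centre: normal is vertical, but the
        # 7 nm sphere spans the 5 nm pit and hits the walls
        ok, reason = nr.attempt_adsorption(state, _ScriptedRng([0.5, 0.5, 0.0]))
        assert not ok and reason == "penetration"
        state.enforce_no_penetration = False
        ok, _ = nr.attempt_adsorption(state, _ScriptedRng([0.5, 0.5, 0.0]))
        assert ok


class TestRunRsa:
    def test_deterministic_given_seed(self):
        surf = nr.make_flat_surface(80.0)
        cfg = nr.AdsorptionConfig(seed=3, stop_after_failures=10_000)
        a = nr.run_rsa(surf, nr.HSA, cfg)
        b = nr.run_rsa(surf, nr.HSA, cfg)
        assert np.array_equal(a.centers, b.centers)
        assert np.array_equal(a.attempts_used, b.attempts_used)
        assert a.n_att == b.n_att

    def test_tiny_box_holds_exactly_one_sphere(self):
        # in an 8x8 nm periodic cell the farthest minimum-image separation
        # is sqrt(32) < 7 nm, so a second disk can never fit
        surf = nr.make_flat_surface(8.0)
        cfg = nr.AdsorptionConfig(seed=1, stop_after_failures=10_000)
        res = nr.run_rsa(surf, nr.HSA, cfg)
        assert res.n_deposits == 1
        assert res.jammed

    def test_hard_core_exclusion_flat(self):
        surf = nr.make_flat_surface(120.0)
        res = nr.run_rsa(surf, nr.HSA, nr.AdsorptionConfig(seed=5, stop_after_failures=10_000))
        assert res.n_deposits > 100
        assert min_image_min_distance(res.centers, 120.0, 120.0) >= nr.HSA.D - 1e-9

    def test_hard_core_exclusion_curved(self, spike_runs):
        res = spike_runs[0]
        Lx = res.A_f ** 0.5
        assert min_image_min_distance(res.centers, Lx, Lx) >= nr.HSA.D - 1e-9

    def test_theta_sequence_strictly_increasing_and_bounded(self, flat_runs):
        theta = flat_runs[0].theta
        assert np.all(np.diff(theta) > 0)
        assert theta[-1] < HEX_PACKING_BOUND

    def test_centers_offset_from_anchors_by_radius(self, spike_runs):
        res = spike_runs[0]
        # periodic wrap can displace the centre's lateral image; compare
        # against the unwrapped offset
        d = res.centers - res.anchors
        Lx = res.A_f ** 0.5
        d[:, :2] = (d[:, :2] + Lx / 2.0) % Lx - Lx / 2.0
        norms = np.linalg.norm(d, axis=1)
        assert np.allclose(norms, nr.HSA.D / 2.0, rtol=1e-9)

    def test_budget_limited_flag(self):
        surf = nr.make_flat_surface(200.0)
        cfg = nr.AdsorptionConfig(seed=2, max_attempts=500, stop_after_failures=10_000)
        res = nr.run_rsa(surf, nr.HSA, cfg)
        assert res.budget_limited
        assert not res.jammed

    def test_config_validation(self):
        with pytest.raises(ValueError):
            nr.AdsorptionConfig(repeats=0)
        with pytest.raises(ValueError):
            nr.AdsorptionConfig(stop_after_failures=100)


class TestOracleEquivalence:
    def test_grid_matches_brute_force_on_random_instances(self):
        """The cell list must be a pure optimisation: same stream, same physics."""
        rng = np.random.default_rng(0)
        n_checked = 0
        for k in range(100):
            if rng.random() < 0.5:
                L = float(rng.uniform(25.0, 100.0))
                surf = nr.make_flat_surface(L)
            else:
                H = float(rng.uniform(-300.0, 300.0))
                if abs(H) < 20.0:
                    H = 50.0
                W = float(rng.uniform(15.0, 50.0))
                d_p = float(rng.uniform(40.0, 100.0))
                surf = nr.make_gaussian_surface(nr.GaussianArraySpec(H, W, d_p))
            cfg = nr.AdsorptionConfig(seed=1000 + k, stop_after_failures=10_000)
            fast = nr.run_rsa(surf, nr.HSA, cfg, use_grid=True)
            slow = nr.run_rsa(surf, nr.HSA, cfg, use_grid=False)
            assert np.array_equal(fast.centers, slow.centers)
            assert np.array_equal(fast.anchors, slow.anchors)
            assert np.array_equal(fast.attempts_used, slow.attempts_used)
            assert fast.n_att == slow.n_att
            n_checked += 1
        assert n_checked == 100


class TestZDistribution:
    def test_flat_all_mass_at_zero(self):
        surf = nr.make_flat_surface(100.0)
        res = nr.run_rsa(surf, nr.HSA, nr.AdsorptionConfig(seed=9, stop_after_failures=10_000))
        counts, edges = nr.z_distribution(res, 1.0)
        assert counts.sum() == res.n_deposits
        nonzero = np.nonzero(counts)[0]
        assert len(nonzero) == 1
        assert edges[nonzero[0]] <= 0.0 <= edges[nonzero[0] + 1]

    def test_pillar_bottom_heavy(self, pillar_runs):
        # far more protein adsorbs near the base than near the pillar tops
        counts, edges = nr.z_distribution(pillar_runs[0], 10.0)
        assert counts.sum() == pillar_runs[0].n_deposits
        mid = len(counts) // 2
        assert counts[:mid].sum() > 2 * counts[mid:].sum()

    def test_empty_run_rejected(self):
        surf = nr.make_flat_surface(100.0)
        res = nr.run_rsa(surf, nr.HSA, nr.AdsorptionConfig(seed=9, max_attempts=0,
                                                           stop_after_failures=10_000))
        with pytest.raises(ValueError):
            nr.z_distribution(res, 1.0)


class TestProteinModel:
    def test_cross_section_consistent(self):
        p = nr.ProteinModel(D=7.0)
        assert p.sigma == pytest.approx(math.pi * 49.0 / 4.0, rel=1e-15)

    def test_invalid_diameter(self):
        with pytest.raises(ValueError):
            nr.ProteinModel(D=-1.0)
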