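"""Model surfaces, Langevin dynamics, metadynamics and charge environments."""

import math

import numpy as np
import pytest

from redelim._units import R_KCAL
from redelim.exceptions import DomainEscapeError, ParameterError
from redelim.fes import count_crossings
from redelim.synthetic_data import (
    HarmonicSurface,
    _coulomb_field_at,
    langevin_trajectory,
    make_charge_environment,
    make_double_well,
    run_metadynamics,
)


class TestDoubleWell:
    def test_analytic_stationary_points(self):
        s = make_double_well(24.0, 1.0, 2.0)
        assert s.value((1.0, 0.0)) == pytest.approx(0.0, abs=1e-12)
        assert s.value((-1.0, 0.0)) == pytest.approx(0.0, abs=1e-12)
        assert s.value((0.0, 0.0)) == pytest.approx(24.0)
        for p in s.stationary_points:
            assert np.linalg.norm(s.gradient(p)) < 1e-8
            assert np.all(np.isfinite(s.value(p)))

    @pytest.mark.parametrize("bad", [(0, 1, 1), (1, -1, 1), (1, 1, 0)])
    def test_rejects_nonpositive_parameters(self, bad):
        with pytest.raises(ParameterError):
            make_double_well(*bad)


class TestLangevin:
    def test_harmonic_equipartition(self):
        """Long sampling of a harmonic well reproduces var(x) = k_BT/k."""
        k = 1.0
        traj = langevin_trajectory(
            HarmonicSurface(k, k), (0.0, 0.0),
            temperature=298.0, friction=1.0, dt=0.02, n_steps=200_000, seed=7,
        )
        target = R_KCAL * 298.0 / k
        assert traj.cv1.var() == pytest.approx(target, rel=0.05)
        # the second CV carries its own finite-sampling noise; looser band
        assert traj.cv2.var() == pytest.approx(target, rel=0.10)

    def test_zero_steps_returns_start_only(self):
        traj = langevin_trajectory(
            HarmonicSurface(), (0.3, -0.2), n_steps=0, seed=1
        )
        assert len(traj) == 1
        assert np.allclose(traj.cvs[0], (0.3, -0.2))

    def test_seed_determinism_is_bitwise(self):
        kw = dict(n_steps=500, dt=0.05, seed=42)
        a = langevin_trajectory(HarmonicSurface(), (0.0, 0.0), **kw)
        b = langevin_trajectory(HarmonicSurface(), (0.0, 0.0), **kw)
        assert np.array_equal(a.cvs, b.cvs)

    def test_domain_escape_carries_last_valid_frames(self):
        s = make_double_well(1.0, 1.0, 0.5)  # domain x in [-3, 3]
        with pytest.raises(DomainEscapeError) as err:
            langevin_trajectory(s, (2.9, 0.0), dt=20.0, n_steps=100, seed=0)
        partial = err.value.last_valid
        assert partial is not None and len(partial) >= 1
        assert s.in_domain(partial.cvs[-1])


class TestMetadynamics:
    def test_hill_count_matches_pace(self):
        s = make_double_well(6.0, 1.0, 2.0)
        _, hills = run_metadynamics(s, pace=30, n_steps=3000, seed=0)
        assert len(hills) == 100

    def test_standard_metadynamics_heights_undamped(self):
        s = make_double_well(6.0, 1.0, 2.0)
        _, hills = run_metadynamics(
            s, bias_factor=math.inf, height=3.1375, n_steps=1500, seed=0
        )
        assert np.allclose(hills.heights, 3.1375)

    def test_well_tempered_heights_decay(self):
        s = make_double_well(6.0, 1.0, 2.0)
        _, hills = run_metadynamics(
            s, bias_factor=15.0, height=3.1375, n_steps=9000, seed=0
        )
        assert hills.heights[0] <= 3.1375
        assert hills.heights[-20:].mean() < hills.heights[:5].mean()

    def test_invalid_bias_factor_rejected(self):
        s = make_double_well(6.0, 1.0, 2.0)
        with pytest.raises(ParameterError):
            run_metadynamics(s, bias_factor=1.0, n_steps=60, seed=0)

    def test_run_until_crossed_visits_both_wells(self):
        """Biased run on the 6 kcal/mol double well commits across the
        dividing surface at least three times (the stopping rule)."""
        s = make_double_well(6.0, 1.0, 2.0)
        traj, hills = run_metadynamics(
            s, n_steps=20_000, min_crossings=3, max_steps=80_000, seed=1
        )
        assert count_crossings(traj, 0.0) >= 3
        assert traj.cv1.min() < -0.5 and traj.cv1.max() > 0.5

    def test_trajectory_and_hills_deterministic(self):
        s = make_double_well(6.0, 1.0, 2.0)
        t1, h1 = run_metadynamics(s, n_steps=900, seed=9)
        t2, h2 = run_metadynamics(s, n_steps=900, seed=9)
        assert np.array_equal(t1.cvs, t2.cvs)
        assert np.array_equal(h1.heights, h2.heights)


class TestChargeEnvironment:
    def test_single_charge_coulomb_magnitude(self):
        """A +1 e charge 10 Å from the probe on the bond axis gives
        |E| = kq/r² = 14.40 MV/cm projected on the bond."""
        mid_x = 2.1 / 2  # bond-1 midpoint
        env, gt = make_charge_environment(
            {
                "bulk_water": {"charges": [1.0],
                               "positions": [[mid_x - 10.0, 0.0, 0.0]]},
                "complexed_water": {},
                "cage": {},
            },
            seed=0,
        )
        assert gt["bulk_water"][0] == pytest.approx(14.3996, rel=1e-4)

    def test_mirror_pair_perpendicular_to_bond_cancels(self):
        mid = [2.1 / 2, 0.0, 0.0]
        env, gt = make_charge_environment(
            {
                "bulk_water": {
                    "charges": [1.0, 1.0],
                    "positions": [
                        [mid[0], 0.0, 5.0],
                        [mid[0], 0.0, -5.0],
                    ],
                },
                "complexed_water": {},
                "cage": {},
            },
            seed=0,
        )
        assert gt["bulk_water"][0] == pytest.approx(0.0, abs=1e-12)

    def test_group_fields_superpose_exactly(self):
        env, gt = make_charge_environment(seed=3)
        merged_q = np.concatenate([q for q, _ in env.groups.values()])
        merged_p = np.vstack([p for _, p in env.groups.values()])
        for b, probe in enumerate(env.probes):
            total = sum(gt[g][b] for g in gt)
            e = _coulomb_field_at(probe.midpoint, merged_q, merged_p)
            assert total == pytest.approx(float(e @ probe.unit), abs=1e-9)

    def test_empty_group_warns_and_records_zero(self):
        with pytest.warns(UserWarning, match="empty"):
            _, gt = make_charge_environment(
                {"bulk_water": {"kind": "water_shell", "n_waters": 3},
                 "complexed_water": {}, "cage": {}},
                seed=1,
            )
        assert gt["cage"] == (0.0, 0.0)

    def test_environment_deterministic_from_seed(self):
        _, gt1 = make_charge_environment(seed=5)
        _, gt2 = make_charge_environment(seed=5)
        assert gt1 == gt2
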