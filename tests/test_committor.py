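"""Transition-state candidate selection and committor shooting."""

import numpy as np
import pytest

from redelim.committor import (
    BasinWindow,
    basin_windows_from_minima,
    estimate_committor,
    is_transition_state,
    select_candidates,
)
from redelim.exceptions import ParameterError
from redelim.synthetic_data import make_double_well
from statsmodels.stats.proportion import proportion_confint


TS_POINT = (2.1, 0.35)


def planted_series(n_total=1000, n_planted=45, seed=0):
    """CV series with exactly ``n_planted`` frames inside the selection
    window around TS_POINT and the rest strictly outside it."""
    rng = np.random.default_rng(seed)
    outside = []
    while len(outside) < n_total - n_planted:
        pts = rng.uniform([1.0, 0.0], [4.0, 1.0], size=(200, 2))
        mask = (np.abs(pts[:, 0] - TS_POINT[0]) > 0.05) | (
            np.abs(pts[:, 1] - TS_POINT[1]) > 0.005
        )
        outside.extend(pts[mask].tolist())
    outside = np.array(outside[: n_total - n_planted])
    inside = TS_POINT + rng.uniform(
        [-0.05, -0.005], [0.05, 0.005], size=(n_planted, 2)
    ) * 0.99
    series = np.vstack([outside, inside])
    rng.shuffle(series)
    return series


class TestSelectCandidates:
    def test_exact_ts_frame_selected(self):
        series = np.array([[3.0, 0.8], list(TS_POINT), [1.5, 0.1]])
        assert select_candidates(series, TS_POINT).tolist() == [1]

    def test_planted_fixture_recovered_exactly(self):
        """The ±0.05 Å / ±0.005 CN window returns exactly the 45 planted
        in-window frames out of 1000."""
        series = planted_series()
        idx = select_candidates(series, TS_POINT)
        assert idx.size == 45
        sel = series[idx]
        assert np.all(np.abs(sel[:, 0] - TS_POINT[0]) <= 0.05)
        assert np.all(np.abs(sel[:, 1] - TS_POINT[1]) <= 0.005)

    def test_empty_selection_warns(self):
        series = np.array([[9.0, 0.9]])
        with pytest.warns(UserWarning, match="no frames"):
            assert select_candidates(series, TS_POINT).size == 0

    def test_nonpositive_tolerance_rejected(self):
        with pytest.raises(ParameterError):
            select_candidates(np.zeros((1, 2)), TS_POINT, tol_distance=0.0)


class TestEstimateCommittor:
    @pytest.fixture(scope="class")
    def surface(self):
        return make_double_well(6.0, 1.0, 2.0)

    @pytest.fixture(scope="class")
    def basins(self):
        return basin_windows_from_minima((-1.0, 0.0), (1.0, 0.0))

    def test_saddle_commits_half_and_half(self, surface, basins):
        result = estimate_committor(surface, (0.0, 0.0), basins,
                                    n_shots=400, seed=11)
        assert 0.44 <= result.p_product <= 0.56
        assert sum(result.outcomes.values()) == 400
        assert is_transition_state(result)

    def test_basin_interior_commits_to_itself(self, surface, basins):
        result = estimate_committor(surface, (-1.0, 0.0), basins,
                                    n_shots=200, seed=12)
        assert result.p_product < 0.05
        assert not is_transition_state(result)

    def test_monotone_along_reaction_coordinate(self, surface, basins):
        """p_product does not decrease when the shooting point moves from
        the reactant side of the saddle toward the product well."""
        ps = [
            estimate_committor(surface, (x, 0.0), basins, n_shots=200,
                               seed=13).p_product
            for x in (-0.4, 0.0, 0.4)
        ]
        assert ps[0] <= ps[1] + 0.05 <= ps[2] + 0.10

    def test_zero_shots_rejected(self, surface, basins):
        with pytest.raises(ParameterError):
            estimate_committor(surface, (0, 0), basins, n_shots=0, seed=0)

    def test_overlapping_basins_rejected(self, surface):
        a = BasinWindow((0.0, 0.0), (1.0, 1.0))
        b = BasinWindow((0.5, 0.0), (1.0, 1.0))
        with pytest.raises(ParameterError):
            estimate_committor(surface, (0, 0), (a, b), n_shots=10, seed=0)

    def test_deterministic_from_seed(self, surface, basins):
        r1 = estimate_committor(surface, (0.1, 0.0), basins, n_shots=50, seed=3)
        r2 = estimate_committor(surface, (0.1, 0.0), basins, n_shots=50, seed=3)
        assert r1.outcomes == r2.outcomes


class TestIsTransitionState:
    def _result(self, p, n):
        k = round(p * n)
        lo, hi = proportion_confint(k, n, alpha=0.05, method="wilson")
        from redelim.committor import CommittorResult

        return CommittorResult(
            p_product=k / n,
            n_shots=n,
            ci95=(float(lo), float(hi)),
            outcomes={"product": k, "reactant": n - k, "timeout": 0},
        )

    def test_57_percent_of_100_accepted(self):
        assert is_transition_state(self._result(0.57, 100))

    def test_99_percent_of_400_rejected(self):
        assert not is_transition_state(self._result(0.99, 400))

    def test_38_percent_of_50_accepted_via_wide_ci(self):
        assert is_transition_state(self._result(0.38, 50))
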