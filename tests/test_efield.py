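"""Field projection, bond dipoles and the electrostatic decomposition."""

import numpy as np
import pytest

from redelim.efield import (
    BondFieldSnapshot,
    bond_dipole,
    compare_reactions,
    decompose,
    delta_g_elec,
    group_fields,
    project_field,
    snapshots_from_table,
)
from redelim.exceptions import ParameterError, SchemaError
from redelim.io import load_reference_table
from redelim.synthetic_data import make_charge_environment


class TestProjectField:
    @pytest.mark.parametrize(
        "field, bond, expected",
        [
            ((10.0, 0.0, 0.0), (1.0, 0.0, 0.0), 10.0),
            ((0.0, 7.0, 0.0), (1.0, 0.0, 0.0), 0.0),
            ((3.0, 4.0, 0.0), (0.6, 0.8, 0.0), 5.0),
        ],
    )
    def test_signed_projection(self, field, bond, expected):
        assert project_field(field, bond) == pytest.approx(expected)

    def test_unnormalized_bond_rejected(self):
        with pytest.raises(ParameterError):
            project_field((1, 0, 0), (2.0, 0.0, 0.0))


class TestBondDipole:
    def test_no_charge_separation(self):
        assert bond_dipole(0.4, 0.4, 2.1) == 0.0

    def test_unit_conversion(self):
        assert bond_dipole(1.0, -1.0, 1.0) == pytest.approx(-4.8032, abs=1e-3)

    def test_linear_in_length(self):
        assert bond_dipole(0.3, -0.5, 4.2) == pytest.approx(
            2 * bond_dipole(0.3, -0.5, 2.1)
        )

    def test_nonpositive_length_rejected(self):
        with pytest.raises(ParameterError):
            bond_dipole(0.1, -0.1, 0.0)


class TestGroupFields:
    def test_matches_environment_ground_truth(self):
        env, gt = make_charge_environment(seed=4)
        computed = group_fields(env)
        for group in gt:
            assert computed[group] == pytest.approx(gt[group], abs=1e-9)

    def test_merged_groups_superpose(self):
        env, _ = make_charge_environment(seed=5)
        per_group = group_fields(env)
        merged_env, _ = make_charge_environment(
            {
                "bulk_water": {
                    "charges": np.concatenate(
                        [q for q, _ in env.groups.values()]
                    ),
                    "positions": np.vstack([p for _, p in env.groups.values()]),
                },
                "complexed_water": {},
                "cage": {},
            },
            seed=0,
        )
        merged = group_fields(merged_env)["bulk_water"]
        for b in range(2):
            assert merged[b] == pytest.approx(
                sum(per_group[g][b] for g in per_group), abs=1e-9
            )


def snapshot(state, dipoles, fields):
    return BondFieldSnapshot(state=state, dipoles=dipoles, fields=fields)


class TestDeltaGElec:
    def test_catalyzed_complexed_water_contribution(self):
        """Reference worked example: the single complexed water stabilizes the
        catalyzed TS by −13.62 kcal/mol."""
        rs = snapshot("RS", {1: -6.15, 2: -2.83},
                      {"complexed_water": {1: 40.81, 2: -7.97}})
        ts = snapshot("TS", {1: 2.05, 2: 0.71},
                      {"complexed_water": {1: 19.30, 2: 22.27}})
        assert delta_g_elec(rs, ts, "complexed_water") == pytest.approx(
            -13.62, abs=0.1
        )

    def test_uncatalyzed_bulk_water_contribution(self):
        rs = snapshot("RS", {1: -6.15, 2: -2.83},
                      {"bulk_water": {1: -21.49, 2: -12.75}})
        ts = snapshot("TS", {1: -1.26, 2: 3.67},
                      {"bulk_water": {1: -4.55, 2: -15.81}})
        assert delta_g_elec(rs, ts, "bulk_water") == pytest.approx(10.58, abs=0.1)

    def test_zero_fields_give_zero(self):
        rs = snapshot("RS", {1: -6.15, 2: -2.83}, {"cage": {1: 0.0, 2: 0.0}})
        ts = snapshot("TS", {1: 2.05, 2: 0.71}, {"cage": {1: 0.0, 2: 0.0}})
        assert delta_g_elec(rs, ts, "cage") == 0.0

    def test_missing_group_is_schema_error(self):
        rs = snapshot("RS", {1: 0.0, 2: 0.0}, {"cage": {1: 1.0, 2: 1.0}})
        ts = snapshot("TS", {1: 0.0, 2: 0.0}, {"bulk_water": {1: 1.0, 2: 1.0}})
        with pytest.raises(SchemaError):
            delta_g_elec(rs, ts, "cage")

    def test_negating_ts_fields_negates_ts_term_only(self):
        rs = snapshot("RS", {1: -2.0, 2: 1.0}, {"cage": {1: 3.0, 2: -4.0}})
        ts = snapshot("TS", {1: 1.5, 2: 0.5}, {"cage": {1: 2.0, 2: 6.0}})
        ts_neg = snapshot("TS", {1: 1.5, 2: 0.5}, {"cage": {1: -2.0, 2: -6.0}})
        rs_zero = snapshot("RS", {1: -2.0, 2: 1.0}, {"cage": {1: 0.0, 2: 0.0}})
        ts_term = delta_g_elec(rs_zero, ts, "cage")
        full = delta_g_elec(rs, ts, "cage")
        flipped = delta_g_elec(rs, ts_neg, "cage")
        assert flipped == pytest.approx(full - 2 * ts_term)


class TestDecompose:
    @pytest.fixture(scope="class")
    def table(self):
        return load_reference_table()

    def test_catalyzed_groups_and_total(self, table):
        d = decompose(table, "catalyzed")
        assert d.per_group["bulk_water"] == pytest.approx(9.07, abs=0.1)
        assert d.per_group["complexed_water"] == pytest.approx(-13.62, abs=0.1)
        assert d.per_group["cage"] == pytest.approx(-1.04, abs=0.1)
        assert d.total == pytest.approx(-5.60, abs=0.1)
        assert d.total == pytest.approx(sum(d.per_group.values()), abs=1e-12)

    def test_uncatalyzed_total(self, table):
        d = decompose(table, "uncatalyzed")
        assert d.total == pytest.approx(-0.71, abs=0.1)

    def test_net_stabilization_about_five(self, table):
        c = compare_reactions(table)
        assert c["difference_magnitude_kcal_mol"] == pytest.approx(4.9, abs=0.1)

    def test_group_additivity_under_summed_fields(self, table):
        """Summing per-group fields first and applying the decomposition once
        gives the same total (linearity in E)."""
        rs, ts = snapshots_from_table(table, "catalyzed")
        merged_fields = {}
        for snap in (rs, ts):
            merged_fields[snap.state] = {
                b: sum(snap.fields[g][b] for g in snap.fields) for b in (1, 2)
            }
        rs_m = snapshot("RS", rs.dipoles, {"all": merged_fields["RS"]})
        ts_m = snapshot("TS", ts.dipoles, {"all": merged_fields["TS"]})
        total = decompose(table, "catalyzed").total
        assert delta_g_elec(rs_m, ts_m, "all") == pytest.approx(total, abs=1e-9)

    def test_raw_charge_consistency_enforced(self):
        with pytest.raises(SchemaError, match="disagrees"):
            BondFieldSnapshot(
                state="RS",
                dipoles={1: 1.0},
                fields={"cage": {1: 5.0}},
                raw={1: (0.3, 0.3, 2.1)},  # implies dipole 0, not 1
            )
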