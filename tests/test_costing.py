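"""Electricity-per-gram and cost conversion algebra."""

import pytest
from hypothesis import given
from hypothesis import strategies as st

from emplix.constants import F, N_A
from emplix.costing import (
    cost_per_tonne,
    cost_table,
    energy_cost,
    energy_per_gram_dual,
    energy_per_gram_single,
    production_rate,
)
from emplix.scenarios import load_scenario

positive = st.floats(0.1, 100, allow_nan=False)


class TestSingleCell:
    def test_wood_ljungdahl_acetate_anchor(self):
        # 8 electrons, 2.0 V, MW 60.05 -> 25.7 kJ/g
        assert energy_per_gram_single(8, 2.0, 60.05, 1.0) == pytest.approx(
            25_710, rel=1e-3
        )

    def test_zero_electrons(self):
        assert energy_per_gram_single(0, 2.0, 60.05) == 0.0

    def test_eeu_acetate_anchor(self):
        # 22 electrons at 1.59 V reproduce the most expensive configuration
        assert energy_per_gram_single(22, 1.59, 60.05) / 1e3 == pytest.approx(
            56.2, abs=0.05
        )

    @given(nu=positive, du=positive, mw=positive, xi=st.floats(0.1, 1.0))
    def test_homogeneity(self, nu, du, mw, xi):
        base = energy_per_gram_single(nu, du, mw, xi)
        assert energy_per_gram_single(2 * nu, du, mw, xi) == pytest.approx(2 * base)
        assert energy_per_gram_single(nu, 2 * du, mw, xi) == pytest.approx(2 * base)
        assert energy_per_gram_single(nu, du, 2 * mw, xi) == pytest.approx(base / 2)
        assert energy_per_gram_single(nu, du, mw, xi / 2) == pytest.approx(2 * base)


class TestDualCell:
    def test_hand_arithmetic(self):
        scn = load_scenario("H2+formate")
        # (F/60.05) * [3.02*2*2/0.8 + 2.0*6] = 43.5 kJ/g
        out = energy_per_gram_dual(6, 2, scn, 60.05)
        assert out / 1e3 == pytest.approx(43.55, abs=0.01)

    def test_zero_requirement(self):
        scn = load_scenario("H2+formate")
        assert energy_per_gram_dual(0, 0, scn, 60.05) == 0.0

    def test_non_formate_scenario_rejected(self):
        with pytest.raises(ValueError, match="no abiotic"):
            energy_per_gram_dual(6, 2, load_scenario("H2"), 60.05)

    def test_reduces_to_single_cell_without_cell1(self):
        scn = load_scenario("H2+formate")
        dual = energy_per_gram_dual(8, 0, scn, 60.05)
        single = energy_per_gram_single(8, scn.delta_u_cell2, 60.05, scn.xi_i2)
        assert dual == pytest.approx(single)


class TestCostPerTonne:
    @pytest.mark.parametrize(
        "kj_per_g, usd", [(25.7, 214.2), (56.2, 468.3), (0.0, 0.0)]
    )
    def test_published_conversions(self, kj_per_g, usd):
        assert cost_per_tonne(kj_per_g * 1e3, 0.03) == pytest.approx(usd, abs=0.5)

    def test_ratio_is_unit_algebra(self):
        # $/t per kJ/g is 1e6/3.6e6*price = 8.333 at 3 cents/kWh
        assert cost_per_tonne(1e3, 0.03) == pytest.approx(25 / 3, rel=1e-12)


class TestProductionRate:
    def test_hand_example(self):
        assert production_rate(330, 2.0, 8, 1.0) == pytest.approx(1.29e20, rel=0.01)

    def test_zero_power(self):
        assert production_rate(0, 2.0, 8) == 0.0

    def test_monotone_decreasing_in_nu_e(self):
        rates = [production_rate(330, 2.0, nu) for nu in (4, 8, 16, 64)]
        assert rates == sorted(rates, reverse=True)

    def test_power_balance_closes(self):
        # rate * (mw/N_A) * e_per_gram == electrical power
        nu, du, mw, p = 8, 2.0, 60.05, 330.0
        rate = production_rate(p, du, nu)
        epg = energy_per_gram_single(nu, du, mw)
        assert rate * mw / N_A * epg == pytest.approx(p, rel=1e-9)


@pytest.fixture(scope="module")
def table():
    return cost_table()


class TestCostTable:
    def test_row_count(self, table):
        assert len(table) == 4 * 7 * 2  # lixiviants x pathways x mediators

    def test_band_ordering(self, table):
        assert (table.kj_per_g_lo <= table.kj_per_g + 1e-9).all()
        assert (table.kj_per_g <= table.kj_per_g_hi + 1e-9).all()

    def test_global_minimum_is_citric_wl_h2(self, table):
        row = table.loc[table.kj_per_g.idxmin()]
        assert (row.lixiviant, row.pathway, row.mediator) == (
            "citric", "wood_ljungdahl", "H2",
        )
        assert row.kj_per_g == pytest.approx(21.1, rel=0.02)

    def test_degenerate_band_for_atp_neutral_network(self, table):
        row = table[
            (table.lixiviant == "acetic")
            & (table.pathway == "wood_ljungdahl")
            & (table.mediator == "H2")
        ].iloc[0]
        assert row.kj_per_g_lo == pytest.approx(row.kj_per_g_hi)

    def test_dollar_column_is_fixed_multiple(self, table):
        ratio = table.usd_per_tonne / table.kj_per_g
        assert ratio.min() == pytest.approx(ratio.max())
        assert ratio.iloc[0] == pytest.approx(25 / 3, rel=1e-9)

    def test_most_expensive_is_acetic_fourhb_eeu(self, table):
        row = table.loc[table.kj_per_g.idxmax()]
        assert (row.lixiviant, row.pathway, row.mediator) == (
            "acetic", "fourhb", "EEU",
        )
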