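"""Reaction parsing, flux balancing and conservation laws."""

from fractions import Fraction

import numpy as np
import pytest

from emplix.constants import degree_of_reduction
from emplix.networks import (
    BalanceError,
    balance,
    parse_network,
    shipped_network,
    shipped_networks,
    write_network,
)
from emplix.networks.balance import stoichiometric_matrix
from emplix.networks.parser import parse_formula, parse_reaction

CARRIER_HEADER = """
@source    co2
@exchange  co2 h2o nadh nad fdred fdox atp adp
! co2   CO2
! h2o   H2O
! nadh  H2
! nad   .
! fdred H2
! fdox  .
! atp   .
! adp   .
"""


def make_network(body: str, target: str, extra_mets: str = "") -> "object":
    text = f"@target    {target}\n{CARRIER_HEADER}\n{extra_mets}\n{body}"
    return parse_network(text, name="toy")


class TestParser:
    def test_formula_parsing(self):
        assert parse_formula("C6H12O7") == {"C": 6, "H": 12, "O": 7}
        assert parse_formula(".") == {}
        with pytest.raises(ValueError):
            parse_formula("6CH")

    def test_reaction_grammar(self):
        rxn = parse_reaction("r1: a + 2 b -> 3/2 c")
        assert rxn.stoich == {"a": Fraction(-1), "b": Fraction(-2), "c": Fraction(3, 2)}
        assert not rxn.reversible
        assert parse_reaction("r2: a <-> b").reversible

    def test_elemental_balance_enforced(self):
        with pytest.raises(ValueError, match="unbalanced"):
            make_network(
                "bad: co2 + nadh -> x + nad",
                target="x",
                extra_mets="! x CH2O",  # CH2O2 would balance; CH2O does not
            )

    def test_write_read_roundtrip(self):
        net = shipped_network("wood_ljungdahl", "acetic")
        again = parse_network(write_network(net))
        assert [r.id for r in again.reactions] == [r.id for r in net.reactions]
        assert all(
            again.reactions[i].stoich == net.reactions[i].stoich
            for i in range(len(net.reactions))
        )
        assert again.exchange_species == net.exchange_species


class TestBalanceToyNetworks:
    def test_single_reaction_identity(self):
        net = make_network(
            "r: co2 + 2 nadh + atp -> x + 2 nad + adp + h2o",
            target="x",
            extra_mets="! x CH2O",
        )
        flux, req = balance(net)
        assert flux["r"] == pytest.approx(1.0)
        assert (req.nu_nadh, req.nu_fd, req.nu_atp) == (2.0, 0.0, 1.0)
        assert req.carbon_in == pytest.approx(1.0)

    def test_two_reaction_chain(self):
        # hand linear solve: y made once, consumed once; 4 NADH, 1 ATP total
        net = make_network(
            "r1: 2 co2 + 4 nadh -> y + 4 nad + 2 h2o\n"
            "r2: y + atp -> x + adp",
            target="x",
            extra_mets="! x C2H4O2\n! y C2H4O2",
        )
        _, req = balance(net)
        assert req.nu_nadh == pytest.approx(4.0)
        assert req.nu_atp == pytest.approx(1.0)
        assert req.carbon_in == pytest.approx(2.0)

    def test_surplus_atp_clamped_not_credited(self):
        net = make_network(
            "r1: 2 co2 + 4 nadh -> y + 4 nad + 2 h2o\n"
            "r2: y + adp -> x + atp",
            target="x",
            extra_mets="! x C2H4O2\n! y C2H4O2",
        )
        _, req = balance(net)
        assert req.nu_atp == 0.0  # clamped
        assert req.raw_atp == pytest.approx(-1.0)  # surplus retained pre-clamp

    def test_infeasible_network_names_metabolite(self):
        # elementally balanced, but 'orphan' is internal and never consumed
        net = make_network(
            "r: co2 + 2 nadh -> x + 2 nad + orphan",
            target="x",
            extra_mets="! x CH2O2\n! orphan H2",
        )
        with pytest.raises(BalanceError, match="orphan"):
            balance(net)


def lstsq_oracle(net):
    """Brute-force least-squares solve of S_internal v = b as an independent
    check on the LP path: returns the exchange imports."""
    S, mets = stoichiometric_matrix(net)
    rows = [mets.index(m) for m in net.internal_metabolites]
    rows.append(mets.index(net.target))
    A = S[rows, :]
    b = np.zeros(len(rows))
    b[-1] = 1.0
    v, *_ = np.linalg.lstsq(A, b, rcond=None)
    assert np.allclose(A @ v - b, 0, atol=1e-9), "oracle residual"
    resid = S @ v
    return {
        m: -resid[mets.index(m)] for m in net.exchange_species if m in mets
    }


@pytest.fixture(scope="module")
def networks():
    return shipped_networks()


class TestShippedNetworks:
    def test_all_28_resolve_and_balance(self, networks, all_requirements):
        assert len(networks) == 28
        for key, req in all_requirements.items():
            req.validate()

    def test_oracle_equivalence(self, networks, all_requirements):
        """LP solution agrees with an independent least-squares solve."""
        for key, net in networks.items():
            imports = lstsq_oracle(net)
            req = all_requirements[key]
            assert imports.get("nadh", 0) == pytest.approx(req.raw_nadh, abs=1e-6), key
            assert imports.get("fdred", 0) == pytest.approx(req.raw_fd, abs=1e-6), key
            assert imports.get("atp", 0) == pytest.approx(req.raw_atp, abs=1e-6), key

    def test_carbon_and_electron_conservation(self, networks, all_requirements):
        for key, net in networks.items():
            all_requirements[key].check_conservation(net)

    def test_carbon_in_matches_target_carbons(self, networks, all_requirements):
        for (pathway, lix), req in all_requirements.items():
            n_c = networks[(pathway, lix)].formulas[networks[(pathway, lix)].target]["C"]
            assert req.carbon_in == pytest.approx(n_c), (pathway, lix)

    def test_co2_networks_electron_identity(self, networks, all_requirements):
        """All product electrons ride the 2-electron carriers from CO2."""
        for (pathway, lix), req in all_requirements.items():
            net = networks[(pathway, lix)]
            if net.carbon_source != "co2":
                continue
            gamma = degree_of_reduction(net.formulas[net.target])
            assert 2 * (req.nu_nadh + req.nu_fd) == pytest.approx(gamma), (pathway, lix)

    def test_wood_ljungdahl_acetate_anchor(self, all_requirements):
        req = all_requirements[("wood_ljungdahl", "acetic")]
        assert req.nu_nadh + req.nu_fd == pytest.approx(4.0)
        assert req.nu_atp == 0.0  # ATP-neutral: the basis of the zero error bar
        assert req.carbon_in == pytest.approx(2.0)

    def test_formolase_acetate_formate_count(self, all_requirements):
        assert all_requirements[("formolase", "acetic")].nu_r == pytest.approx(2.0)

    def test_calvin_gluconate_carbon(self, all_requirements):
        assert all_requirements[("calvin", "gluconic")].carbon_in == pytest.approx(6.0)

    def test_pathway_energy_ranking(self):
        """Wood-Ljungdahl is the most, the 4HB cycle the least efficient
        fixation route, for every lixiviant and mediator."""
        from emplix.costing import energy_cost
        from emplix.networks.library import CO2_PATHWAYS, LIXIVIANT_IDS

        for lix in LIXIVIANT_IDS:
            for med in ("H2", "EEU"):
                energies = {
                    p: energy_cost(lix, p, med).e_per_gram for p in CO2_PATHWAYS
                }
                assert min(energies, key=energies.get) == "wood_ljungdahl", (lix, med)
                assert max(energies, key=energies.get) == "fourhb", (lix, med)
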