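"""Electron-requirement equations: proton bookkeeping and step behaviour."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from emplix.bioenergetics import (
    DEFAULT_PARAMS,
    ElectronTransportParams,
    electrons_eeu,
    electrons_h2,
    protons_per_atp,
)
from emplix.networks.model import CofactorRequirement


def req(n=0.0, f=0.0, a=0.0):
    return CofactorRequirement(
        nu_nadh=n, nu_fd=f, nu_atp=a, nu_r=0.0, carbon_in=0.0,
        raw_nadh=n, raw_fd=f, raw_atp=a,
    )


class TestProtonsPerAtp:
    @pytest.mark.parametrize(
        "dg, du, expected",
        [
            (50_000.0, 0.14, 4),  # ceil(50000/13508)
            (50_000.0, 0.24, 3),  # ceil(2.159)
            (1e-6, 0.14, 1),  # vanishing dG clamps at one proton
        ],
    )
    def test_hand_arithmetic(self, dg, du, expected):
        p = ElectronTransportParams(delta_u_membrane=du, dg_atp=dg)
        assert protons_per_atp(p) == expected


class TestElectronsH2:
    def test_zero_requirement(self):
        assert electrons_h2(req()).nu_e == 0.0

    def test_hand_example(self):
        # span floor(1.23/0.14)=8 at defaults; spec'd smaller-span variant:
        # floor((0.82+0.41)/0.14) with a single NADH and one ATP
        p = ElectronTransportParams(delta_u_membrane=0.14, dg_atp=50_000.0)
        out = electrons_h2(req(n=1, a=1), p)
        assert out.nu_e == pytest.approx(2 + 4 / 8)
        assert sum(out.breakdown.values()) == pytest.approx(out.nu_e)

    def test_atp_free_reduces_to_carrier_electrons(self):
        """With nu_ATP = 0 the result is 2(nu_NADH + nu_Fd), independent of
        every potential."""
        for du in (0.08, 0.11, 0.14, 0.19, 0.24):
            p = DEFAULT_PARAMS.at_membrane_potential(du)
            assert electrons_h2(req(n=3, f=1), p).nu_e == 8.0

    def test_membrane_too_large_raises(self):
        p = ElectronTransportParams(delta_u_membrane=0.4, u_h2=0.5, u_acceptor=0.82)
        with pytest.raises(ValueError, match="cannot pump"):
            electrons_h2(req(n=1, a=1), p)


class TestElectronsEEU:
    def test_zero_requirement(self):
        assert electrons_eeu(req()).nu_e == 0.0

    def test_single_nadh_hand_arithmetic(self):
        # uphill ceil(0.2315/0.14) = 2 protons per electron, two electrons
        # per NAD(P)H; span floor(0.9085/0.14) = 6
        out = electrons_eeu(req(n=1), DEFAULT_PARAMS)
        assert out.nu_e == pytest.approx(2 + 2 * 2 / 6)

    def test_fd_term_activates(self):
        # ferredoxin sits lower: ceil(0.3315/0.14) = 3 protons per electron
        out = electrons_eeu(req(f=1), DEFAULT_PARAMS)
        assert out.nu_e == pytest.approx(2 + 2 * 3 / 6)
        assert out.breakdown["fd_uphill"] > out.breakdown["nadh_uphill"]

    def test_eeu_dominates_h2_for_all_shipped(self, all_requirements):
        for key, r in all_requirements.items():
            assert electrons_eeu(r).nu_e >= electrons_h2(r).nu_e, key

    @given(
        n=st.floats(0, 20), f=st.floats(0, 10), a=st.floats(0, 50),
    )
    def test_eeu_at_least_carrier_electrons(self, n, f, a):
        out = electrons_eeu(req(n=n, f=f, a=a))
        assert out.nu_e >= 2 * (n + f) - 1e-9


class TestStepBehaviour:
    def test_piecewise_constant_in_membrane_potential(self):
        """nu_e is a step function of dU_membrane: finitely many values over
        a dense sweep, with the central value bracketed by the edges."""
        r = req(n=6, f=3, a=6)  # the citrate-via-WL requirement
        sweep = np.linspace(0.08, 0.27, 400)
        values = [electrons_h2(r, DEFAULT_PARAMS.at_membrane_potential(du)).nu_e
                  for du in sweep]
        assert len(set(values)) < 25
        v08 = electrons_h2(r, DEFAULT_PARAMS.at_membrane_potential(0.08)).nu_e
        v14 = electrons_h2(r, DEFAULT_PARAMS.at_membrane_potential(0.14)).nu_e
        v24 = electrons_h2(r, DEFAULT_PARAMS.at_membrane_potential(0.24)).nu_e
        assert min(v08, v24) <= v14 <= max(v08, v24)

    def test_fractional_requirements_not_rounded(self):
        out = electrons_h2(req(n=1, a=1))
        assert out.nu_e % 1 != 0  # 2.5 — sub-integer widths must survive


def test_default_potential_ordering():
    p = DEFAULT_PARAMS
    assert p.u_acceptor > p.u_q > p.u_nadh
    with pytest.raises(ValueError):
        ElectronTransportParams(u_q=-0.5).validate()
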