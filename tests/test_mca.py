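"""Flux control coefficients: oracles, summation theorem, Monte Carlo."""

import numpy as np
import pytest

from atpwaste.mca import (
    compute_fccs,
    fcc_finite_difference,
    predict_enzyme_doubling,
    sample_preserving_steady_state,
    sign_dominance,
)
from atpwaste.model_core import build_model
from atpwaste.simulate import integrate_to_steady_state


def _chain_config(kms, vmaxes):
    """Linear chain SRC -> A -> B ... -> SINK with MM steps."""
    n = len(vmaxes)
    species = [{"id": "SRC", "concentration": 100.0, "is_boundary": True},
               {"id": "SINK", "concentration": 0.0, "is_boundary": True}]
    inner = [f"M{i}" for i in range(n - 1)]
    species += [{"id": m, "concentration": 1.0} for m in inner]
    chain = ["SRC"] + inner + ["SINK"]
    reactions, params = [], {}
    for i in range(n):
        rid = f"R{i}"
        reactions.append({
            "id": rid,
            "stoichiometry": {chain[i]: -1, chain[i + 1]: 1},
        })
        params[rid] = {"vmax": vmaxes[i], "km": {chain[i]: kms[i]}}
    return {"species": species, "reactions": reactions,
            "parameters": params}


def test_saturated_first_step_has_full_control():
    """Classic limit: a saturated committed step carries all control."""
    model = build_model(_chain_config(kms=[1e-4, 1.0], vmaxes=[1.0, 4.0]))
    state = integrate_to_steady_state(model, x0=np.array([0.5]))
    assert state.converged
    fcc = compute_fccs(model, state)
    assert fcc.get("R1", "R0") == pytest.approx(1.0, abs=1e-3)
    assert fcc.get("R1", "R1") == pytest.approx(0.0, abs=1e-3)


def test_matrix_method_matches_finite_difference_oracle():
    rng = np.random.default_rng(5)
    model = build_model(_chain_config(
        kms=list(rng.uniform(0.5, 3.0, 3)),
        vmaxes=[2.0, 3.5, 5.0],
    ))
    state = integrate_to_steady_state(model, x0=np.array([1.0, 1.0]))
    assert state.converged
    fcc = compute_fccs(model, state)
    for enzyme in model.reaction_ids:
        brute = fcc_finite_difference(model, state, "R2", enzyme)
        assert fcc.get("R2", enzyme) == pytest.approx(brute, abs=1e-3)


def test_full_model_matrix_vs_finite_difference(model_v1, wt_state_v1):
    m = model_v1.copy()
    m.vmax_atpase = 0.0
    fcc = compute_fccs(m, wt_state_v1)
    for enzyme in ("NGAM", "PFK", "PTS"):
        brute = fcc_finite_difference(m, wt_state_v1, "PTS", enzyme)
        assert fcc.get("PTS", enzyme) == pytest.approx(brute, abs=1e-3)


def test_summation_theorem_at_wild_type(model_v1, wt_state_v1):
    m = model_v1.copy()
    m.vmax_atpase = 0.0
    sums = compute_fccs(m, wt_state_v1).row_sums()
    checked = 0
    for s in sums:
        if not np.isnan(s):
            assert s == pytest.approx(1.0, abs=1e-3)
            checked += 1
    assert checked >= 25


class TestSampling:
    def test_degenerate_range_reproduces_base_fccs(self, model_v1,
                                                   wt_state_v1):
        m = model_v1.copy()
        m.vmax_atpase = 0.0
        base = compute_fccs(m, wt_state_v1)
        s = sample_preserving_steady_state(m, wt_state_v1, n=1, seed=3,
                                           range_decades=0.0)
        assert np.allclose(s.samples[0].matrix, base.matrix,
                           equal_nan=True, atol=1e-9)

    def test_reproducible_under_seed(self, model_v1, wt_state_v1):
        m = model_v1.copy()
        m.vmax_atpase = 0.0
        a = sample_preserving_steady_state(m, wt_state_v1, n=5, seed=7)
        b = sample_preserving_steady_state(m, wt_state_v1, n=5, seed=7)
        for sa, sb in zip(a.samples, b.samples):
            assert np.array_equal(sa.matrix, sb.matrix, equal_nan=True)

    def test_samples_preserve_reference_and_sum_to_one(self, wt_samples_v1):
        # construction guarantees the reference fluxes; the summation
        # theorem must additionally hold in every sample
        for fcc in wt_samples_v1.samples[:50]:
            sums = fcc.row_sums()
            finite = sums[~np.isnan(sums)]
            assert np.allclose(finite, 1.0, atol=1e-3)

    def test_inconsistent_reference_rejected(self, model_v1, wt_state_v1):
        m = model_v1.copy()
        m.vmax_atpase = 5.0  # does not match the vmax=0 reference state
        with pytest.raises(ValueError, match="vmax_atpase"):
            sample_preserving_steady_state(m, wt_state_v1, n=1, seed=1)


def test_sign_dominance_all_positive_toy():
    class Fake:
        def sign_fraction(self, flux, enzyme, sign=+1):
            return 1.0 if sign >= 0 else 0.0

    assert sign_dominance(Fake(), "J", "E") == 1.0


def test_wild_type_demand_control_predominantly_positive(wt_samples_v1):
    """Higher maintenance demand raises uptake in almost all samples."""
    assert sign_dominance(wt_samples_v1, "PTS", "NGAM") > 0.95


def test_high_demand_state_control_signs(hc_samples_v2):
    for enzyme in ("PYK", "PFL", "PFK"):
        assert sign_dominance(hc_samples_v2, "PTS", enzyme) > 0.5, enzyme
    for enzyme in ("NGAM", "ATPASE"):
        assert sign_dominance(hc_samples_v2, "PTS", enzyme) < 0.5, enzyme


class TestEnzymeDoubling:
    def test_doubling_all_enzymes_doubles_all_fluxes(self, model_v1,
                                                     wt_state_v1):
        m = model_v1.copy()
        m.vmax_atpase = 0.0
        for params in m.parameters.values():
            params["vmax"] *= 2.0
        state = integrate_to_steady_state(m, x0=wt_state_v1.x,
                                          check_moieties=False)
        assert state.converged
        for rid, v in wt_state_v1.fluxes.items():
            assert state.fluxes[rid] == pytest.approx(2.0 * v, rel=1e-6,
                                                      abs=1e-9)
        for sid, c in wt_state_v1.concentrations.items():
            assert state.concentrations[sid] == pytest.approx(c, rel=1e-6)

    def test_bottleneck_doubling_raises_uptake(self, hc_reference_v2):
        ref_model, state, _ = hc_reference_v2
        out = predict_enzyme_doubling(ref_model, state,
                                      ["PFK", "PFL", "PGK", "ATPASE"])
        base = state.fluxes["PTS"]
        assert out["PFK"] > base
        assert out["PFL"] > base
        # PGK is near-equilibrium: negligible control
        assert abs(out["PGK"] - base) / base < 0.02
        # more ATPase does not buy more uptake on the declining branch
        assert out["ATPASE"] <= base
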