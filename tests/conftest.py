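import numpy as np
import pytest

from atpwaste.model_core import build_default_model
from atpwaste.simulate import integrate_to_steady_state, scan_atpase

SCAN_GRID = np.arange(0.0, 86.0, 1.0)


@pytest.fixture(scope="session")
def model_v1():
    return build_default_model("v1")


@pytest.fixture(scope="session")
def model_v2():
    return build_default_model("v2")


@pytest.fixture(scope="session")
def wt_state_v1(model_v1):
    m = model_v1.copy()
    m.vmax_atpase = 0.0
    state = integrate_to_steady_state(m)
    assert state.converged
    return state


@pytest.fixture(scope="session")
def scan_v1(model_v1):
    return scan_atpase(model_v1, SCAN_GRID)


@pytest.fixture(scope="session")
def scan_v1_clamped(model_v1):
    return scan_atpase(model_v1, SCAN_GRID, clamp_adp_activation=True)


@pytest.fixture(scope="session")
def hc_reference_v2(model_v2):
    from atpwaste.mca import reference_state

    ref_model, state, vmax = reference_state(model_v2, "HC")
    assert state.converged
    return ref_model, state, vmax


@pytest.fixture(scope="session")
def wt_samples_v1(model_v1, wt_state_v1):
    from atpwaste.mca import sample_preserving_steady_state

    m = model_v1.copy()
    m.vmax_atpase = 0.0
    return sample_preserving_steady_state(
        m, wt_state_v1, n=200, seed=1, reference_label="WT")


@pytest.fixture(scope="session")
def hc_samples_v2(hc_reference_v2):
    from atpwaste.mca import sample_preserving_steady_state

    ref_model, state, _ = hc_reference_v2
    return sample_preserving_steady_state(
        ref_model, state, n=200, seed=1, reference_label="HC")


@pytest.fixture
def toy_linear_config():
    """Constant influx -> A -> drain; closed-form steady state."""
    return {
        "species": [
            {"id": "SRC", "concentration": 1.0, "is_boundary": True},
            {"id": "A", "concentration": 1.0},
            {"id": "SINK", "concentration": 0.0, "is_boundary": True},
        ],
        "reactions": [
            {"id": "IN", "stoichiometry": {"SRC": -1, "A": 1},
             "rate_law": "convenience"},
            {"id": "OUT", "stoichiometry": {"A": -1, "SINK": 1},
             "rate_law": "mass_action"},
        ],
        "parameters": {
            "IN": {"vmax": 2.0},        # no Km: zero-order influx
            "OUT": {"k": 0.5},          # linear drain
        },
    }


@pytest.fixture
def toy_fermentation_factory():
    """Builder for a lumped-fermentation stoichiometric toy model."""
    import numpy as np
    from atpwaste.mfa import StoichModel

    def build(with_acetate=False, with_ethanol=False):
        mets = ["PYR", "ATP", "NADH"]
        cols = {"GLY": {"PYR": 2, "ATP": 2, "NADH": 2},
                "LDH": {"PYR": -1, "NADH": -1},
                "ATPM": {"ATP": -1}}
        measured = {"r_glc": "GLY", "r_lac": "LDH"}
        if with_acetate:
            cols["ACK"] = {"PYR": -1, "ATP": 1, "NADH": -1}
            measured["r_ace"] = "ACK"
        if with_ethanol:
            cols["ADH"] = {"PYR": -1, "NADH": -1}
            measured["r_eth"] = "ADH"
        rids = list(cols)
        S = np.zeros((len(mets), len(rids)))
        for j, rid in enumerate(rids):
            for m, coeff in cols[rid].items():
                S[mets.index(m), j] = coeff
        return StoichModel(
            matrix=S, metabolite_ids=mets, reaction_ids=rids,
            lb=np.zeros(len(rids)), ub=np.full(len(rids), 1e4),
            atpm_id="ATPM", measured=measured,
        )

    return build
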