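import numpy as np
import pytest

from rhizoflux import synth


@pytest.fixture
def chain3():
    """Exchange -> transport -> one gene-bearing step -> biomass; optimum 10."""
    return synth.make_chain_model(n_steps=1, uptake_bound=10.0)


@pytest.fixture
def branched():
    return synth.make_branched_model(uptake_bound=10.0)


@pytest.fixture
def branched_dead_end():
    return synth.make_branched_model(uptake_bound=10.0, dead_end_branch=True)


@pytest.fixture
def branched_half_capacity():
    return synth.make_branched_model(uptake_bound=10.0, branch_capacity=(5.0, 5.0))


@pytest.fixture
def isozyme():
    return synth.make_isozyme_model()


@pytest.fixture
def symbiosis():
    return synth.make_symbiosis_toy()


def fba_oracle(model, objective_id=None, sense="max"):
    """LP optimum by exhaustive vertex enumeration (independent of HiGHS)."""
    from rhizoflux.bruteforce import vertex_optimum

    S, _, rxn_ids = model.stoichiometric_matrix()
    lb, ub = model.bounds_arrays()
    c = np.zeros(len(rxn_ids))
    c[rxn_ids.index(objective_id or model.objective_id)] = 1.0
    value, vertex = vertex_optimum(S, lb, ub, c, sense=sense)
    return value, dict(zip(rxn_ids, vertex))


def moma_oracle(model, reference_flux):
    """MOMA by scipy trust-constr: independent of the OSQP path."""
    from scipy.optimize import Bounds, LinearConstraint, minimize

    S, _, rxn_ids = model.stoichiometric_matrix()
    S = S.toarray()
    lb, ub = model.bounds_arrays()
    v_ref = np.array([reference_flux.get(r, 0.0) for r in rxn_ids])
    x0 = np.clip(np.zeros(len(rxn_ids)), lb, ub)
    res = minimize(
        lambda v: np.sum((v - v_ref) ** 2),
        x0,
        jac=lambda v: 2 * (v - v_ref),
        method="trust-constr",
        constraints=[LinearConstraint(S, 0.0, 0.0)],
        bounds=Bounds(lb, ub),
        options={"gtol": 1e-12, "xtol": 1e-14, "maxiter": 5000},
    )
    return float(res.fun), dict(zip(rxn_ids, res.x))
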