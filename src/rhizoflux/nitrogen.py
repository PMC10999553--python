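"""Nitrogen-fixation module analysis and MOMA overexpression scan.

In a symbiotically conditioned model, nitrogenase (EC 1.18.6.1) reduces
N2 to ammonia using reduced ferredoxin as electron donor, so the
ferredoxin-regenerating reactions partition the network into candidate
nitrogen-fixation modules. Two analyses are provided:

* knock out each module's ferredoxin-producing reaction and report how
  cofactor turnover (NADH/NADPH, ATP), symbiotic production and the
  nitrogen-fixation flux respond;
* cap the fixed-NH3 exchange at a token rate, then for each candidate
  reaction force its flux up to its attainable maximum (overexpression),
  release the cap and solve MOMA against the wild-type reference to see
  whether fixed-NH3 output rises.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import yaml

from .lp import fba, fva, moma, production_rate
from .model import DEFAULT_BOUND, MetabolicModel

__all__ = [
    "ModuleReport",
    "TargetReport",
    "module_knockout_report",
    "overexpression_scan",
]


@dataclass
class ModuleReport:
    module: str
    knocked_reaction_id: str
    nadh_nadph_production: float
    atp_production: float
    symbiotic_production: float
    nitrogen_fixation: float


@dataclass
class TargetReport:
    reaction_id: str
    enzyme_name: str
    ec_number: str
    module: str
    fixed_nh3_rate: float
    symbiotic_rate: float
    wild_type_fixed_nh3: float
    wild_type_symbiotic: float


def _rates(model, solution, nfix_reaction_id, objective_id, cofactor_pools):
    nadh = production_rate(model, solution, cofactor_pools["nadh_nadph"])
    atp = production_rate(model, solution, cofactor_pools["atp"])
    sym = max(0.0, solution.fluxes.get(objective_id, 0.0))
    nfix = max(0.0, solution.fluxes.get(nfix_reaction_id, 0.0))
    return nadh, atp, sym, nfix


def module_knockout_report(
    model: MetabolicModel,
    module_map: Mapping[str, str],
    nfix_reaction_id: str,
    cofactor_pools: Mapping[str, Sequence[str]],
    objective_id: str | None = None,
) -> list[ModuleReport]:
    """Knock out each module's reaction and re-run symbiotic FBA.

    ``module_map`` maps reaction id -> module label (the ferredoxin
    producers); ``cofactor_pools`` must name the metabolite pools
    "nadh_nadph" and "atp". An infeasible or zero-growth knockout
    reports all rates as 0.
    """
    objective_id = objective_id or model.objective_id
    missing = set(module_map) - set(model.reactions)
    if missing:
        raise KeyError(f"module reactions not in model: {sorted(missing)}")
    if nfix_reaction_id not in model.reactions:
        raise KeyError(f"nitrogen-fixation reaction {nfix_reaction_id!r} not in model")
    reports = []
    for rid, module in module_map.items():
        mutant = model.copy()
        mutant.reactions[rid].lower_bound = 0.0
        mutant.reactions[rid].upper_bound = 0.0
        sol = fba(mutant, objective_id)
        if sol.ok:
            nadh, atp, sym, nfix = _rates(
                mutant, sol, nfix_reaction_id, objective_id, cofactor_pools
            )
        else:
            nadh = atp = sym = nfix = 0.0
        reports.append(ModuleReport(module, rid, nadh, atp, sym, nfix))
    return reports


def overexpression_scan(
    model: MetabolicModel,
    candidates: Sequence[str],
    nfix_exchange_id: str,
    nfix_cap: float = 0.001,
    boost_factor: float = 1.0,
    objective_id: str | None = None,
    candidate_info: Mapping[str, Mapping[str, str]] | None = None,
) -> list[TargetReport]:
    """Scan candidate reactions for fixed-NH3 enhancement under MOMA.

    Wild type: the fixed-NH3 exchange upper bound is capped at
    ``nfix_cap`` and FBA on the symbiotic objective provides the MOMA
    reference. Per candidate: the cap is released, the candidate's lower
    bound is raised to ``boost_factor`` x its wild-type FVA maximum
    (forced overexpression), and MOMA finds the flux state closest to
    the reference. An infeasible boost collapses the network and is
    reported as all-zero rates.
    """
    objective_id = objective_id or model.objective_id
    missing = set(candidates) - set(model.reactions)
    if missing:
        raise KeyError(f"candidate reactions not in model: {sorted(missing)}")
    if nfix_exchange_id not in model.reactions:
        raise KeyError(f"fixed-NH3 exchange {nfix_exchange_id!r} not in model")
    info = candidate_info or {}

    wild = model.copy()
    wild.reactions[nfix_exchange_id].upper_bound = float(nfix_cap)
    wt_sol = fba(wild, objective_id)
    if not wt_sol.ok:
        raise RuntimeError(f"capped wild-type FBA is {wt_sol.status}")
    wt_nh3 = wt_sol.fluxes.get(nfix_exchange_id, 0.0)
    wt_sym = wt_sol.fluxes.get(objective_id, 0.0)

    # attainable maxima measured on the capped wild type, cap released for
    # the boost itself so overexpression is not throttled by the token cap
    probe = model.copy()
    probe.reactions[nfix_exchange_id].upper_bound = DEFAULT_BOUND
    fva_max = {
        rid: fva(probe, fraction_of_optimum=0.0, reaction_ids=[rid]).ranges[rid][1]
        for rid in candidates
    }

    reports = []
    for rid in candidates:
        boosted = model.copy()
        boosted.reactions[nfix_exchange_id].upper_bound = DEFAULT_BOUND
        target_flux = boost_factor * fva_max[rid]
        rxn = boosted.reactions[rid]
        rxn.lower_bound = max(rxn.lower_bound, target_flux)
        if rxn.upper_bound < rxn.lower_bound:
            rxn.upper_bound = rxn.lower_bound
        sol = moma(boosted, wt_sol.fluxes)
        if sol.ok:
            nh3 = max(0.0, sol.fluxes.get(nfix_exchange_id, 0.0))
            sym = max(0.0, sol.fluxes.get(objective_id, 0.0))
        else:  # network collapse under the forced flux
            nh3 = sym = 0.0
        meta = info.get(rid, {})
        reports.append(
            TargetReport(
                reaction_id=rid,
                enzyme_name=meta.get("enzyme", ""),
                ec_number=meta.get("ec", ""),
                module=meta.get("module", ""),
                fixed_nh3_rate=nh3,
                symbiotic_rate=sym,
                wild_type_fixed_nh3=wt_nh3,
                wild_type_symbiotic=wt_sym,
            )
        )
    return reports


def load_nitrogen_config(path) -> dict:
    """YAML config: objective/nitrogenase/fixed-NH3 ids, module map, pools."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    required = {"objective_id", "nitrogenase_id", "fixed_nh3_exchange_id", "modules"}
    missing = required - set(cfg)
    if missing:
        raise ValueError(f"nitrogen config missing keys: {sorted(missing)}")
    return cfg
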