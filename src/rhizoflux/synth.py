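"""Synthetic toy networks with planted, independently verified ground truth.

Each generator returns ``(model, truth)`` where ``truth`` is a plain
dict of planted facts (optimum, essential sets, blocked sets, ...)
computed from the construction itself and re-verified at generation
time with the brute-force routines in :mod:`rhizoflux.bruteforce` - so
nothing downstream has to trust the LP engine being tested. Generators
are deterministic under a fixed seed.

The fixtures mirror, at miniature scale, the situations a rhizobial
genome-scale model presents: linear catabolic chains, isozyme
redundancy, dead-end branches, and a symbiotic nitrogen-fixation core
(dicarboxylate feed, ATP/NADH pools, ferredoxin cycle, nitrogenase,
fixed-NH3 export coupled to a symbiotic product drain).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from . import bruteforce
from .eflux import ExpressionProfile, HomologMap
from .model import MediaCondition, Metabolite, MetabolicModel, Reaction

__all__ = [
    "make_chain_model",
    "make_branched_model",
    "make_isozyme_model",
    "make_symbiosis_toy",
    "make_expression_profile",
    "make_homolog_map",
    "make_phenotype_plate",
    "write_fixture",
]


def _verify_optimum(model: MetabolicModel, expected: float, tol: float = 1e-6) -> None:
    S, _, rxn_ids = model.stoichiometric_matrix()
    lb, ub = model.bounds_arrays()
    c = np.zeros(len(rxn_ids))
    c[rxn_ids.index(model.objective_id)] = 1.0
    value, _ = bruteforce.vertex_optimum(S, lb, ub, c, sense="max")
    if abs(value - expected) > tol:
        raise AssertionError(
            f"planted optimum {expected} disagrees with vertex oracle {value}"
        )


def make_chain_model(
    n_steps: int = 1, uptake_bound: float = 10.0
) -> tuple[MetabolicModel, dict]:
    """Linear chain: exchange -> transport -> n enzymatic steps -> biomass.

    Each enzymatic step carries one gene, so every internal reaction and
    every gene is essential and the FBA optimum equals the uptake bound.
    ``n_steps=1`` is the canonical "chain3" fixture (3 metabolites,
    4 reactions, 1 gene).
    """
    if n_steps < 1:
        raise ValueError("n_steps must be >= 1")
    model = MetabolicModel(name=f"chain_{n_steps}")
    model.add_metabolite(Metabolite("A_e", "substrate (external)", compartment="e"))
    model.add_metabolite(Metabolite("A_c", "substrate", compartment="c"))
    names = ["A_c"] + [f"M{i}_c" for i in range(1, n_steps + 1)]
    for mid in names[1:]:
        model.add_metabolite(Metabolite(mid, compartment="c"))
    model.add_reaction(
        Reaction("EX_A", "substrate exchange", {"A_e": -1.0},
                 lower_bound=-uptake_bound, upper_bound=1000.0,
                 reaction_class="exchange")
    )
    model.add_reaction(
        Reaction("T_A", "substrate transport", {"A_e": -1.0, "A_c": 1.0},
                 lower_bound=0.0, reaction_class="transport")
    )
    genes = []
    for i in range(1, n_steps + 1):
        gene = f"g{i}"
        genes.append(gene)
        model.add_reaction(
            Reaction(f"R{i}", f"step {i}", {names[i - 1]: -1.0, names[i]: 1.0},
                     lower_bound=0.0, gpr=gene, reaction_class="enzymatic")
        )
    model.add_reaction(
        Reaction("BIO", "biomass drain", {names[-1]: -1.0},
                 lower_bound=0.0, reaction_class="biomass")
    )
    model.objective_id = "BIO"
    model.validate()
    truth = {
        "optimum": float(uptake_bound),
        "essential_genes": genes,
        "neutral_genes": [],
        "essential_reactions": ["EX_A", "T_A", *(f"R{i}" for i in range(1, n_steps + 1)), "BIO"],
        "blocked_reactions": [],
    }
    _verify_optimum(model, truth["optimum"])
    return model, truth


def make_branched_model(
    uptake_bound: float = 10.0,
    branch_capacity: tuple[float, float] = (1000.0, 1000.0),
    dead_end_branch: bool = False,
) -> tuple[MetabolicModel, dict]:
    """Two parallel branches from one feed, optional dead-end side branch.

    With equal unlimited branches the optimum is the uptake bound and
    either branch alone can carry it; with capacities (5, 5) and uptake
    10, deleting one branch halves growth. The dead-end branch R4 feeds
    a metabolite nothing consumes, so R4 can never carry steady-state
    flux (planted blocked set).
    """
    model = MetabolicModel(name="branched")
    for mid, comp in [("A_e", "e"), ("A_c", "c"), ("B_c", "c"), ("C_c", "c")]:
        model.add_metabolite(Metabolite(mid, compartment=comp))
    model.add_reaction(
        Reaction("EX_A", "feed exchange", {"A_e": -1.0},
                 lower_bound=-uptake_bound, upper_bound=1000.0,
                 reaction_class="exchange")
    )
    model.add_reaction(
        Reaction("T_A", "feed transport", {"A_e": -1.0, "A_c": 1.0},
                 lower_bound=0.0, reaction_class="transport")
    )
    cap1, cap2 = branch_capacity
    model.add_reaction(
        Reaction("R1", "branch 1", {"A_c": -1.0, "B_c": 1.0},
                 lower_bound=0.0, upper_bound=cap1, gpr="g1")
    )
    model.add_reaction(
        Reaction("R2", "branch 2", {"A_c": -1.0, "B_c": 1.0},
                 lower_bound=0.0, upper_bound=cap2, gpr="g2")
    )
    model.add_reaction(
        Reaction("R3", "downstream step", {"B_c": -1.0, "C_c": 1.0},
                 lower_bound=0.0, gpr="g3")
    )
    model.add_reaction(
        Reaction("BIO", "biomass drain", {"C_c": -1.0},
                 lower_bound=0.0, reaction_class="biomass")
    )
    blocked = []
    if dead_end_branch:
        model.add_metabolite(Metabolite("D_c", compartment="c"))
        model.add_reaction(
            Reaction("R4", "dead-end branch", {"A_c": -1.0, "D_c": 1.0},
                     lower_bound=0.0, gpr="g4")
        )
        blocked = ["R4"]
    model.objective_id = "BIO"
    model.validate()
    optimum = min(uptake_bound, cap1 + cap2)
    truth = {
        "optimum": float(optimum),
        "blocked_reactions": blocked,
        "branch_ids": ["R1", "R2"],
    }
    _verify_optimum(model, truth["optimum"])
    return model, truth


def make_isozyme_model(uptake_bound: float = 10.0) -> tuple[MetabolicModel, dict]:
    """Chain with one isozyme step ("g1 or g2") and one complex ("g3 and g4").

    Planted essentiality: either isozyme alone is dispensable, either
    complex subunit is essential; both catalysed steps are essential as
    reactions.
    """
    model = MetabolicModel(name="isozyme")
    for mid, comp in [("A_e", "e"), ("A_c", "c"), ("B_c", "c"), ("C_c", "c")]:
        model.add_metabolite(Metabolite(mid, compartment=comp))
    model.add_reaction(
        Reaction("EX_A", "feed exchange", {"A_e": -1.0},
                 lower_bound=-uptake_bound, upper_bound=1000.0,
                 reaction_class="exchange")
    )
    model.add_reaction(
        Reaction("T_A", "feed transport", {"A_e": -1.0, "A_c": 1.0},
                 lower_bound=0.0, reaction_class="transport")
    )
    model.add_reaction(
        Reaction("S1", "isozyme step", {"A_c": -1.0, "B_c": 1.0},
                 lower_bound=0.0, gpr="g1 or g2")
    )
    model.add_reaction(
        Reaction("S2", "complex step", {"B_c": -1.0, "C_c": 1.0},
                 lower_bound=0.0, gpr="g3 and g4")
    )
    model.add_reaction(
        Reaction("BIO", "biomass drain", {"C_c": -1.0},
                 lower_bound=0.0, reaction_class="biomass")
    )
    model.objective_id = "BIO"
    model.validate()
    truth = {
        "optimum": float(uptake_bound),
        "essential_genes": ["g3", "g4"],
        "neutral_genes": ["g1", "g2"],
        "essential_reactions": ["EX_A", "T_A", "S1", "S2", "BIO"],
        "blocked_reactions": [],
    }
    _verify_optimum(model, truth["optimum"])
    return model, truth


def make_symbiosis_toy(
    dicarboxylate_uptake: float = 1.38,
    redundant_fdx_source: bool = True,
) -> tuple[MetabolicModel, dict]:
    """Miniature symbiotic nitrogen-fixation network.

    Succinate feeds catabolism (``succ -> 2.5 atp + nadh``); ferredoxin
    reductases regenerate reduced ferredoxin from NADH (two isoforms,
    one redundant); nitrogenase burns 2 fdxrd + 4 atp per NH3; the
    symbiotic pseudo-reaction drains 1 atp + 1 nadh + 1 nh3 per unit of
    product and hands one unit of fixed NH3 to the host, which must
    leave through the fixed-NH3 exchange - so capping that exchange caps
    symbiosis, as in the genome-scale model. A disconnected import/drain
    side branch (W) is included as a negative control for target scans.

    Yield arithmetic: one unit of symbiotic product costs 5 atp and
    2 nadh, i.e. exactly 2 succinate, so the planted optimum is
    ``uptake / 2``.
    """
    model = MetabolicModel(name="symbiosis_toy")
    mets = [
        ("succ_e", "e"), ("succ_c", "c"), ("atp_c", "c"), ("nadh_c", "c"),
        ("fdxrd_c", "c"), ("fdxox_c", "c"), ("nh3_c", "c"), ("nh3_e", "e"),
        ("sym_c", "c"), ("w_e", "e"), ("w_c", "c"),
    ]
    for mid, comp in mets:
        model.add_metabolite(Metabolite(mid, compartment=comp))

    model.add_reaction(
        Reaction("EX_succ", "succinate exchange", {"succ_e": -1.0},
                 lower_bound=-dicarboxylate_uptake, upper_bound=1000.0,
                 reaction_class="exchange")
    )
    model.add_reaction(
        Reaction("T_succ", "succinate transport", {"succ_e": -1.0, "succ_c": 1.0},
                 lower_bound=0.0, gpr="gt", reaction_class="transport")
    )
    model.add_reaction(
        Reaction("CAT", "dicarboxylate catabolism",
                 {"succ_c": -1.0, "atp_c": 2.5, "nadh_c": 1.0},
                 lower_bound=0.0, gpr="gc")
    )
    model.add_reaction(
        Reaction("FDX1", "ferredoxin reductase 1",
                 {"nadh_c": -1.0, "fdxox_c": -2.0, "fdxrd_c": 2.0},
                 lower_bound=0.0, gpr="gf1")
    )
    if redundant_fdx_source:
        model.add_reaction(
            Reaction("FDX2", "ferredoxin reductase 2",
                     {"nadh_c": -1.0, "fdxox_c": -2.0, "fdxrd_c": 2.0},
                     lower_bound=0.0, gpr="gf2")
        )
    model.add_reaction(
        Reaction("NIT", "nitrogenase",
                 {"fdxrd_c": -2.0, "atp_c": -4.0, "fdxox_c": 2.0, "nh3_c": 1.0},
                 lower_bound=0.0, gpr="gn")
    )
    model.add_reaction(
        Reaction("SYM", "symbiotic product synthesis",
                 {"atp_c": -1.0, "nadh_c": -1.0, "nh3_c": -1.0,
                  "sym_c": 1.0, "nh3_e": 1.0},
                 lower_bound=0.0, reaction_class="biomass")
    )
    model.add_reaction(
        Reaction("SK_sym", "symbiotic product sink", {"sym_c": -1.0},
                 lower_bound=0.0, reaction_class="sink")
    )
    model.add_reaction(
        Reaction("EX_NH3", "fixed NH3 exchange", {"nh3_e": -1.0},
                 lower_bound=0.0, upper_bound=1000.0, reaction_class="exchange")
    )
    model.add_reaction(
        Reaction("EX_W", "control nutrient exchange", {"w_e": -1.0},
                 lower_bound=-1.0, upper_bound=1000.0, reaction_class="exchange")
    )
    model.add_reaction(
        Reaction("T_W", "control transport", {"w_e": -1.0, "w_c": 1.0},
                 lower_bound=0.0, gpr="gw", reaction_class="transport")
    )
    model.add_reaction(
        Reaction("DM_W", "control drain", {"w_c": -1.0},
                 lower_bound=0.0, reaction_class="demand")
    )
    model.objective_id = "SYM"
    model.validate()

    optimum = dicarboxylate_uptake / 2.0
    truth = {
        "optimum": float(optimum),
        "nitrogen_fixation_at_optimum": float(optimum),
        "fixed_nh3_export_at_optimum": float(optimum),
        "nfix_exchange_id": "EX_NH3",
        "nitrogenase_id": "NIT",
        "fdx_sources": ["FDX1"] + (["FDX2"] if redundant_fdx_source else []),
        "control_reaction": "T_W",
        "cofactor_pools": {"nadh_nadph": ["nadh_c"], "atp": ["atp_c"]},
        "atp_gross_production_at_optimum": float(2.5 * dicarboxylate_uptake),
        "nadh_gross_production_at_optimum": float(dicarboxylate_uptake),
        "capped_optimum": 0.001,  # with EX_NH3 ub = 0.001 the cap binds
    }
    _verify_optimum(model, truth["optimum"])
    return model, truth


def make_expression_profile(
    model: MetabolicModel,
    rule: str = "uniform",
    gene: str | None = None,
    fraction: float = 0.5,
    seed: int = 0,
    base: float = 10.0,
) -> ExpressionProfile:
    """Expression profiles emulating averaged peptide counts.

    Rules: ``uniform`` (every gene at ``base``), ``single_limited``
    (every gene at ``base`` except ``gene`` at ``fraction * base``,
    planting a known rate-limiting step), ``random`` (Poisson counts
    with mean ``base``, seeded).
    """
    genes = sorted(model.genes)
    if rule == "uniform":
        abundances = {g: base for g in genes}
    elif rule == "single_limited":
        if gene is None or gene not in model.genes:
            raise ValueError(f"single_limited needs a model gene, got {gene!r}")
        if not 0.0 <= fraction <= 1.0:
            raise ValueError("fraction must lie in [0, 1]")
        abundances = {g: base for g in genes}
        abundances[gene] = fraction * base
    elif rule == "random":
        rng = np.random.default_rng(seed)
        abundances = {g: float(rng.poisson(base)) for g in genes}
    else:
        raise ValueError(f"unknown rule {rule!r}")
    return ExpressionProfile(abundances, condition=rule)


def make_homolog_map(
    model: MetabolicModel,
    seed: int = 0,
    min_ratio: float = 90.0,
    fraction_below: float = 0.2,
) -> tuple[HomologMap, dict]:
    """Map a fictitious donor strain's genes onto the model's genes.

    Donor ids are the model genes prefixed ``donor_``; a seeded fraction
    of pairs gets a BBH ratio below threshold (planted drop set).
    """
    rng = np.random.default_rng(seed)
    genes = sorted(model.genes)
    pairs: dict[str, tuple[str, float]] = {}
    dropped = []
    for g in genes:
        if rng.random() < fraction_below:
            ratio = float(rng.uniform(50.0, min_ratio - 1.0))
            dropped.append(f"donor_{g}")
        else:
            ratio = float(rng.uniform(min_ratio, 100.0))
        pairs[f"donor_{g}"] = (g, round(ratio, 2))
    truth = {"dropped_sources": sorted(dropped)}
    return HomologMap(pairs=pairs, min_ratio=min_ratio), truth


def make_phenotype_plate() -> tuple[MetabolicModel, MediaCondition, list, dict, dict]:
    """A toy plate: model, minimal medium, wells, substrate map, truth.

    Six substrates: four catabolisable (one observed "not-used" to plant
    a false positive), one orphan exchange (true negative), one absent
    from the model entirely (unmappable, counted inconsistent). Planted
    accuracy: 4 of 6.
    """
    model = MetabolicModel(name="plate_toy")
    model.add_metabolite(Metabolite("B_c", compartment="c"))
    model.add_reaction(
        Reaction("BIO", "biomass drain", {"B_c": -1.0},
                 lower_bound=0.0, reaction_class="biomass")
    )
    for i in range(1, 5):
        model.add_metabolite(Metabolite(f"C{i}_e", compartment="e"))
        model.add_metabolite(Metabolite(f"C{i}_c", compartment="c"))
        model.add_reaction(
            Reaction(f"EX_C{i}", f"substrate {i} exchange", {f"C{i}_e": -1.0},
                     lower_bound=0.0, upper_bound=1000.0, reaction_class="exchange")
        )
        model.add_reaction(
            Reaction(f"T_C{i}", f"substrate {i} transport",
                     {f"C{i}_e": -1.0, f"C{i}_c": 1.0}, lower_bound=0.0,
                     reaction_class="transport")
        )
        model.add_reaction(
            Reaction(f"R_C{i}", f"substrate {i} catabolism",
                     {f"C{i}_c": -1.0, "B_c": 1.0}, lower_bound=0.0,
                     gpr=f"gc{i}")
        )
    # orphan exchange: external metabolite that connects to nothing else
    model.add_metabolite(Metabolite("X_e", compartment="e"))
    model.add_reaction(
        Reaction("EX_X", "orphan exchange", {"X_e": -1.0},
                 lower_bound=0.0, upper_bound=1000.0, reaction_class="exchange")
    )
    model.objective_id = "BIO"
    model.validate()

    minimal_medium = MediaCondition(uptakes={}, label="minimal")
    plate = [
        ("substrate-1", "used"),
        ("substrate-2", "used"),
        ("substrate-3", "used"),
        ("substrate-4", "not-used"),  # model grows: planted false positive
        ("orphan-X", "not-used"),
        ("unknown-compound", "used"),  # absent from model: unmappable
    ]
    exchange_map = {
        "substrate-1": "EX_C1",
        "substrate-2": "EX_C2",
        "substrate-3": "EX_C3",
        "substrate-4": "EX_C4",
        "orphan-X": "EX_X",
    }
    # independent reachability check of the planted growth calls
    for i in range(1, 5):
        assert bruteforce.can_reach_reaction(model, {f"C{i}_e"}, "BIO")
    assert not bruteforce.can_reach_reaction(model, {"X_e"}, "BIO")
    truth = {
        "accuracy": 4 / 6,
        "tp": 3, "tn": 1, "fp": 1, "fn": 0, "unmappable": 1,
    }
    return model, minimal_medium, plate, exchange_map, truth


def write_fixture(model: MetabolicModel, truth: dict, directory, stem: str) -> tuple[Path, Path]:
    """Write a fixture as COBRA-JSON plus a sidecar ground-truth JSON."""
    from .io import write_json_model

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    model_path = directory / f"{stem}.json"
    truth_path = directory / f"{stem}.truth.json"
    write_json_model(model, model_path)
    with open(truth_path, "w") as fh:
        json.dump(truth, fh, indent=1, sort_keys=True)
    return model_path, truth_path
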