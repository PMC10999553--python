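"""Single-gene and single-reaction deletion screens.

A deletion is simulated by forcing to zero every reaction whose GPR rule
evaluates false without the gene (gene screen) or the reaction itself
(reaction screen), re-running FBA, and classifying by the mutant/wild-type
growth ratio: essential at ratio <= 0.05, growth-affecting below 1, and
neutral otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

from .lp import fba
from .model import MetabolicModel

__all__ = [
    "EssentialityRecord",
    "single_gene_deletion",
    "single_reaction_deletion",
]

#: Growth ratio at or below which an element is called essential.
ESSENTIALITY_THRESHOLD = 0.05
#: Ratios within this of 1 are numerically "no effect".
NEUTRAL_TOL = 1e-6


@dataclass
class EssentialityRecord:
    element_id: str
    wild_type_growth: float
    mutant_growth: float
    ratio: float
    label: str  # essential | growth_affecting | neutral

    @property
    def is_essential(self) -> bool:
        return self.label == "essential"


def _classify(ratio: float, threshold: float) -> str:
    if ratio <= threshold:
        return "essential"
    if ratio < 1.0 - NEUTRAL_TOL:
        return "growth_affecting"
    return "neutral"


def _wild_type_growth(model: MetabolicModel, objective_id: str | None) -> float:
    wt = fba(model, objective_id)
    if not wt.ok:
        raise RuntimeError(f"wild-type FBA is {wt.status}")
    if wt.objective_value <= 0:
        raise ValueError(
            "wild-type growth is zero; deletion ratios are undefined"
        )
    return wt.objective_value


def single_gene_deletion(
    model: MetabolicModel,
    genes: Iterable[str] | None = None,
    threshold: float = ESSENTIALITY_THRESHOLD,
    objective_id: str | None = None,
) -> list[EssentialityRecord]:
    """Screen genes one at a time for their effect on the objective.

    Reactions with an empty GPR are never disabled. A gene absent from
    every GPR is therefore always neutral.
    """
    wt_growth = _wild_type_growth(model, objective_id)
    targets = sorted(genes) if genes is not None else sorted(model.genes)
    records = []
    for gene in targets:
        affected = [
            rid
            for rid, rxn in model.reactions.items()
            if not rxn.gpr.is_empty
            and gene in rxn.gpr.genes()
            and not rxn.gpr.evaluate({gene})
        ]
        if not affected:
            records.append(
                EssentialityRecord(gene, wt_growth, wt_growth, 1.0, "neutral")
            )
            continue
        mutant = model.copy()
        for rid in affected:
            mutant.reactions[rid].lower_bound = 0.0
            mutant.reactions[rid].upper_bound = 0.0
        sol = fba(mutant, objective_id)
        growth = sol.objective_value if sol.ok else 0.0
        growth = 0.0 if growth <= 0 else growth
        ratio = growth / wt_growth
        records.append(
            EssentialityRecord(gene, wt_growth, growth, ratio, _classify(ratio, threshold))
        )
    return records


def single_reaction_deletion(
    model: MetabolicModel,
    reactions: Sequence[str] | None = None,
    threshold: float = ESSENTIALITY_THRESHOLD,
    objective_id: str | None = None,
) -> list[EssentialityRecord]:
    """Screen reactions one at a time (bounds pinned to zero)."""
    wt_growth = _wild_type_growth(model, objective_id)
    targets = list(reactions) if reactions is not None else list(model.reactions)
    unknown = set(targets) - set(model.reactions)
    if unknown:
        raise KeyError(f"unknown reactions {sorted(unknown)}")
    records = []
    for rid in targets:
        mutant = model.copy()
        mutant.reactions[rid].lower_bound = 0.0
        mutant.reactions[rid].upper_bound = 0.0
        sol = fba(mutant, objective_id)
        growth = sol.objective_value if sol.ok else 0.0
        growth = 0.0 if growth <= 0 else growth
        ratio = growth / wt_growth
        records.append(
            EssentialityRecord(rid, wt_growth, growth, ratio, _classify(ratio, threshold))
        )
    return records


def summarize(records: list[EssentialityRecord]) -> dict[str, int]:
    """Counts by label, plus 'affecting' = essential + growth_affecting."""
    counts = {"essential": 0, "growth_affecting": 0, "neutral": 0}
    for rec in records:
        counts[rec.label] += 1
    counts["affecting"] = counts["essential"] + counts["growth_affecting"]
    return counts
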