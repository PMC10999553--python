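"""E-Flux integration of protein abundance into flux bounds.

E-Flux narrows each reaction's flux bounds in proportion to the
expression of its catalysing genes, building a condition-specific model
from a reference network plus one proteome (or transcriptome) profile.
Expression is mapped through the GPR rule: an AND complex is limited by
its scarcest subunit (min), OR isozymes add capacity (sum).

The pipeline here first measures what each reaction can attain at all
(FVA at fraction 0 under the stated media), clamps those ranges so zero
flux stays attainable, then scales them by relative expression
``e / e_max`` where ``e_max`` is the largest reaction-level expression.
Reactions with no gene association keep their clamped ranges.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

from .gpr import GPRExpression, GPRLeaf, GPRNode
from .lp import fva
from .model import MediaCondition, MetabolicModel, apply_media

__all__ = [
    "UNCONSTRAINED",
    "ExpressionProfile",
    "HomologMap",
    "reaction_expression",
    "eflux_transform",
    "map_homologs",
    "read_expression_tsv",
    "read_homolog_tsv",
]

#: Sentinel: reaction has no usable expression signal, leave bounds alone.
UNCONSTRAINED = math.inf


@dataclass
class ExpressionProfile:
    """Gene id -> abundance (mean peptide count, dimensionless, >= 0)."""

    abundances: dict[str, float] = field(default_factory=dict)
    condition: str = ""

    def __post_init__(self):
        bad = {g: a for g, a in self.abundances.items() if a < 0}
        if bad:
            raise ValueError(f"negative abundances: {bad}")

    def get(self, gene: str, default: float = UNCONSTRAINED) -> float:
        return self.abundances.get(gene, default)

    def genes_not_in(self, model: MetabolicModel) -> set[str]:
        return set(self.abundances) - model.genes

    def scaled(self, factor: float) -> "ExpressionProfile":
        return ExpressionProfile(
            {g: a * factor for g, a in self.abundances.items()}, self.condition
        )


@dataclass
class HomologMap:
    """source gene -> (target gene, best-bidirectional-hit ratio in %)."""

    pairs: dict[str, tuple[str, float]] = field(default_factory=dict)
    min_ratio: float = 90.0


def reaction_expression(
    gpr: GPRExpression,
    profile: ExpressionProfile,
    or_rule: str = "sum",
    missing: float = UNCONSTRAINED,
) -> float:
    """Aggregate gene abundances into one reaction-level expression.

    AND -> min of children; OR -> sum (isozymes pool capacity) or max if
    ``or_rule="max"``. A gene absent from the profile contributes
    ``missing`` (default: the unconstrained sentinel, since peptide
    non-detection is not evidence of absence). An empty GPR returns the
    sentinel outright.
    """
    if gpr.is_empty:
        return UNCONSTRAINED

    def walk(node) -> float:
        if isinstance(node, GPRLeaf):
            return profile.get(node.gene, missing)
        assert isinstance(node, GPRNode)
        vals = [walk(c) for c in node.children]
        if node.op == "and":
            return min(vals)  # inf sentinel never undercuts a finite subunit
        # OR: one unmeasured isozyme means the capacity cannot be bounded
        if any(v == UNCONSTRAINED for v in vals):
            return UNCONSTRAINED
        return max(vals) if or_rule == "max" else sum(vals)

    return walk(gpr.root)


def eflux_transform(
    model: MetabolicModel,
    profile: ExpressionProfile,
    media: MediaCondition | None = None,
    or_rule: str = "sum",
    clamp_source: str = "fva",
) -> MetabolicModel:
    """Build a condition-specific model by E-Flux bound scaling.

    Steps: (1) apply the media; (2) take per-reaction attainable ranges
    from FVA at fraction 0 (``clamp_source="bounds"`` instead reuses the
    declared bounds); (3) clamp each range so 0 is attainable (a positive
    minimum drops to 0, a negative maximum rises to 0), which keeps the
    all-zero flux state feasible after any downscaling; (4) scale both
    ends by ``e / e_max`` for reactions with a finite expression ``e``.

    Raises if every reaction-level expression is zero (no scale).
    """
    conditioned = apply_media(model, media) if media is not None else model.copy()

    expr: dict[str, float] = {
        rid: reaction_expression(rxn.gpr, profile, or_rule=or_rule)
        for rid, rxn in conditioned.reactions.items()
    }
    finite = [e for e in expr.values() if e != UNCONSTRAINED]
    e_max = max(finite) if finite else 0.0
    if e_max <= 0:
        raise ValueError("all reaction-level expressions are zero; no E-Flux scale")

    if clamp_source == "fva":
        ranges = fva(conditioned, fraction_of_optimum=0.0).ranges
    elif clamp_source == "bounds":
        ranges = {
            rid: (rxn.lower_bound, rxn.upper_bound)
            for rid, rxn in conditioned.reactions.items()
        }
    else:
        raise ValueError(f"unknown clamp_source {clamp_source!r}")

    out = conditioned
    for rid, rxn in out.reactions.items():
        lo, hi = ranges[rid]
        lo, hi = min(lo, 0.0), max(hi, 0.0)  # keep zero attainable
        e = expr[rid]
        if e != UNCONSTRAINED:
            scale = e / e_max
            lo, hi = lo * scale, hi * scale
        rxn.lower_bound, rxn.upper_bound = lo, hi
    return out


def map_homologs(
    profile: ExpressionProfile, homologs: HomologMap
) -> tuple[ExpressionProfile, dict]:
    """Re-key a profile from source-strain genes to target-strain genes.

    Pairs below the map's minimum BBH ratio are dropped. When two sources
    map to the same target, the higher-ratio pair wins (the best matching
    outcome of the bidirectional comparison). Returns the mapped profile
    and a report: dropped_below_threshold, unmapped_sources,
    duplicate_losers.
    """
    best: dict[str, tuple[str, float]] = {}  # target -> (source, ratio)
    dropped, duplicates = [], []
    for source, (target, ratio) in homologs.pairs.items():
        if ratio < homologs.min_ratio:
            dropped.append(source)
            continue
        if target in best and best[target][1] >= ratio:
            duplicates.append(source)
            continue
        if target in best:
            duplicates.append(best[target][0])
        best[target] = (source, ratio)

    mapped, unmapped = {}, []
    usable_sources = {s for t, (s, r) in best.items()}
    for source, abundance in profile.abundances.items():
        if source in usable_sources:
            target = homologs.pairs[source][0]
            mapped[target] = abundance
        else:
            unmapped.append(source)
    report = {
        "dropped_below_threshold": sorted(dropped),
        "unmapped_sources": sorted(unmapped),
        "duplicate_losers": sorted(duplicates),
    }
    return ExpressionProfile(mapped, condition=profile.condition), report


# ---------------------------------------------------------------------------
# Tabular readers
# ---------------------------------------------------------------------------

def read_expression_tsv(path: str | Path, condition: str = "") -> ExpressionProfile:
    """Read gene expression TSV: gene_id + one or more abundance columns.

    Multiple numeric columns (replicates) are averaged on load.
    """
    import pandas as pd

    df = pd.read_csv(path, sep="\t", comment="#")
    gene_col = df.columns[0]
    values = df.drop(columns=[gene_col]).mean(axis=1, numeric_only=True)
    return ExpressionProfile(
        dict(zip(df[gene_col].astype(str), values.astype(float))), condition
    )


def read_homolog_tsv(path: str | Path, min_ratio: float = 90.0) -> HomologMap:
    """Read homolog map TSV: source_id, target_id, bbh_ratio."""
    import pandas as pd

    df = pd.read_csv(path, sep="\t", comment="#")
    pairs = {
        str(row[0]): (str(row[1]), float(row[2]))
        for row in df.itertuples(index=False)
    }
    return HomologMap(pairs=pairs, min_ratio=min_ratio)
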