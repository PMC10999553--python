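"""Sole-carbon-source growth prediction against a phenotype microarray.

Each plate well offers one carbon source as the only exogenous carbon
intake on an otherwise minimal medium (non-carbon nutrients open). The
model predicts growth when biomass FBA exceeds a small threshold; calls
are compared with the observed used/not-used truth table of a Biolog
GEN III plate. Substrates with no exchange reaction in the model are
"unmappable" and count as mismatches, since the plate did test them.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

from .lp import fba
from .model import MediaCondition, MetabolicModel, apply_media

__all__ = [
    "PhenotypeCall",
    "ConfusionSummary",
    "sole_source_growth",
    "call_plate",
    "plate_accuracy",
]

#: Biomass flux above this counts as growth; above LP noise, below any
#: biologically meaningful rate.
GROWTH_THRESHOLD = 1e-6
#: Default uptake allowance for the tested carbon source (mmol/gDW/h).
DEFAULT_UPTAKE = 10.0


@dataclass
class PhenotypeCall:
    carbon_source: str
    exchange_id: str  # or "absent-from-model"
    predicted: str  # growth | no-growth | unmappable
    observed: str  # used | not-used | untested

    @property
    def consistent(self) -> bool:
        if self.predicted == "unmappable":
            return False
        return (self.predicted == "growth") == (self.observed == "used")


@dataclass
class ConfusionSummary:
    tp: int
    tn: int
    fp: int
    fn: int
    unmappable: int

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn + self.unmappable

    @property
    def consistent(self) -> int:
        return self.tp + self.tn

    @property
    def accuracy(self) -> float:
        if self.total == 0:
            raise ValueError("no tested wells")
        return self.consistent / self.total


def sole_source_growth(
    model: MetabolicModel,
    minimal_medium: MediaCondition,
    carbon_exchange: str,
    uptake_rate: float = DEFAULT_UPTAKE,
    growth_threshold: float = GROWTH_THRESHOLD,
    objective_id: str | None = None,
) -> str:
    """Predict growth with one carbon source as sole exogenous intake.

    The minimal medium lists the non-carbon nutrients left open; every
    other exchange has uptake closed, then the tested exchange is opened
    to ``uptake_rate``.
    """
    if carbon_exchange not in model.reactions:
        raise KeyError(f"exchange {carbon_exchange!r} not in model")
    conditioned = apply_media(model, minimal_medium, close_others=True)
    conditioned.reactions[carbon_exchange].lower_bound = -float(uptake_rate)
    sol = fba(conditioned, objective_id)
    if sol.ok and sol.objective_value > growth_threshold:
        return "growth"
    return "no-growth"


def call_plate(
    model: MetabolicModel,
    minimal_medium: MediaCondition,
    plate: Sequence[tuple[str, str]],
    exchange_map: Mapping[str, str],
    uptake_rate: float = DEFAULT_UPTAKE,
    growth_threshold: float = GROWTH_THRESHOLD,
) -> list[PhenotypeCall]:
    """Predict every well of a plate.

    ``plate`` is (substrate_name, observed) with observed in
    {used, not-used}; ``exchange_map`` maps substrate names to exchange
    reaction ids. Substrates missing from the map, or mapped to an
    exchange absent from the model, are called unmappable.
    """
    calls = []
    for substrate, observed in plate:
        exchange_id = exchange_map.get(substrate)
        if exchange_id is None or exchange_id not in model.reactions:
            calls.append(
                PhenotypeCall(substrate, "absent-from-model", "unmappable", observed)
            )
            continue
        predicted = sole_source_growth(
            model, minimal_medium, exchange_id, uptake_rate, growth_threshold
        )
        calls.append(PhenotypeCall(substrate, exchange_id, predicted, observed))
    return calls


def plate_accuracy(calls: Sequence[PhenotypeCall]) -> ConfusionSummary:
    """Confusion counts and accuracy over all tested wells."""
    if not calls:
        raise ValueError("empty call list")
    tp = tn = fp = fn = unmappable = 0
    for call in calls:
        if call.observed not in {"used", "not-used"}:
            continue
        if call.predicted == "unmappable":
            unmappable += 1
        elif call.predicted == "growth" and call.observed == "used":
            tp += 1
        elif call.predicted == "no-growth" and call.observed == "not-used":
            tn += 1
        elif call.predicted == "growth":
            fp += 1
        else:
            fn += 1
    return ConfusionSummary(tp, tn, fp, fn, unmappable)


def read_plate_csv(path: str | Path) -> list[tuple[str, str]]:
    """Plate truth CSV: well, substrate_name, observed(0/1)."""
    import pandas as pd

    df = pd.read_csv(path, comment="#")
    return [
        (str(row.substrate_name), "used" if int(row.observed) else "not-used")
        for row in df.itertuples(index=False)
    ]


def read_exchange_map_tsv(path: str | Path) -> dict[str, str]:
    """Mapping TSV: substrate_name, exchange_id."""
    import pandas as pd

    df = pd.read_csv(path, sep="\t", comment="#")
    return dict(zip(df.iloc[:, 0].astype(str), df.iloc[:, 1].astype(str)))
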