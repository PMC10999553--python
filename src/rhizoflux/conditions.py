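"""Study growth conditions for *Sinorhizobium fredii* CCBAU45436.

Free-living cells are modelled on a defined medium (malate, succinate,
oxygen, glutamate, inositol); bacteroids in the nodule receive the host
dicarboxylates succinate and malate only. Rates are uptake magnitudes
in mmol/gDW/h, applied as negative exchange lower bounds.
"""

from __future__ import annotations

from .model import MediaCondition, MetabolicModel

__all__ = [
    "FREE_LIVING_UPTAKES",
    "SYMBIOTIC_UPTAKES",
    "find_exchange",
    "build_medium",
]

#: Defined free-living medium (compound -> uptake rate, mmol/gDW/h).
FREE_LIVING_UPTAKES: dict[str, float] = {
    "malate": 1.44,
    "succinate": 1.38,
    "oxygen": 1.26,
    "glutamate": 2.0,
    "inositol": 0.01,
}

#: Host-supplied dicarboxylates for the bacteroid (symbiotic) state.
SYMBIOTIC_UPTAKES: dict[str, float] = {
    "succinate": 1.38,
    "malate": 1.44,
}

#: ModelSEED compound ids, to match deposited models that key exchanges
#: by database id rather than by trivial name.
_COMPOUND_ALIASES: dict[str, tuple[str, ...]] = {
    "malate": ("malate", "l-malate", "cpd00130"),
    "succinate": ("succinate", "cpd00036"),
    "oxygen": ("oxygen", "o2", "cpd00007"),
    "glutamate": ("glutamate", "l-glutamate", "cpd00023"),
    "inositol": ("inositol", "myo-inositol", "cpd01171"),
}


def find_exchange(model: MetabolicModel, compound: str) -> str:
    """Locate the exchange reaction for a named compound.

    Matches the compound's known aliases (trivial names and ModelSEED
    ids) against the exchanged metabolite's id, name and annotations,
    case-insensitively. Raises KeyError when nothing matches.
    """
    aliases = _COMPOUND_ALIASES.get(compound.lower(), (compound.lower(),))
    for rxn in model.exchanges():
        (met_id,) = rxn.stoichiometry
        met = model.metabolites[met_id]
        haystack = [met.id.lower(), met.name.lower(), rxn.id.lower()]
        for values in met.annotation.values():
            if isinstance(values, (list, tuple)):
                haystack.extend(str(v).lower() for v in values)
            else:
                haystack.append(str(values).lower())
        for alias in aliases:
            if any(alias in item for item in haystack):
                return rxn.id
    raise KeyError(f"no exchange reaction found for {compound!r}")


def build_medium(
    model: MetabolicModel, uptakes: dict[str, float], label: str
) -> MediaCondition:
    """Resolve compound names to the model's exchange ids and build media."""
    resolved = {find_exchange(model, compound): rate
                for compound, rate in uptakes.items()}
    return MediaCondition(uptakes=resolved, label=label)
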