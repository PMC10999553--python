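"""Draft-model diagnostics: blocked reactions, duplicates, dead ends.

A curated network should have no reaction that can never carry flux and
no chemical species registered twice. This example plants both defects
and shows the diagnostics finding exactly them.
"""

from rhizoflux import (
    Metabolite,
    find_blocked_reactions,
    find_dead_ends,
    find_duplicate_metabolites,
    synth,
)

model, truth = synth.make_branched_model(10.0, dead_end_branch=True)
blocked = find_blocked_reactions(model)
print(f"blocked reactions (exchange/transport excluded): {blocked}")
print(f"  planted blocked set:                           {truth['blocked_reactions']}")
print(f"dead-end metabolites: {find_dead_ends(model)}")
print("R4 feeds D_c, which nothing consumes, so R4 can never run at steady state.")

model.add_metabolite(
    Metabolite("succ1_c", compartment="c", annotation={"seed.compound": "cpd00036"})
)
model.add_metabolite(
    Metabolite("succ2_c", compartment="c", annotation={"seed.compound": "cpd00036"})
)
groups = find_duplicate_metabolites(model)
print(f"\nduplicate metabolite groups: {groups}")
print("both carry the same ModelSEED id in the same compartment -> aliases.")
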