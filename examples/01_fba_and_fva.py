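"""Flux balance and flux variability analysis on a toy symbiotic network.

Builds the miniature bacteroid network (succinate feed, ferredoxin
cycle, nitrogenase, symbiotic product drain) and asks: how fast can the
cell make symbiotic product, and how much freedom does each reaction
have at that optimum?
"""

from rhizoflux import fba, fva, synth

model, truth = synth.make_symbiosis_toy()
solution = fba(model)

print(f"symbiotic production optimum: {solution.objective_value:.4f} mmol/gDW/h")
print(f"  (planted ground truth:      {truth['optimum']:.4f})")
print(f"fixed-NH3 export at optimum:  {solution.fluxes['EX_NH3']:.4f} mmol/gDW/h")

ranges = fva(model, fraction_of_optimum=1.0, reaction_ids=["FDX1", "FDX2", "NIT"])
print("\nflux ranges at 100% of the optimum (min, max):")
for rid, (lo, hi) in ranges.items():
    print(f"  {rid:6s} [{lo:7.4f}, {hi:7.4f}]")
print("\nFDX1 and FDX2 are redundant isoforms, so either can carry the whole")
print("ferredoxin flux (range 0..total) while nitrogenase is pinned.")
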