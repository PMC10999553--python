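# Methods

## Model representation and conventions

A model is a set of metabolites (id, formula, charge, compartment),
reactions (stoichiometry, bounds, GPR rule, subsystem, class) and genes,
with one objective reaction. Conventions follow the COBRA standard:
negative stoichiometric coefficients consume; exchange flux < 0 is
uptake; media are stated as positive uptake magnitudes and applied as
negative exchange lower bounds. Unbounded fluxes default to
±1000 mmol/gDW/h, irreversible reactions to a lower bound of 0. The
biomass pseudo-reaction is treated as having a molecular weight of
1 g/mmol, so its flux reads directly as a growth-rate-equivalent in 1/h
units and no rescaling is applied anywhere.

Reaction class (enzymatic, transport, exchange, demand, sink, biomass,
spontaneous) is resolved in a fixed precedence: explicit annotation,
then id prefix (`EX_`/`DM_`/`SK_`), then boundary structure
(single-metabolite reactions default to exchange), then the objective
flag. Deposited models vary widely in annotation completeness, which is
why the cascade exists; when a file disagrees with the inference, an
explicit `reaction_class` annotation wins.

GPR rules are parsed with a recursive-descent parser: case-insensitive
`and`/`or`, parentheses, AND binding tighter than OR. Malformed rules
raise with the character position. An empty rule means "no gene
dependency" and always evaluates active.

## LP/QP engines

FBA and FVA are solved with HiGHS through `scipy.optimize.linprog`
(feasibility/optimality tolerances 1e-9). FVA adds the optimality
constraint `c·v ≥ fraction · optimum` as a linear row; fraction 0 probes
pure feasibility, which is also the primitive behind blocked-reaction
detection and E-Flux range measurement. Degenerate optima are real: the
objective value is unique, the flux vector is not, so any comparison of
flux vectors in tests and reports goes through objective values or FVA
intervals, never a single arbitrary vertex.

MOMA is the strictly convex QP `min Σ (v − v_ref)²` under the perturbed
network's constraints, solved with OSQP (absolute/relative tolerance
1e-8, polishing on). The reference defaults to the wild-type FBA
solution; when that solution is degenerate the chosen vertex mildly
influences the MOMA distance, an acknowledged source of small
discrepancies in any MOMA-based analysis. The test suite cross-checks
the OSQP path against a `trust-constr` solve of the same QP.

Cofactor "production rate" for a metabolite pool (e.g. NADH+NADPH
across compartments) is defined as gross production at the reported
flux state: `Σ_r max(0, Σ_{m∈pool} S[m,r]·v_r)`. A balanced pool
accumulates nothing at steady state, so turnover is the only meaningful
single number; an alternative definition via a dedicated demand
reaction's flux is selectable (`mode="demand"`) because published
tables of such rates rarely state which convention they used, and the
two can differ.

## QC diagnostics

A reaction is blocked when FVA at fraction 0, with all exchange bounds
opened to ±1000, pins it to [0, 0] within 1e-9 (below solver
feasibility tolerance). Opening the exchanges makes the verdict a
property of network topology rather than of the current media, and
running at fraction 0 makes it objective-independent; both properties
are asserted in tests. Exchange and transport reactions are excluded
from the report by convention (configurable). Duplicate metabolites are
connected components of pairwise links: same compartment plus identical
non-empty formula+charge, or a shared KEGG/ModelSEED annotation.
Dead-end metabolites are those only produced or only consumed, with
reversible reactions counting on both sides.

## Essentiality

Gene deletion zeroes every reaction whose GPR evaluates false without
the gene; reaction deletion pins the reaction's bounds to zero. Ratios
are mutant/wild-type objective. Labels: essential at ratio ≤ 0.05
(the published convention this package follows), growth-affecting below
1 − 1e-6, neutral otherwise — so the essential set is a subset of the
growth-affecting-or-essential set and the two counts can be compared
directly with published "X affect growth, of which Y are essential"
statements. Wild-type growth of zero is an error (ratios undefined), not
a silent all-essential result. Reactions with empty GPRs are never
disabled by gene deletions. Screens default to the unconstrained
condition-specific model (media applied, no expression constraint); an
E-Flux-constrained screen is a caller choice, since published screens
do not always state which model they ran.

## E-Flux

Expression is aggregated over the GPR with AND → min (a complex is
limited by its scarcest subunit) and OR → sum (isozymes pool capacity;
OR → max selectable). A gene missing from the profile is treated as
unmeasured, not absent — peptide non-detection is weak evidence — so an
unmeasured AND partner cannot undercut a measured subunit and an
unmeasured OR isozyme leaves the reaction unconstrained; zeroing missing
genes would silence most of a genome-scale network. Reactions with no
finite expression keep their measured ranges.

The transform: apply media; measure attainable per-reaction ranges by
FVA at fraction 0 (clamping the declared bounds instead is available
behind `clamp_source="bounds"`, since either reading of the published
procedure is defensible — the FVA reading is the default because it
guarantees the ranges are jointly attainable); clamp each range so zero
stays inside it (positive minima drop to 0, negative maxima rise to 0),
which keeps the model feasible under any downscaling; scale both ends
by `e/e_max`, where `e_max` is the maximum reaction-level (not
gene-level) expression, because bounds are per-reaction quantities.
Consequences asserted as properties: bounds never widen, the transform
is invariant to rescaling the whole profile, and a planted rate-limiting
gene at fraction *f* yields exactly *f* × the unconstrained optimum.

Cross-strain profiles are re-keyed through a best-bidirectional-hit
homolog map: pairs below the 90% BBH ratio threshold are dropped, and
when two sources claim one target the higher-ratio pair wins; dropped,
unmapped and losing sources are reported, not silently discarded.

## Phenotype prediction

A well is simulated by closing uptake on every exchange except the
minimal medium's non-carbon nutrients, opening the tested carbon
exchange to 10 mmol/gDW/h, and calling growth when biomass FBA exceeds
1e-6 (above LP noise, below any biological rate). The minimal medium is
a caller-supplied `MediaCondition` because published "minimal medium"
compositions are rarely itemised; accuracy reproduction is sensitive to
it. Substrates that map to no exchange are "unmappable" and count as
inconsistent — the plate tested them, the model cannot. Accuracy is
(TP+TN)/total tested wells.

## Nitrogen-fixation targets

Module knockouts pin one ferredoxin-producing reaction to zero, re-run
symbiotic FBA, and report NADH/NADPH and ATP gross production plus the
symbiotic and nitrogenase fluxes; an infeasible knockout reports zeros.
The overexpression scan caps the fixed-NH3 exchange at a token
0.001 mmol/gDW/h to define a nitrogen-limited wild type whose FBA
solution is the MOMA reference, then per candidate releases the cap,
raises the candidate's lower bound to `boost_factor ×` its attainable
FVA maximum (measured with the cap released), and solves MOMA.
"Overexpression" as a forced lower bound at the attainable maximum is
an interpretive choice — the published procedure is stated loosely —
so the boost factor and cap are explicit parameters; a boost beyond
network capacity has no steady state and is reported as zero rates (the
collapsed case). Candidate ids, module labels and cofactor pools come
from a YAML config because deposited models key these reactions by
database ids that differ between models.

## Synthetic fixtures and what they do / don't show

Generators produce: linear chains (one gene per enzymatic step; optimum
= uptake bound; every internal reaction essential), branched networks
(parallel branches, optional capacity asymmetry and a dead-end branch as
the planted blocked set), an isozyme/complex fixture (planted neutral
and essential gene sets), and a symbiosis toy. The toy mirrors the
bacteroid economy: succinate at 1.38 mmol/gDW/h (the host-supplied
dicarboxylate rate used throughout), catabolism yielding 2.5 ATP + 1
NADH per succinate, two redundant ferredoxin reductases, a nitrogenase
burning 2 fdxrd + 4 ATP per NH3, and a symbiotic pseudo-reaction that
consumes 1 ATP + 1 NADH + 1 NH3 and obligately exports one NH3 to the
host per product unit — that coupling is what makes a cap on the
fixed-NH3 exchange bind the symbiotic optimum, the behaviour the target
scan depends on. Yield arithmetic gives the planted optimum uptake/2 =
0.69. Every planted optimum is re-verified at generation time by
exhaustive vertex enumeration, so a generator bug cannot silently
become the expected value of a test.

These fixtures establish correctness of the machinery, not biological
realism: they have exact integer-ish yields, no cofactor leaks, no
alternative optima beyond the planted redundancies, and peptide-count
profiles that are uniform or single-perturbed rather than heavy-tailed.
Passing on them says the algorithms compute what they claim; it does
not say a genome-scale model's predictions are right.

## Numerical choices

LP tolerances 1e-9; QP 1e-8; blocked-reaction tolerance 1e-9; growth
threshold 1e-6; neutrality tolerance 1e-6 on ratios. FVA min/max pairs
that cross by solver noise are collapsed to their midpoint. Ratios are
clamped at 0 (an infeasible mutant grows at 0, not at a tiny negative).
Vertex enumeration dedupes vertices at 1e-7 and is restricted by design
to fixture-sized networks. The test oracles (vertex enumeration, truth
tables, `trust-constr` MOMA, cobrapy/GLPK cross-checks) are independent
code paths from the engines under test.
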