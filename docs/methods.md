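# Methods

`bofsens` studies how the **biomass objective function** — the
pseudo-reaction whose flux is the predicted specific growth rate — shapes
the predictions of a constraint-based metabolic model. This note records
the models and procedures implemented, the choices that were genuinely
open, and what the synthetic test system does and does not show.

## Constraint-based model and FBA/FVA

A model is a stoichiometric matrix **S** (metabolites × reactions) with
flux bounds `lb ≤ v ≤ ub` (mmol/gCDW/hr). Flux balance analysis (FBA)
solves

```
max c·v   s.t.   S·v = 0,   lb ≤ v ≤ ub
```

with `c` selecting the active biomass reaction (growth maximisation)
unless stated otherwise. LPs are solved with HiGHS through
`scipy.optimize.linprog`; every accepted solution is checked to satisfy
`‖S·v‖∞ ≤ 1e-6`. Flux variability analysis (FVA) fixes the objective at
a fraction γ of its optimum (inequality `c·v ≥ γ·z* − 1e-9`; the 1e-9
slack absorbs solver round-off) and reports each reaction's attainable
`[v_min, v_max]`. γ defaults to 1.0 — the "allowable range" at the
optimum — and is configurable.

Measured exchange rates constrain the model with the sign convention
*negative flux = uptake*: a measured uptake magnitude `u` is applied as
the equality `(-u, -u)` (chemostat rates are measurements, not caps),
a measured secretion `s` as the floor `(s, 1000)`. Default bounds when a
format omits them are ±1000 (reversible) or (0, 1000) (irreversible).
Magnitudes below 1e-5 mmol/gCDW/hr are reported as zero in user-facing
output; raw values are kept internally.

FBA optima can be degenerate. All cross-condition comparisons therefore
use FVA ranges or samples drawn from them, never a single solver vertex;
growth/CER predictions use the objective value and an exchange flux,
which are unique on the shipped test system (degenerate FVA ranges at
γ = 1).

## Gene deletions and essentiality

Gene-protein-reaction (GPR) rules are boolean trees: `and` joins complex
subunits, `or` joins isoenzymes; the empty rule is always active. The
text grammar is the community convention (infix `and`/`or`,
case-insensitive, `and` binds tighter). Deleting gene *g* clamps to
(0, 0) every reaction whose rule evaluates inactive under {*g*}; the
mutant is re-solved and called **inviable** when its objective falls
below an absolute threshold of 1e-6 (the strictest reading of
"no growth"; a relative criterion is available via the `threshold`
argument). The screening condition fixes glucose uptake to 1 mmol/gCDW/hr,
closes the other carbon sources, and leaves oxygen free.

Benchmarking against reference phenotypes uses a confusion matrix with
*viable* as the positive class; sensitivity, specificity, PPV, NPV and
percent-correct are reported in percent at 0.1 precision and
nearest-percent rounding.

## Biomass compilation

A composition lists macromolecule mass fractions (protein, carbohydrate,
lipid, RNA, DNA; g/gDCW, sum accepted in [0.8, 1.05] to tolerate
unmeasured mass), monomer mole-fraction profiles per pool, and the
growth-associated maintenance GAM (mmol ATP/gDCW). The drain coefficient
of monomer *k* in a pool with fraction *f* is

```
coeff_k = 1000 · f · x_k / Σ_k x_k (MW_k − 18.02)      [mmol/gDCW]
```

using polymerised-residue weights (one water lost per bond). GAM is
added as `gam ATP + gam H2O → gam ADP + gam Pi`, and the reaction
produces one unit of a biomass pseudo-metabolite. The drained residue
mass per unit flux equals the composition's total mass within 1e-6
(asserted in tests). A default monomer table ships with standard free
monomer weights (20 amino acids, 4 NMPs, 4 dNMPs, glucose-equivalent
carbohydrates, an average 700 g/mol lipid species); models override the
table and the energy-metabolite ids as needed. Multiple biomass
reactions are registered side by side; exactly one is active (bounds
(0, 1000), objective) while the rest are clamped to (0, 0).

## Flux-sampling significance procedure

To compare the flux state under biomass equations *i* and *j*:

1. compute FVA ranges under each (γ = 1 by default);
2. draw *n* independent uniform samples per reaction within its range
   (*n* = 100 by default; 50/1000/10000 for the sample-size study);
3. per reaction, a two-sided Mann–Whitney U test (exact distribution for
   min(n,m) ≤ 8 without ties, otherwise the normal approximation with
   continuity and tie correction; two identical constant samples give
   p = 1) and a fold change of mean sampled fluxes, computed after
   zeroing magnitudes below 1e-5 — FC = max(|m_i|,|m_j|)/min(|m_i|,|m_j|),
   FC = 1 when both means are zero and +∞ when exactly one is;
4. a reaction is significant iff p < 0.01 **and** FC > 2. No
   multiple-testing correction is applied by default (a
   Benjamini–Hochberg option exists in the enrichment utility).

Two deliberate properties: sampled vectors are independent per reaction
and therefore **not stoichiometrically consistent** — the procedure
probes the geometry of the FVA envelope, not feasible flux states — and
the registered biomass reactions themselves are excluded from the
comparison, since each is clamped to zero in every condition but its own
and its "flux difference" would only restate which equation is active.

Randomness: one seed per scan; each (condition, reaction) pair gets its
own stream derived by stable CRC hashing, so results are independent of
reaction ordering and reproducible across runs.

Correlation matrices (Pearson) are computed both over per-condition flux
vectors and over biomass coefficient vectors; zero-variance vectors give
missing values, never 0. The flux vectors default to FBA optima per
condition; mean sampled vectors are available by calling the correlation
on the sample means.

## Target identification

**FSEOF** (flux scanning based on enforced objective flux): the product
flux is raised as a lower bound in 10 evenly spaced levels from its
growth-optimal baseline to 90% of its theoretical maximum, maximising
growth at each level. Reactions whose flux magnitude increases
monotonically (within 1e-6, no sign change, total rise > 1e-6) are
overexpression candidates. Candidate *genes* come only from reactions
with a 1:1 gene-reaction mapping: OR rules (isoenzymes), AND rules
(complexes), and genes shared across reactions (promiscuous enzymes) are
excluded and logged. Step count and fraction are configurable; the
defaults follow common FSEOF practice.

**Knockout ranking** is a variability-based surrogate score, not a
replication of any published knockout-design tool: for each 1:1-mapped
gene, the deletion mutant's maximum growth is computed; mutants below
50% of wild type are excluded; otherwise growth is **fixed** (equality)
at 50% of the mutant maximum and the deletion is scored by the minimum
product flux the mutant then guarantees — deletions that force carbon
toward the product score highest. Ties break by higher mutant growth,
then gene id, giving a deterministic total order. The growth pin must be
an equality: with a one-sided bound the surplus substrate is absorbed by
extra biomass and every score collapses to zero.

**Robustness across compositions**: candidates found under every biomass
equation are *robust*; those found under only some are *conditional*
(set intersection/union algebra). For rankings, genes whose rank moves
by more than a configurable displacement are listed as rank-unstable.

## Synthetic study system

The core fixture is a deterministic 47-reaction, 2-compartment network
emulating a methylotrophic yeast: glucose/glycerol/methanol uptake
(methanol oxidation by an isoenzyme pair, mirroring the AOX1/AOX2
situation), a respiration-vs-fermentation redox branch, a
capacity-limited arabitol overflow that is a net NADH sink, a
non-growth-associated maintenance ATPase, precursor pathways for two
amino acids, three carbohydrate species (structural glucan, glycogen,
trehalose), an averaged lipid, NMP and dNMP, and a heterologous-protein
drain (amino acids + ATP → product) with OR-catalysed export. GPRs
include nine essential single-copy genes, three isoenzyme pairs, one
enzyme complex and one promiscuous gene, so every rule shape the
pipeline distinguishes is present with known ground truth.

Its twelve biomass compositions mirror the structure of
condition-resolved composition measurements (aeration series for
wild-type and producer strains; glycerol:methanol ratios at two dilution
rates): protein 0.36–0.46 g/gDCW, carbohydrate 0.23–0.30, lipid
0.09–0.15, RNA 0.060–0.097, DNA ~0.012, GAM 24–34 mmol/gDCW. Values are
plausible yeast numbers chosen once for structure, not fits to any
dataset. Two pairs are deliberate controls: `wt_normoxic` /
`fab_normoxic` are *identical* (the significance procedure must find
nothing) and `wt_normoxic` / `fab_hypoxic` differ strongly in the
glycine share of protein and the trehalose share of carbohydrate (the
procedure must stably flag the glycine- and trehalose-synthesis fluxes).
Three constraint sets ship with the fixture: `glucose` (essentiality
convention), `oxygen_limited` (glucose and O2 fixed — the overflow
regime used for target identification), and `met_gly` (a
glycerol/methanol co-feed chemostat condition used for the biomass
scan).

Random toy networks compose linear chains (every gene the sole route
from a carbon source to an obligatory precursor — essential by
construction) with parallel-reaction and isoenzyme motifs (each gene
individually dispensable). Feasibility (growth = 1 at unit uptakes) and
freedom from dead ends hold by construction; ground truth is never
derived from the pipeline under test, and tests double-check it against
a brute-force dense-LP oracle.

What passing on this system shows — and does not. It validates the
machinery end to end: LP correctness against an independent oracle,
exact ground-truth recovery, the negative/positive controls of the
significance procedure, and the set algebra of robustness
classification. It does not reproduce genome-scale behaviour: at
γ = 1 the fixture's FVA ranges are degenerate (a 47-reaction network at
fixed uptakes has little alternate-optimum freedom), so the sampling
procedure is exercised mostly on location shifts rather than on wide
overlapping ranges, and the FSEOF robust/conditional split is 2/0 rather
than the rich partition a 1,424-reaction model yields. Genome-scale
claims require supplying a real model (SBML, either FBC v2 or the legacy
COBRA-notes dialect) to the same entry points.

## Numerical and interface choices

- LP tolerances: steady-state residual ≤ 1e-6; FVA objective-fix slack
  1e-9; degenerate FVA ranges snapped when min exceeds max by round-off.
- Viability threshold 1e-6 absolute (configurable).
- Zero-flux reporting tolerance 1e-5, applied to samples and means in
  the significance procedure.
- Serialisation: tabular TSV round-trips coefficients bit-exactly (17
  significant digits); SBML round-trips at libsbml's ~15 significant
  digits. The biomass registry travels in SBML model notes.
- The composition scan flags infeasible compositions and continues.
- Every pipeline output table carries the run seed and a hash of the
  scientifically meaningful configuration.

## Known limitations

- Uniform, per-reaction-independent sampling is faithful to the
  procedure it implements but thermodynamically naive; do not interpret
  sampled vectors as achievable flux states.
- The knockout score is a deliberately simple surrogate; it shares only
  the candidate-restriction rule (1:1 mappings) with score-based
  knockout design tools and will not reproduce their rankings.
- No gap-filling, mass/charge balancing, loopless FBA, pFBA/MOMA, or
  double-deletion analysis.
- Term enrichment is a generic hypergeometric test over a user-supplied
  gene→term map; it does not parse ontology files or propagate the term
  hierarchy.
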