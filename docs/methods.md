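# Methods

This note records the modeling choices behind `entroflux`: what each stage
computes, which parameters matter, what the synthetic generator does and
does not emulate, and the numerical decisions a maintainer would want
written down.

## Entropic flux balance analysis

The solver minimizes `Ψ(v_f, v_r) = Σ_j v_f,j ln v_f,j + Σ_j v_r,j ln v_r,j`
subject to `S(v_f − v_r) = 0`, `lb ≤ v_f − v_r ≤ ub`, `v_f, v_r ≥ 0`, with
the convention `0·ln 0 = 0`.  Only the *net* flux is bounded: a reaction
that is irreversible in the net sense still carries the symmetric
microscopic split `v_f = v_r = 1/e` when its net flux is zero, which is
what makes the objective finite and strictly convex everywhere.

**Reduction.** For fixed net flux `v`, Lagrangian stationarity of the
split gives `ln v_f + 1 = μ`, `ln v_r + 1 = −μ`, hence `v_f·v_r = e⁻²`
and `v_f(v) = (v + √(v² + 4e⁻²))/2`.  Substituting back yields a smooth
per-reaction potential φ(v) with `φ′(v) = 1 + ln v_f(v)` and
`φ″(v) = (v² + 4e⁻²)^(−1/2) > 0`.  eFBA is therefore a strictly convex
program in `v` alone.  We parametrize the steady-state affine subspace
exactly — fixed rates (lb = ub) are substituted, a minimum-norm particular
solution is computed by least squares, and `scipy.linalg.null_space`
supplies the basis — so `‖S v‖∞` is at numerical null-space precision
(~1e-13) by construction, and minimize with `trust-constr` using the
analytic gradient and Hessian; only the box constraints remain as
inequalities.  If the minimum-norm point violates the box, a
max-slack LP recentres the start.  Tolerances: `gtol 1e-12`,
`xtol 1e-14`; the returned objective is well within 1e-6 of the optimum on
every fixture with a known closed form.

**Solution scale.**  The entropy is not invariant to flux units.  Fluxes
are solved in µmol/gDW/hr; an explicit `scale` parameter divides fluxes
before they enter the entropy and is recorded in every solution, making
the unit dependence visible rather than implicit.

**Independent oracle.**  `efba_oracle` re-solves problems with ≤ 3 flux
degrees of freedom using only the inner closed form plus iterative grid
refinement over the null-space coordinates (13 points per axis, 60
shrink-and-zoom rounds, infeasible points scored +∞).  It shares no code
path with the trust-region solver beyond the per-reaction split and agrees
with it to ≤ 1e-6 in objective on all fixtures and randomized small
networks.

**Why cycles vanish.**  On a closed loop the only steady-state solutions
are equal-magnitude circulating fluxes `t`; the reduced objective is
`Σ φ(t)`, minimized at `t = 0` since each φ has its minimum at zero net
flux.  FBA, by contrast, happily drives the same loop to its ±1000 bound.
This is the method's operational answer to thermodynamically infeasible
cycles, with no explicit loop-law machinery.

**Driving constraints.**  With pure inequality uptake bounds the global
entropic optimum is the trivial all-zero net flux.  The pipeline therefore
imposes measured media uptakes as *fixed* exchange rates in the eFBA stage
(the extraction stage itself uses inequality bounds, the safer reading for
consistency analysis; a strict mode is available there too).

## Context-specific extraction

Inputs per cell line: a TPM table, spent-media measurements, optional
curation lists.  Parameters and defaults:

| parameter | default | meaning |
|---|---|---|
| `tpm_threshold` | 2 TPM | gene active iff mean TPM ≥ threshold (inclusive: "below threshold" is inactive) |
| `protein_fraction` | 0.5593 | protein share of cell dry weight; DW = protein mass / fraction |
| `close_ion_exchange` | true | ion exchanges pinned to [0, 0] |
| `ion_ids` | h, h2o, pi, na1, k, cl, ca2, fe2, mg2 | the closable ion set (configurable; no canonical list exists) |
| `priority` | experimental > curation | conflict resolution between omics calls and curation lists, every override logged |
| empty GPR | active | reactions without gene annotation are kept |

Gene activity uses the mean TPM across a line's replicate columns (one
column per line in the default design); the aggregation across replicates
is a package choice.  Uptake bounds follow
`conc × volume / (DW × interval)`; a literal mode that additionally
divides by protein mass is available behind a flag because the
dimensional reading of the denominator (dry weight *and* protein
concentration, with dry weight itself protein-derived) is ambiguous — the
derived-DW mode is the default.

**Consistency pruning.**  The extraction is a FASTCC-style fixed point
rather than a thermodynamic kernel: (1) reactions whose GPR evaluates
inactive (or curation-inactive) are removed; (2) blocked reactions
(flux-variability min = max = 0, tolerance 1e-9, HiGHS LPs) are stripped
iteratively; (3) if a designated-active reaction becomes blocked, removed
reactions are greedily re-added (single best candidate first, then the
full complement for multi-reaction dependencies), each retention logged;
(4) every active gene without a surviving reaction gets one add-back
attempt; genes that still cannot be served (e.g. their only reaction is
structurally blocked) are reported as unsatisfiable, never silently
patched.  The output always satisfies `find_blocked_reactions(model) = ∅`.

## Differential flux analysis

Fold change per reaction and model: `(v − μ_ctrl)/μ_ctrl` with `μ_ctrl`
the mean of the control columns, computed over the intersection of
reaction sets across all models.  Control columns are included (their FCs
measure within-control spread).  Entries with `|μ_ctrl|` below a masking
epsilon are undefined and masked — never divided, never imputed as zero
for ranking.  Two epsilons exist deliberately: the algebraic default
(1e-9, the mathematical "μ = 0" guard) and the pipeline default (1e-6),
which additionally masks fluxes that are zero up to solver convergence
noise; fold changes between two ~1e-8 numerical residues are meaningless
and would otherwise dominate the ranking.

Ranking uses the maximum |FC| across model columns (mean/median
selectable), ties broken lexicographically.  Clustering is agglomerative
with Euclidean distance and Ward linkage on both axes (the conventional
heatmap default; nothing in the analysis depends on the linkage choice
beyond tie structure), serialized as Newick.  Subsystem tallies merge
subsystems holding exactly one listed reaction into "others" before the
top-five cut.  Cofactor views select reactions touching a cofactor base
id in one compartment, or by subsystem label.

Model-topology similarity is the Pearson correlation of binary
presence/absence vectors over the entity union (the phi coefficient) —
the simplest defensible reading of an "average correlation of model
composition"; identical vectors score 1 even when constant, a single
constant vector scores 0.

## Biomarker cross-match

Matching keys are compartment-stripped, case-insensitive VMH-style base
ids.  "Replicated" means ≥ 2 catalogue records regardless of direction
agreement.  Direction classes: exclusively_increased /
exclusively_decreased / inconsistent / single_study (single_study is kept
distinct so the replicated/non-replicated split is recoverable).  An empty
match reports the replicated proportion as not-applicable rather than 0.
The bundled catalogue fixture encodes a published 15-metabolite replicated
PD biomarker panel (per-study directions and biospecimens) plus five
synthetic decoy metabolites that no fixture network produces.

## Synthetic data: what it emulates, and what not

The generator mirrors the target study design: 3 disease vs 3 control
lines, one expression profile per line, identical media, log2-TPM drawn
as `N(baseline + shift, sd)` so TPM is log-normal and positive; the
disease shift (default log2FC = −2) applies to every gene of one target
subsystem.  Defaults chosen once: noise sd 0.4 on the log2 scale
(line-to-line variability), media glucose 240 µmol/L in 2 mL over 48 h
with protein 5.593e-4 g per culture, giving a glucose uptake of
10 µmol/gDW/hr through the worked-example formula; per-line protein mass
varies log-normally with 1% CV — assay-level precision, deliberately
small so that media-scale variability exists but remains subordinate to
the planted network effect (a much larger CV would confound column scale
with condition, which is a statement about this fixture, not about real
cohorts).

The default toy network (79 reactions, compartments e/c/m, one gene per
internal reaction plus a few AND/OR rules) contains: a glycolysis chain,
a TCA cycle with anaplerotic pyruvate carboxylase and a reversible
dicarboxylate tail, NAD+/NADH coupled to redox steps in both compartments
with an electron-shuttle reaction between them, NAD synthesis/degradation,
serine/glycine, glutamate/glutamine and tyrosine→dopamine→norepinephrine
branches, a cholesterol chain, a dead-end folate branch (the ground-truth
blocked reactions, whose genes are also below threshold in every line),
and a lipid-synthesis subsystem built as ten parallel two-step routes from
acetyl-CoA.  Gene baselines straddle the 2-TPM threshold by design: two
"vulnerable" routes sit at log2-TPM 2.2 (active in controls, lost under
the −2 disease shift), the rest at 4.5–6 (active everywhere).  Knocking
out two of ten routes re-routes lipid flux through the surviving eight,
raising their fluxes ~25% — a planted, identifiable differential signal
carried by reactions that remain *shared* across all models (wholesale
removal of a subsystem would remove its reactions from the fold-change
table entirely).  Several metabolite ids intentionally coincide with
catalogue entries (cit, gly, ser_L, gln_L, tyr_L, dopa, nrpphr) so the
cross-match stage has true positives; decoys provide true negatives.

What the generator does **not** emulate: read-level RNA-seq or its
normalization, mass-spectrometry measurement error, growth/biomass
requirements, mass- or charge-balanced stoichiometry (coefficients are
unit), thermodynamic potentials, and realistic genome-scale redundancy
(GPRs are one-gene rules except for designated cases).  Passing recovery
tests therefore demonstrate that the pipeline's inference machinery works
when its assumptions hold — not that real cohort data of this size would
yield the same power.

## Recovery analysis

Per seed: simulate a cohort, extract six context models, solve eFBA, rank
the top-50 |FC| reactions, then (a) test over-representation of the
target subsystem among the top-50 against a hypergeometric null over the
rankable (unmasked) shared reactions, and (b) cut the model dendrogram at
two clusters and ask whether the cut separates disease from control.
Under the default scenario the rankable universe is ~69 reactions of
which 16 belong to the target subsystem; full recovery gives
p ≈ 2.6e-3.  Ten seeds run in under two minutes on one CPU; problem sizes
(79-reaction network, 12 flux degrees of freedom after fixing media
exchanges) were chosen so the whole pipeline stays interactive.

## Known limitations

- The eFBA box constraints are handled by an interior-point method;
  returned fluxes can sit within ~1e-9 outside a bound and are clipped.
- The greedy consistency add-back is not minimal-cardinality; it is
  deterministic and logged, which we consider the more important property.
- `efba_oracle` refuses problems with more than three degrees of freedom;
  it is a verification tool, not a solver.
- Fold changes are undefined for reactions whose control-mean flux is
  zero; such reactions are excluded from ranking and clustering rather
  than given a pseudo-count.
- The SBML dialect covers FBC bounds, GPRs, compartments and
  notes-encoded subsystems; events, rules and unit definitions beyond
  flux bounds are out of scope.
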