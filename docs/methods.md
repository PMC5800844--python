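# Methods

This note documents the models implemented in `hypoxiscan`, the parameter
choices that matter, the conventions that keep the numerics honest, and
what the synthetic data do — and do not — establish about real data.

## Homolog selection (RBH)

Candidate homologs of a reference protein are the reciprocal best hits
between two proteomes: pair (q, s) is kept iff s is q's top-scoring
subject in the forward search and q is s's top in the reverse search,
after discarding hits with e-value > 1e-5 (inclusive cutoff, matching the
`-evalue` semantics of common search tools). Multiple HSPs per
query–subject pair are collapsed to the single best-bitscore record
before ranking, because the reciprocal criterion is gene-level. Ranking
ties break by smaller e-value, then lexicographic subject id, so results
are deterministic; these tie rules are package conventions.

A structural caveat, verified on simulation: when the subject lineage
carries in-paralogs (a 1-to-many relation), one reciprocal pair still
forms — the query's best in-paralog points back at the query. RBH
therefore equals the true 1:1 ortholog set exactly only on
duplication-free families; with duplications it equals the best-hit
evaluation of the tables, which is what the tests assert in each regime.

## Gene-tree orthology and the presence–absence matrix

Internal nodes are labelled by the **species-overlap rule**: a node is a
duplication iff the species sets of its child subtrees intersect
(polytomies are treated pairwise). This needs no species-tree topology,
which keeps the classification agnostic about the contested branching
order of sponges and ctenophores; the alternative — reconciliation
against a fixed species tree — would bake that controversy into every
verdict. The cost is an asymmetric error mode, which the tests pin down:
on loss-free gene trees the labels equal the true events at every node;
with losses, species overlap can *miss* duplications (when losses hide
the overlap) but never invents them.

Verdicts for a reference gene r against a target species follow an
O/R-set rule. O is the set of target-species leaves whose LCA with r is a
speciation node; R is the set of reference-species leaves
speciation-related to any member of O. |O|=1 ∧ |R|=1 → 1-to-1 ortholog;
|O|>1 ∧ |R|=1 → 1-to-many; |R|>1, or O empty while the species has
family members → homolog (the "sister to a duplication block" pattern);
no family member at all → absent. For the reference's own species the
reference gene counts as its own trivial ortholog, so a reference clade
always reads as present. Clade-level verdicts take the best verdict over
member species (ordered 1to1 > 1tomany > homolog > absent): presence in
any member species is presence for the clade. An absence is upgraded to
**secondary loss** only when a configured non-metazoan outgroup clade
(default Choanoflagellata, Capsaspora) retains the component. A clade is
flagged 'M' when ≥2 duplication nodes have all descendant species inside
it. Support values are parsed but not used to collapse nodes by default;
an optional minimum-support collapse to polytomies exists because the
classification rules never condition on support. Unrooted inputs are
rooted on the outgroup species when present, else by midpoint; parsed
trees are treated as rooted so that rerooting never dissolves the basal
bifurcation.

Verdict recovery, measured against the simulator's event-history replay
(500 families, duplication rate 0.1 and loss rate 0.05 per unit branch
length), exceeds 95% — in practice it has been exact on every family the
suite draws, because the O/R rule degrades gracefully even where event
labels err.

## Domain architectures and the C-terminal region

Domain hits come from HMMER3 `--domtblout` files (envelope coordinates)
or a simplified TSV; both are 1-based inclusive on disk and 0-based
half-open in memory, converted exactly once at the I/O boundary.
Significance cutoffs are e-value ≤ 0.1 AND bitscore ≥ 10. Overlaps
resolve greedily by bitscore: a hit is dropped when it overlaps an
accepted hit by more than 50% of the shorter of the two. The bHLH-PAS
family call requires ≥1 bHLH-class domain N-terminal to the first
PAS-class domain; the PAS-class vocabulary {PAS, PAS_3, PAS_11, PAC} and
bHLH-class {HLH} are the PFAM models that tile canonical family members,
and both the vocabulary and the ordering requirement are configurable
because annotation practice varies. The region scanned for degrons runs
from the end of the last PAS/PAC domain to the protein end; a protein
with no PAS-class domain raises a distinct error rather than silently
scanning the full sequence.

## ODD-degron scanning and chance occurrence

Strict mode matches the full consensus `L[D/E]x[L/R]AP[F/Y]I`
(overlapping matches all reported); core mode matches the tetramer
`[L/R]AP[F/Y]`, which captures clade variants (LAPY/RAPY/RAPF/LAPF) and
near-miss octamers such as LAMRAPYI that carry the core but fail the
strict consensus. No fuzzy scoring is used: a sequence either matches a
declared pattern or it does not, which keeps presence/absence claims
auditable.

Because bHLH-PAS C-terminal tails are P/S/Q-rich, core matches arise by
chance. Two nulls are reported side by side: (1) the analytic i.i.d.
expectation E = (L−k+1)·Π over pattern positions of the summed allowed-
residue frequencies (a free position contributes factor 1), verified in
the tests against exhaustive enumeration of all k-mers over the support
alphabet; and (2) a within-region permutation test,
p = (1 + #{shuffles with count ≥ observed}) / (n_shuffles + 1), which
preserves composition exactly but destroys residue runs. The i.i.d. model
ignores the autocorrelation of P/S/Q repeats; the permutation null does
not, which is why both are kept.

## Oxygen conversions

Percent air saturation (%AS) is referenced to equilibrium with
water-saturated air at 1 atm. The solubility routine is the
Garcia–Gordon combined refit of the Benson–Krause data, per-litre
(cm³ dm⁻³) variant, converted to µmol L⁻¹ with the ideal molar volume of
O₂ (22.3916 L mol⁻¹); validity spans −2…40 °C and salinity 0…42. At the
experimental conditions (26 °C, S = 32) it gives 211.6 µM at 100% AS,
and linear scaling gives 21.16 µM at 10%, 8.46 at 4%, 3.94 at 1.86%,
0.529 at 0.25%, and 105.8 nM at 0.05%. The µmol kg⁻¹ variant of the same
fit gives 207.3 µM and was rejected because the per-litre variant is the
one consistent with the reference concentration set to better than 1%.
Hydrostatic and altitude corrections are out of scope; saturation scales
linearly with barometric pressure.

## Imaging

Segmentation is threshold-based: optional background subtraction, global
Otsu threshold, morphological closing (radius 2 px), largest connected
component, hole fill; the component boundary is the detected edge, and
the output is the projected area in pixels, optionally calibrated to mm²
by dividing by (pixels per mm)². A gradient mode (Sobel magnitude →
Otsu → close → fill → 1-px erosion to re-centre the boundary) is provided
behind config. A frame whose contrast is below 20 intensity units, or
whose largest component is under 25 px, yields an explicit "no object"
result that propagates as a missing value — gaps are never interpolated.
On noise-free synthetic ellipses the measured area is within 3% of the
pixel-rasterization truth, within 2% under rotation, and within 5% at
σ = 10 intensity units of Gaussian noise on an 8-bit frame. No numeric
equivalence with any particular camera/optics pipeline is claimed — only
these internal-consistency properties.

## Contraction detection and rate comparison

The area trace is median-smoothed (5 samples), normalized by a rolling
90th-percentile baseline over 2 h, and thresholded: an event is a maximal
interval with normalized area < 1 − θ_sub, with events closer than 5 min
merged. θ_sub = 0.1 and θ_full = 0.5 (trough below 1 − θ_full ⇒
full-body, else sub-contraction) are package conventions — the
full-body/sub distinction is qualitative in the source observations —
and are exposed in the detector config. The upper-quantile baseline
tracks slow size drift while staying insensitive to the dips themselves.

Rates across stable O₂ plateaus are compared with a Poisson log-linear
model, log E[count] = log(exposure_days) + α_individual + β_level, with
fixed per-individual intercepts standing in for the random effects a
mixed model would use: with a handful of clonal individuals this is a
standard small-N approximation that keeps the likelihood exact and
testable. The fit is IRLS maximum likelihood (tolerance 1e-8 on
coefficients, ≤100 iterations); the global test is the likelihood-ratio
statistic 2(ℓ_fit − ℓ_null) against χ² with (levels − 1) df; pairwise
level contrasts are Wald z-tests with Holm adjustment (uniformly valid
without distributional extras, where a single-step multiple-comparison
procedure would need them). The reference level is the level with the
largest total count, so the baseline is never an all-zero group; a level
with no events at all sits on the boundary of the parameter space and its
effect is reported as −∞ rather than a meaningless finite estimate.
Calibration, measured by simulation at the study's scale (8 individuals,
3 levels, 1-day exposures, 200 replicates): type-I error ≈4.5% at
nominal 5%, power ≈100% for a 10-vs-2 events/day contrast.

O₂ uptake is the rolling least-squares slope of the O₂ trace (sign
flipped so uptake is positive), default window 21 samples (10.5 min at
30 s cadence). Contraction-coupled uptake contrasts mean uptake inside
vs outside event intervals; the null circularly shifts the phase labels
against the rate series, preserving both the rate autocorrelation and the
phase-duration structure.

## DE-table thresholding

The package implements only the published-threshold summary of externally
produced differential-expression tables: Benjamini–Hochberg step-up
adjustment (verified against direct evaluation of the definition and
against statsmodels) and the filter adjusted-p < 0.01 with log₂ fold
change ≥ 2 (overexpressed) or ≤ −2 (underexpressed) — fold-change bounds
inclusive, significance strict, matching the printed comparison symbols.
The DE testing itself (negative-binomial modelling) is an external-tool
step and is deliberately not reimplemented.

## Synthetic data: what it emulates and what it does not

Gene families evolve gene-tree-first by a birth–death duplication–loss
process along a fixed 14-species ultrametric opisthokont tree (four
sponge classes, two ctenophores, cnidarian, placozoan, three bilaterians,
choanoflagellate, Capsaspora). Every event is recorded, so true pairwise
relations, per-species verdicts and per-clade duplication counts are
exact replay, not re-inference. No sequences evolve — the orthology
oracles need only the tree — which is precisely why they are exact.
Default rates in the analyses (duplication 0.08–0.1, loss 0.04–0.05 per
unit branch length) produce the mixture of 1:1, 1:many and lost families
a curated gene set typically shows.

Homology tables assign bitscores as a strictly decreasing function of
gene-tree patristic distance, 500/(1+d), plus seeded jitter bounded below
half the smallest gap between distinct base scores, so ranks of distinct
distances never reorder; e-values decrease monotonically with bitscore.

Proteomes carry the planned domain series (annotated in the companion
TSV), a disordered tail drawn from a P/S/Q-rich composition (defaults
P 0.20, S 0.15, Q 0.10), and planted strict octamers at chosen offsets;
chance strict matches are resampled away so the strict truth is exactly
the planted set, while chance core matches remain part of the
composition-driven background.

Experiments follow a stepped %AS schedule sampled at 30 s, with
first-order relaxation (τ = 30 min) between steps. Contraction events are
a Poisson process per plateau, thinned to enforce a 20-min refractory gap
after each 12-min event, with full-body amplitudes drawn U(0.55, 0.75)
and sub-contraction amplitudes U(0.15, 0.40) — conventions chosen to sit
clearly on either side of the detector thresholds, since the source
observations do not quantify amplitudes. The refractory thinning makes
accepted events a renewal process with mean gap 1/λ + 32 min, and the
generator tests check counts against that analytic mean, not against the
unthinned λ. Rendered frames are 8-bit ellipses (intensity 200 on
background 30) whose area tracks the trace; no optics, lens distortion or
lighting drift is modelled.

Passing on these data therefore shows that the inference chain is
correct *given its own assumptions*; it does not show robustness to
misassembled transcriptomes (a missing gene is indistinguishable from a
true absence — the matrix records absence agnostic of assembly
completeness), alignment/tree-search error upstream of the gene trees,
non-elliptical or partially occluded bodies, or drifting illumination.

## Numerical conventions

Coordinates are 0-based half-open internally everywhere; file formats
keep their native conventions (BLAST/HMMER/TSV 1-based inclusive) with
conversion at the I/O boundary only, and report writers print 1-based
positions. All stochastic routines take explicit integer seeds and are
deterministic given them; generator outputs are byte-identical under the
same seed. Permutation p-values use the add-one estimator
(1 + exceedances)/(n + 1), which can never return 0. Matrix cells
serialize as verdict codes with an optional `+M` suffix and round-trip
through TSV unchanged.

## Known limitations

- The species-overlap rule under-counts duplications in the presence of
  loss; verdicts inherit that bias, though the measured effect at the
  simulated rates is negligible.
- Fixed-intercept Poisson modelling slightly underestimates between-
  individual variance relative to a random-effects fit when individuals
  are many and heterogeneous; at the study's scale (≤8 individuals) the
  approximation is standard and the measured calibration is accurate.
- The amplitude classes, detector thresholds and segmentation parameters
  are conventions, not measured properties of any real animal; real
  deployments should calibrate them against annotated footage.
- The i.i.d. composition null ignores residue autocorrelation; use the
  permutation p-value when repeats dominate a tail.
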