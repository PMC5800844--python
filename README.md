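# hypoxiscan

Comparative-genomic and physiological analysis of oxygen sensing in early
animals: does a lineage possess the HIF pathway, and how does a sponge
behave when oxygen gets scarce?

The HIF pathway is the canonical animal oxygen sensor: under normoxia the
transcription factor HIFa (a bHLH-PAS protein) is hydroxylated at a key
proline inside the oxygen-dependent degradation (ODD) motif
`L[D/E]x[L/R]AP[F/Y]I` by the prolyl hydroxylase EGL9/PHD, then targeted for
destruction by VHL; under hypoxia it escapes degradation, dimerises with
ARNT and activates transcription. Profiling which lineages carry true
orthologs of these components — and whether a lineage that lacks them still
responds behaviourally and transcriptionally to low oxygen — bears directly
on how much oxygen the earliest animals needed.

`hypoxiscan` implements that inference chain as a tested Python library
plus a set of analysis drivers, exercisable end-to-end on synthetic data
with known truth:

- **homology** — reciprocal-best-hit (RBH) candidate selection from BLAST
  tabular (`-outfmt 6`) output, e-value cutoff 1e-5;
- **orthology** — gene-tree event labelling by the species-overlap rule
  (a node is a duplication iff its child subtrees share a species),
  per-clade verdicts {1-to-1 ortholog, 1-to-many, homolog, absent,
  secondary loss}, lineage-duplication flags, and the presence–absence
  matrix rendered under both Porifera-sister and Ctenophora-sister clade
  orders;
- **domains / motifs** — HMMER-style domain tables with the e ≤ 0.1,
  bitscore ≥ 10 cutoffs, bHLH+PAS architecture calls, C-terminal region
  delimitation, and ODD-degron scanning in strict (octamer) and core
  (`[L/R]AP[F/Y]` tetramer) modes with two chance-occurrence nulls: the
  analytic i.i.d. expectation E = (L−k+1)·Π_i p_i and a within-region
  permutation test;
- **imaging / physiology** — projected-area segmentation of a bright body
  on a dark background, seawater O₂ solubility (Garcia–Gordon fit of the
  Benson–Krause data, per-litre variant) with %-air-saturation ↔ µM
  conversion, contraction-event detection from baseline-normalized area
  traces, a Poisson log-linear rate model
  log E[count] = log(exposure) + α_individual + β_level with
  likelihood-ratio test and Holm post-hoc contrasts, and
  contraction-coupled O₂ uptake via a circular-shift permutation test;
- **simulate** — generators for every input (duplication–loss gene
  families on a species tree, bHLH-PAS proteomes with planted degrons,
  rank-preserving homology tables, stepped-O₂ contraction experiments,
  rendered frames), each with an exact truth record.

## Worked example

Oxygen unit conversion at the experimental conditions (26 °C, salinity 32):

```
$ hypoxiscan convert-o2 --percent-as 10 --temp 26 --sal 32
10.0% AS = 21.162 uM
```

i.e. 10% air saturation corresponds to ≈21.2 µM dissolved O₂; 100% AS is
≈211.6 µM at these conditions.

The full analysis sequence runs from the repository root:

```
python analysis/01_simulate_inputs.py
python analysis/02_orthology_matrix.py
python analysis/03_motif_survey.py
python analysis/04_contraction_experiment.py
```

Step 02 selects RBH pairs from the simulated homology tables (`precision
1.000, recall 1.000` against the generator's true 1:1 orthologs) and
prints the five-component presence–absence matrix. Step 03 scans the
simulated proteome and prints, per protein, the observed strict/core motif
counts against both nulls, e.g.:

```
            protein  cterm_len  psq_fraction  strict_obs  core_obs  core_perm_p  planted
 euplokamis|bhlhpas        350         0.429           0         1        0.016        0
        human|HIF1A        400         0.430           1         1        0.015        1
    tethya|bhlhpas1        380         0.434           0         0        1.000        0
```

— the planted vertebrate degron is recovered exactly, the sponge tails
show no motif despite ~44% P/S/Q content, and the ctenophore-style
protein carries a core-only near-miss (`LAMRAPYI`). Step 04 detects
contraction events in three simulated individuals and fits the rate
model:

```
Poisson rate model: LRT = 70.1 (df 4), p = 2.13e-14
   0.25%AS (   0.53 uM O2): log-rate effect -inf (no events)
     10%AS (  21.16 uM O2): log-rate effect +0.00
    100%AS ( 211.62 uM O2): log-rate effect -0.29
      2%AS (   4.23 uM O2): log-rate effect -inf (no events)
      5%AS (  10.58 uM O2): log-rate effect +0.07
contraction-coupled O2 uptake: +0.88 uM/hr during contractions, p = 0.001
```

— contraction rates are statistically indistinguishable from 100% down to
5% air saturation, cease at the two lowest plateaus, and the planted
uptake elevation during contraction phases is recovered by the
permutation test.

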