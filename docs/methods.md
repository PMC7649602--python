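# Methods

## Interface truth construction

**Mutagenesis route.** Each point mutation's disruption of the dimerisation
signal is `d = (w − m)/w`, where `w` is the wildtype and `m` the mutant
reporter signal (arbitrary units, `w > 0`).  `d` is positive when the
mutation weakens dimerisation and negative when it strengthens it.  The
per-position mean `d̄` over all available mutations is thresholded at 0.24;
the boundary is inclusive (`d̄ ≥ 0.24` is interfacial) so that the printed
cutoff itself is meaningful.  Unmutated positions are labelled
non-interface: in the datasets this rule emulates, mutation coverage was
near-complete, so absence of evidence is treated as a negative label (the
choice is logged).  Per-study renormalisation of heterogeneous reporter
scales is not attempted.

**Structural route.** Residues *i* (chain A) and *j* (chain B) are in
contact when any pair of heavy atoms, one from each residue, lies strictly
closer than 3.5 Å; ties at exactly 3.5 Å are excluded.  Heavy atoms are all
non-hydrogen atoms including side chains; alternate locations resolve to the
highest-occupancy conformer (the reader's default).  A residue is
interfacial when it appears in any contact pair, in either chain role (the
dimers are homotypic).  Only the first model of an NMR ensemble is used.
Candidate atom pairs come from a k-d tree; an O(N²) all-pairs scan serves as
the test oracle.

**X-ray subset rules.** Helix pairs extracted from crystal structures are
retained only when the resolution is ≤ 3.5 Å, the helices are parallel (sign
of the dot product of per-helix first principal components of Cα
coordinates, oriented N→C), and at least four interface residues exist.
Because such helices usually sit inside polytopic complexes, their residues
are partitioned into group A (homotypic contact with the identical partner
chain), group C (no homotypic contact but a heavy-atom contact with some
other chain — a folding contact), and group B (no protein contact; assumed
lipid-facing).  Group C rows are excluded from training but retained as
negatives during validation, mirroring the practice of comparing against
structure predictors that cannot exclude single residues.

**Symmetry statistic.** For a contact map and interface mask, the symmetry
fraction is the share of interface residues touching their own image (i,i)
or a direct neighbour of it (i,i±1) in the opposing chain.

## Feature census (103 columns)

| family | n | contents |
|---|---|---|
| coevolution | 52 | {MI, DI} × 13 row summaries × {raw, per-TMD min–max normalised} |
| PSSM | 25 | 20 amino-acid fractions + small/strongly-polar/aromatic/aliphatic composites + gap fraction |
| conservation | 8 | entropy `H`, `C = 1 − H/log₂20`, gap-inclusive variants, modal fraction, reference identity, flank-relative `C` and `H` |
| polarity | 8 | mean negated GES polarity, flank-relative polarity, query-sequence variants, LIPS-style face score and its components |
| position | 5 | residue depth, normalised position, TMD length, TMD mean polarity and conservation |
| motifs | 3 | GxxxG, (small)xxx(small), (polar)xxx(polar) membership |
| physical | 2 | β-branched {I,V,T}, small {G,A,S,C} |

The 13 coevolution summaries are max, top-2/3/4/8 means, mean, median, std,
neighbour-window means over separations ≤ 1..4, and the within-4 maximum.
The main text of the study this census reconstructs gives only the family
sizes (52/25/8/8/5/3/2), not the identities of every member; the
composition above is this package's documented reconstruction and is
enforced by a hard schema check, so the 103-column count cannot drift
silently.  Conservation based on phylogenetic rate estimation (rate4site) is
replaced by entropy-derived variants; this package deliberately has no
external-binary dependencies.

Sign conventions: the GES scale measures hydrophobicity, so polarity is its
negation (Arg high, Phe low); conservation is inverted entropy so values
rise toward 1 for conserved columns.  "Relative" features subtract the mean
of up to three positions on each side, truncated at the termini.  Residue
depth is `1 − |2i − (L−1)|/(L−1)` (0 at either terminus, 1 at the centre),
a proxy for depth in the bilayer.

**LIPS-style face score.** The seven helix faces follow the two-turn repeat:
face *k* contains positions with `(i − k) mod 7 ∈ {0, 3, 4}` (i.e. *i*,
*i*+3, *i*+4, *i*+7, …; ~100° of azimuth per residue).  Each face is scored
by the mean of z-scored conservation plus z-scored polarity over its
members; a residue (member of three faces) inherits its best face's score,
with ties broken toward the lowest face index.  This is a simplified
re-statement of the lipid-facing-surface idea, not a bit-exact port of the
original algorithm.

**Row validity.** Homologue rows with more than 30 % gaps inside the TMD
span are excluded from all column statistics; the reference row is always
valid.

## Coevolution

Mean-field direct coupling analysis over the 21-state alphabet (20 residues
+ gap): sequences are reweighted by the inverse size of their ≥ 80 %-identity
neighbourhood; single and pair frequencies are regularised with pseudocount
`λ = 0.5·M_eff`; couplings are the negative inverse of the covariance matrix
(last state as gauge); the direct information of a pair is the KL divergence
of the two-site direct model from the product of its marginals.  The
auxiliary fields of the two-site model are fitted by damped (0.5)
Gauss–Seidel iteration to tolerance 1e−10 — the undamped simultaneous
update can oscillate without converging.  A singular covariance raises an
error advising a larger pseudocount.  Mutual information uses the same
weighted, regularised frequencies and is reported in bits.  Matrices are
computed on the TMD columns; the diagonal is defined as 0 so row summaries
never self-select.  Min–max normalisation maps a constant vector to zeros,
making it invariant under affine transforms otherwise.

## Classifier

Extremely randomised trees with balanced class weights (class weighting
rather than resampling keeps per-TMD residue sets intact).  Hyperparameters
(trees, depth, leaf size, feature subsampling) are chosen by grid search
maximising mean average precision over TMD-grouped folds — no residue of one
helix ever appears on both sides of a fold — and the winner is refitted on
all training TMDs.  Feature reduction to 27 proceeds by recursive
elimination: at each round permutation importances (average-precision drop)
are averaged over grouped folds and the weakest quarter is removed.  The
procedure is deterministic given the seed; the selected 27 are recorded in
the model archive as a reconstruction, since the original selection protocol
and final feature identities are not published in the main text.  Model
archives store the fitted ensemble plus JSON metadata (seed, grid, selected
features, training ids) under a format version; reloaded models reproduce
predictions bit-identically.

## Validation metrics

Short TMDs (~20 residues with ~28 % interfacial) make the random precision
baseline high, so the package reports, besides pooled precision–recall:

- **Best overlap (BO)**: for k = 1..10, the fraction of the top-k ranked
  residues that are truly interfacial, averaged over TMDs, with the per-TMD
  random expectation `n_interface/L` alongside.  **AUBOC5** is the sum of
  the mean fractions for k = 1..5 (range 0–5).  Overlap is normalised by k
  (precision@k form); whether the original area used counts or fractions is
  not stated, so fractions are used and documented.  Score ties break by
  ascending residue position.
- **FIMCO-PR**: per TMD, precision and recall of the binary calls
  (probability ≥ 0.5, since a single call set per TMD is required); the
  curve is the fraction of TMDs whose precision *and* recall reach each
  cutoff in 0.1..0.9, with the headline value at 0.5.  A TMD with zero
  positive calls has undefined precision and counts as failing every cutoff
  (logged convention).
- **MCC** on the pooled binary calls; a vanishing denominator yields 0.

Interfaces of third-party predicted dimer structures are extracted from the
top-ranked model with exactly the 3.5 Å contact rule used for experimental
structures.

## Statistics

**Bootstrap t-test.** The observed statistic is the equal-variance
two-sample t.  The null distribution resamples both groups, at their
original sizes, from the pooled mean-centred data;
`p = (1 + #{|t*| ≥ |t_obs|})/(n_boot + 1)` lies in (0, 1].  Only
"bootstrapped data" is specified by the work this reconstructs; this pooled
centred scheme was chosen because it is exchangeable under the null, and its
behaviour is pinned by a test requiring agreement with the analytic t-test
within ±0.02 on normal data.  Two identical constant samples give p = 1 by
convention.

**Enrichment.** For a residue class, enrichment is the class's fraction
among interface residues divided by its fraction among all residues; ratios
weighted by overall propensity average to 1 over a partition.

**Motif nulls.** Motif instances are (i, i+4) pairs with both residues in
the defining set; overlapping instances all count (GxxxGxxxG = 2).  Nulls
shuffle each sequence 100 times preserving its exact amino-acid multiset and
length; for interfacial-motif fractions the interface masks stay fixed to
positions while sequences shuffle, so the null reflects mask geometry and
composition alone.  Replicates in which no motif instance occurs anywhere
are undefined and excluded from the null mean.

## Synthetic data

The generators are pure functions of their spec (seed included).

- **MSAs**: background columns draw from the mean amino-acid composition of
  the packaged 50-sequence reference set (computed at run time, not
  hard-coded).  Conserved columns mutate at 5 %; other columns at 40 %, plus
  Poisson-distributed 2–3-column "segment" mutation events that make
  neighbouring columns co-vary, reproducing the high neighbour-coevolution
  background of real alignments (phylogeny and indels produce it in nature).
  Planted couplings draw a two-state joint distribution of configurable
  strength.
- **Helix dimers**: ideal α-helices (1.5 Å rise, 100°/residue), side chains
  as one Cβ pseudo-atom 2.4 Å beyond the Cα (radius 4.7 Å from the axis) —
  sufficient for the heavy-atom contact rule without a rotamer library.
  Chain B is chain A rotated 180° about the membrane normal and shifted by
  the axis separation (default 10 Å), so each residue faces its own image;
  the planted facing mask follows analytically from the same-index Cβ–Cβ
  distance (`sep² − 2(2R)·sep·cosφ + (2R)²`), and equals the contact-called
  interface exactly.  Separations at or below the 4.7 Å radius raise a
  clash error.
- **Mutagenesis tables**: w = 1; interface positions receive mean disruption
  `effect_size` (default 0.5), others 0, with Gaussian noise; two mutations
  per position (Ala, or Ile at small residues), echoing typical scanning
  designs.
- **Benchmark**: each of 50 TMDs (length 15–30) gets a face-periodic,
  centre-biased mask of `round(0.28·L)` residues clipped to 3–10 (the
  published dataset's coverage and range).  Interface columns carry GxxxG
  pairs (planted with probability 0.7 on up to two face pairs), small/polar
  consensus bias, and a 15 % mutation rate versus 45 % elsewhere.  This
  yields a strong, cleanly recoverable signal: held-out average precision is
  near 1.0, versus the ~0.28 base rate.  Real data are far harder — few
  valid homologues, assay noise, heterogeneous interfaces — so passing the
  benchmark demonstrates that the pipeline recovers the signal structure it
  encodes, not that comparable accuracy is attainable on real TMDs.

**Synthetic reference masks.** The packaged 50 TMD sequences are real; their
per-residue interface annotations are not redistributable, so
`synthetic_reference_masks()` reconstructs stand-ins constrained only by the
published aggregate census: 304 interface residues allotted across helices
by largest remainder proportional to length and clipped to 3–10; within a
helix, the top-n residues by `cos(100°·i − face azimuth) + 0.5·depth`
(single interaction face, central bias), with the face azimuth derived from
a stable per-id hash.  These masks carry the right coverage and geometry but
no information about which residues of a given sequence are truly
interfacial; statistics that require the true sequence↔mask correlation
(e.g. the observed interfacial GxxxG percentage) are not expected to match
published values, and the corresponding acceptance checks say so rather than
being skipped.  Notably the geometric shuffle-null for interfacial GxxxG
computes ≈ 20 % with these perfectly face-periodic masks: lag-4 position
pairs are over-represented inside an ideal face relative to real interfaces,
which follow helical periodicity only approximately (a uniform-random mask
of the same coverage would give ≈ 8 %).

## Problem sizes and numerical choices

Tests run the full pipeline at reduced scale — benchmarks of 14–30 TMDs with
60–80-row MSAs, DI recovery over 20 seeded simulations, 200-replicate
randomisation checks — sizes chosen so the complete suite exercises every
stage end-to-end in a few minutes on one core.  Degenerate inputs are
defined rather than crashed on: all-gap columns yield flagged missing
conservation (imputed to 0 in the assembled table), spans shorter than five
fall back to the available pairs in top-k summaries, and empty truth masks
are excluded from BO averaging with a warning.

## Known limitations

- Homologue retrieval and alignment construction are out of scope; the
  package consumes a ready MSA and its quality bounds every evolutionary
  feature.
- The mean-field DCA is the classic naive inversion; no pseudolikelihood
  variant is provided.
- Crystallographic symmetry reconstruction and NMR ensemble averaging are
  not performed; contacts come from the deposited chains of the first model.
- The conservation family approximates rate-based conservation with entropy
  variants; columns with extreme gap content are handled but phylogenetic
  correlation between homologues is ignored beyond sequence reweighting.
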