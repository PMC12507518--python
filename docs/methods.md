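# Methods

## Motif models and log-odds

TF binding preferences are represented as position-specific probability
matrices (PSPMs): `L × 4` for mononucleotide models, `L × 16` for
dinucleotide models over the adjacent-pair alphabet AA, AC, …, TT
(row-major; a matrix with D dinucleotide positions spans D+1 bases).
Matrix files use the plain-text HOCOMOCO dialect (`>name` header followed
by numeric rows); counts and probabilities are auto-detected per record by
whether rows sum to ~1 (tolerance 0.01), since both flavours circulate,
and rows are renormalized either way.

Probabilities are mixed with a uniform pseudocount before the log:
`p' = p·(1 − c·A) + c` with alphabet size `A` and default `c = 0.001`.
Curated matrices routinely contain exact zeros; this keeps every log-odds
finite while shifting well-populated entries by less than the matrices'
own estimation noise. Log-odds are natural-log against the background;
the base is an internal convention — every downstream quantity is either
a CDF value or a min–max-mapped ratio, both base-invariant. The
background defaults to uniform (0.25 per nucleotide); each motif's own
marginal frequencies can be used instead (`--background motif`). For
dinucleotide matrices a 4-symbol background is expanded to the
independent-pair 16-symbol product.

## Exact score distributions and probNorm

The score of a motif placement on background sequence is a sum of
independent per-position terms, so its exact distribution is obtained by
discretizing each weight to a grid of width ε (default 0.001,
round-half-to-even) and convolving one position at a time, starting from
a point mass at zero. For dinucleotide matrices consecutive terms share a
nucleotide, so the dynamic program carries the last nucleotide as state —
initialization puts each first base at its background probability, each
step moves `(x, s) → (y, s + w[j][xy])` with probability `b[y]` — and
marginalizes it at the end. The background sequence model is a zero-order
chain in both cases; first-order backgrounds are a possible extension.

probNorm maps a placement score `s` to `g(s) = P(S ≤ s)`, the CDF of this
distribution. Two numerical choices matter:

* **Discretized scanning.** In probNorm mode sequences are scanned with
  the grid-snapped weights (`round(w/ε)·ε`), not the raw ones, so every
  achievable placement score is an element of the distribution support and
  the CDF lookup is exact — in particular the consensus placement maps to
  exactly 1. Scores between support values take the CDF of the largest
  support value at or below them; a guard of `ε·10⁻⁶` absorbs float
  summation error at bin edges.
* **Granularity.** Per-position rounding error is ≤ ε/2, so total score
  error is ≤ L·ε/2 ≈ 0.01 for typical motif lengths at the default ε.
  A coarser grid can merge distinct sequence scores into one bin, moving
  their CDF values together as a block; the default ε makes such merges
  rare for real-valued matrices. The support size is capped (default
  5·10⁶ bins) with an error suggesting a larger ε.

Distributions are computed once per motif in `prepare_motifs` and reused
for every variant; this amortization is what makes CDF normalization
affordable at large variant counts.

## Scanning, FABIAN normalization and pooling

Scanning computes, for every placement, the sum of weights selected by
the one-hot sequence — a convolution, implemented as `L` vectorized
gathers over a batch of encoded sequences. Both strands are always
scanned (a `forward_only` flag disables this): the reverse strand is
scored by the reverse-complement motif at the same coordinates, which
makes pooled scores independent of reference orientation. Placements
overlapping an ambiguous base (N) are masked (−∞ sentinel) and excluded
from pooling rather than scored, to avoid spurious diffs at assembly
gaps; lowercase (soft-masked) bases are treated as their uppercase
equivalents.

The FABIAN-style normalization shifts each PWM column so its maximum is
zero, sums the shifted column minima into a per-motif factor `F < 0`, and
maps a placement's shifted score `s' ∈ [F, 0]` to `1 − s'/F`. The
orientation — perfect match → 1, worst match → 0 — is this package's
convention, chosen so that Diff signs agree across all modes; endpoint
float round-off is clipped into [0, 1]. A degenerate all-flat motif
(`F = 0`) maps every placement to 1.

Pooling over the placements of one window (both strands jointly) is
either the maximum (best match) or the arithmetic mean of unmasked values
(average occupancy). Average pooling of raw log-odds is rejected: without
a probability-scale normalization the mean of match scores has no natural
interpretation.

## Variant windows and the Diff matrix

For a motif of span `L` the default window is
`[pos − (L−1) − flank, pos + |REF| − 1 + (L−1) + flank]` (1-based
inclusive, `flank = 0` by default), exactly the placements that overlap
the variant; motif positions that cannot see the variant contribute
nothing, and an `extra_flank` option widens the window for applications
where near-miss sites matter. VCF coordinates are 1-based; internal
arithmetic is 0-based half-open with the conversion isolated in
`extract_windows`. REF alleles are validated against the genome;
windows running off a contig are truncated with a warning.

`Diff = pooled(ALT) − pooled(REF)` is antisymmetric under allele swap and
exactly zero for REF == ALT, by construction. Multi-allelic VCF records
are split into bi-allelic variants and scored independently. Indels are
handled by the same construction with unequal window lengths built from
VCF-padded alleles (a 2-bp deletion is a 3-bp REF with a 1-bp ALT
anchor); SNVs are the validated primary path and are scored in vectorized
batches — all interior SNVs share one encoded window matrix per motif
span, and each motif slices its own sub-window from it. 10,000 SNVs ×
100 motifs score in roughly ten seconds on one CPU at default settings,
including the one-off distribution computation.

## Fine-tuning evaluation

The elastic-net layer regresses a measured allelic effect on the full
Diff feature block. Data are split 80/20 into training and holdout with a
fixed seed; the penalty strength (50-point auto-scaled path) and the
L1/L2 mixing ratio (grid {0.1, 0.5, 0.9}) are chosen by 5-fold
cross-validation inside the training split; features are standardized on
the training split (scaler and model are one pipeline, so the holdout
never leaks into either). Missing Diffs are imputed as 0 — a missing
placement means no scoreable binding change — and all-missing columns are
dropped with a warning. Reported metrics are holdout Pearson correlation,
the AUROC of predictions against `sign(effect)` (undefined and reported
as missing when only one sign class is present), and the nonzero
coefficients sorted by magnitude. `single_motif_eval` gives the
no-fitting baseline for one motif column.

## EPPS and the shift test

EPPS is the proportion of strictly positive Diffs among non-zero ones;
exact zeros are neither gain nor loss and are excluded from numerator and
denominator (this matters for small samples and is why tiny columns can
give EPPS of exactly 0 or 1). The shift test defaults to a one-sample
Wilcoxon signed-rank test of the Diffs against location zero, two-sided,
using the normal approximation — discretized scores produce tied absolute
values, which the exact method cannot handle; a two-sample rank-sum test
against a sampled zero-mean normal of matched size and scale is available
(`method="rank_sum_normal"`) for users who prefer an explicit parametric
null. Columns with fewer than `min_n = 10` non-zero values report a
missing p-value; all-zero columns report p = 1. FDR adjustment is
Benjamini–Hochberg across motifs.

## Synthetic data

The generator (`motifdelta.fixtures`) emulates a small slice of a
regulatory-variant study: an i.i.d. genome (default 100 kb at 41% GC,
the human-like value), motifs with a target information content per
position (default 1.6 bits, typical of curated TF models; the consensus
probability is solved from the IC by bisection and the remaining mass
Dirichlet-jittered), consensus sites written into non-overlapping slots,
one site-disrupting SNV per site (consensus base → worst column base) and
background SNVs far from every site, and labels linear in the true Diff
features plus Gaussian noise. Defaults give 20 motifs × 25 sites = 500
destructive SNVs plus 500 background SNVs.

What it does *not* emulate — chromatin context, co-factor logic, linkage
disequilibrium, allele-frequency structure, indel-rich loci — bounds what
passing tests show: they validate the scoring machinery and its
statistics, not predictive performance on in-vivo allelic-effect data.
The regression benchmark task (`make_linear_task`: n = 2000, 200
features, 10 coefficients of ±1, noise scaled to population R² = 0.5)
likewise checks estimator behaviour under a known generative model, not
real-data performance.

## Known limitations

* Mononucleotide and dinucleotide matrices only; no higher-order or
  flexible-length models, no motif discovery or trimming, and no
  JASPAR/MEME parsers.
* Zero-order background for the score distribution; no Markov
  backgrounds.
* No structural variants, phased-haplotype scoring, or liftover; indel
  windows are a natural generalization of the SNV construction but are
  less exercised.
* The FABIAN re-implementation follows the published description of the
  normalization factor; its exact endpoint conventions elsewhere may
  differ from the original tool's internals.
* Scoring is single-threaded (vectorized); the `--threads` flag is
  reserved.
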