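# motifdelta

Fast, interpretable variant-effect scoring with biophysical models of
transcription-factor (TF) binding.

Noncoding variants act in large part by strengthening or weakening TF
binding sites. `motifdelta` quantifies this directly from position weight
matrices: for each variant and each motif it scans the reference (REF) and
alternate (ALT) allele windows, normalizes the match scores onto a
probability scale, pools them, and reports

```
Diff[v, m] = pooled(ALT window) − pooled(REF window)
```

so positive values mean binding gained (constructive) and negative values
binding lost (destructive). Scanning is a vectorized convolution over both
strands, and per-motif score distributions are computed once and reused, so
large variant sets score in seconds.

## The model

A TF motif is a position-specific probability matrix (PSPM) `P`, with
`P[j, i]` the probability of symbol `i` at motif position `j` (4 symbols for
mononucleotide models, 16 adjacent-pair symbols for dinucleotide models).
Against a background distribution `b`, the log-odds weight matrix is
`W[j, i] = log(P'[j, i] / b[i])` (with a small uniform pseudocount `P'`),
and a placement's match score is the sum of its per-position weights.

Raw log-odds differences ignore where on the score axis a change happens,
yet the binding-probability curve `f(s)` is steep only near high scores.
`motifdelta` therefore supports three normalizations of placement scores:

* **none** — raw log-odds (baseline);
* **probnorm** — the score's value under `g(s) = P(S ≤ s)`, the *exact*
  cumulative distribution of the motif score under the background model,
  computed by a per-position dynamic program on a discretized score grid;
* **fabian** — a per-motif min–max rescaling: columns are shifted so their
  maximum is zero, the shifted score is divided by the normalization factor
  `F = Σ_j min_i shifted[j, i]`, and mapped so a perfect match scores 1 and
  the worst match 0.

Pooling is `max` (best match on either strand) or `avg` (occupancy-like
mean over all placements; only meaningful after normalization, so it is
rejected for raw scores).

Two evaluation layers sit on top of the Diff matrix:

* **Elastic-net fine-tuning** — regress a measured allelic effect (e.g. a
  z-score-like `−log10(P)·sign(effect)`) on the full variant × motif Diff
  matrix; report holdout Pearson correlation and the AUROC of predictions
  against the effect sign.
* **EPPS gain/loss analysis** — per motif, the Empirical Probability of
  Positive Shift (proportion of variants with `Diff > 0`; 0.5 under the
  null), a Wilcoxon signed-rank shift test against zero, and
  Benjamini–Hochberg FDR across motifs — the ingredients of a gain/loss
  volcano plot for evolutionary variant sets.

## Worked example

Everything below runs on synthetic data produced by the built-in generator
(`motifdelta.fixtures`); no downloads are needed.

```python
from motifdelta.fixtures import FixtureSpec, plant_sites_and_variants
fx = plant_sites_and_variants("demo_data", FixtureSpec(
    seed=7, n_motifs=5, sites_per_motif=10, n_background_variants=20))
```

This writes a 100 kb genome with 50 planted consensus sites, a VCF with 50
site-disrupting and 20 background SNVs, and the 5 motif matrices. Score it:

```bash
motifdelta score --vcf demo_data/variants.vcf --fasta demo_data/genome.fa \
    --motifs demo_data/motifs.txt --mode probnorm --pool max --out diff.tsv
# parsed 5 motifs from demo_data/motifs.txt
# read 70 bi-allelic variants from demo_data/variants.vcf
# scored 70 variants x 5 motifs in 0.0 s -> diff.tsv
```

`diff.tsv` is a 70 × 5 TSV of Diff values whose `#` header echoes the full
configuration. Site-disrupting variants get negative Diffs for their target
motif; background variants hover near zero. The gain/loss summary:

```bash
motifdelta epps --diff diff.tsv --out epps.tsv
```

```text
motif     n   epps    epps_centered  p_value  fdr_p
MOTIF_03  70  0.5429   0.0429        0.1949   0.4671
MOTIF_02  70  0.4857  -0.0143        0.6045   0.7556
MOTIF_00  70  0.4571  -0.0429        0.7900   0.7900
MOTIF_01  70  0.3857  -0.1143        0.1736   0.4671
MOTIF_04  70  0.3571  -0.1429        0.2803   0.4671
```

Centred EPPS below zero reflects the excess of planted-site-destroying
variants; none of the shifts is FDR-significant at this small n. With
labels that are a (noisy) linear function of the Diff features,
fine-tuning recovers the signal that no single motif explains:

```python
import numpy as np
from motifdelta import DiffMatrix, single_motif_eval
from motifdelta.fixtures import make_labels
diff = DiffMatrix.read("diff.tsv")
labels = make_labels(diff, np.array([2.0, -1.5, 0.0, 1.0, 0.0]),
                     noise_sd=0.0005, seed=1)
labels.to_csv("labels.tsv", sep="\t", index=False)
print(round(single_motif_eval(diff, labels, "MOTIF_00"), 3))  # 0.849
```

```bash
motifdelta finetune --diff diff.tsv --labels labels.tsv --folds 3 --out report.tsv
# holdout correlation 1.0000, sign AUROC 1.0000 (56 train / 14 holdout) -> report.tsv
```

The single best motif correlates at r = 0.849 with the simulated effect,
while the elastic net over all five motif features reaches r ≈ 1.0 on the
holdout — the fine-tuning gap the evaluation layer is designed to measure.

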