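"""REF/ALT window construction and the variant x motif Diff matrix.

For every bi-allelic variant, two sequence windows are cut out of the
reference genome: the reference window as-is and the alternate window
with the ALT allele substituted.  By default the window size is driven by
the motif span L, covering exactly the placements that overlap the
variant — ``[pos - (L-1) - flank, pos + |REF| - 1 + (L-1) + flank]`` in
1-based inclusive coordinates — so motif positions that cannot see the
variant contribute nothing.  An ``extra_flank`` widens the window
symmetrically for users whose downstream task benefits from near-miss
sites.

Both windows are scanned, normalized and pooled identically, and

    Diff[v, m] = pooled(ALT window) - pooled(REF window)

so positive values are constructive (binding gained) and negative values
destructive (binding lost).  Swapping REF and ALT negates the Diff
exactly, and REF == ALT gives exactly zero.

VCF coordinates are 1-based; all internal arithmetic is 0-based
half-open, with the conversion isolated in :func:`extract_windows`.
Indels are handled by the same construction with unequal window lengths;
SNVs are the validated fast path (scored in vectorized batches).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import pysam
from pyfaidx import Fasta

from .motif_io import PSPM, PWM, Background, to_pwm
from .scanning import (
    FabianConstants,
    _scan_matrix,
    encode_sequence,
    normalize,
    pool,
    scan_raw,
)
from .score_distribution import ScoreDistribution, discretize_pwm, exact_distribution

logger = logging.getLogger(__name__)


class VariantValidationError(ValueError):
    """Raised when a variant's REF allele disagrees with the genome."""


@dataclass
class VariantRecord:
    """One bi-allelic variant (VCF conventions: 1-based ``pos``)."""

    chrom: str
    pos: int
    ref: str
    alt: str
    id: str | None = None

    @property
    def key(self) -> str:
        if self.id and self.id != ".":
            return self.id
        return f"{self.chrom}_{self.pos}_{self.ref}_{self.alt}"

    @property
    def is_snv(self) -> bool:
        return len(self.ref) == 1 and len(self.alt) == 1


@dataclass
class PreparedMotif:
    """A motif ready for scanning under one normalization mode.

    For probNorm the scanning weights are snapped to the distribution's
    discretization grid so CDF lookups are exact; for the other modes the
    raw log-odds are used directly.
    """

    name: str
    mode: str
    scan_pwm: PWM
    dist: ScoreDistribution | None = None
    fabian: FabianConstants | None = None

    @property
    def span(self) -> int:
        return self.scan_pwm.span


def prepare_motifs(
    pspms: list[PSPM],
    mode: str = "probnorm",
    background: Background | None = None,
    pseudocount: float = 1e-3,
    granularity: float = 1e-3,
    background_from_motif: bool = False,
) -> list[PreparedMotif]:
    """Turn PSPMs into scan-ready motifs (log-odds + per-mode constants).

    The exact score distribution is computed once per motif here and
    reused for every variant — the cost of the dynamic program is
    amortized over the whole variant set.

    Parameters
    ----------
    background_from_motif : bool
        Use each motif's own marginal symbol frequencies as its
        background instead of the shared (default uniform) one.
    """
    prepared = []
    for pspm in pspms:
        bg = Background.from_pspm(pspm) if background_from_motif else background
        if bg is not None and bg.probs.size == 16:
            raise ValueError("pass the 4-nucleotide background; it is expanded as needed")
        pwm = to_pwm(pspm, background=bg, pseudocount=pseudocount)
        if mode == "probnorm":
            nt_bg = bg if (bg is not None and bg.probs.size == 4) else Background.uniform(4)
            dist = exact_distribution(pwm, background=nt_bg, granularity=granularity)
            prepared.append(
                PreparedMotif(
                    name=pspm.name,
                    mode=mode,
                    scan_pwm=discretize_pwm(pwm, granularity),
                    dist=dist,
                )
            )
        elif mode == "fabian":
            prepared.append(
                PreparedMotif(
                    name=pspm.name,
                    mode=mode,
                    scan_pwm=pwm,
                    fabian=FabianConstants.from_pwm(pwm),
                )
            )
        elif mode == "none":
            prepared.append(PreparedMotif(name=pspm.name, mode=mode, scan_pwm=pwm))
        else:
            raise ValueError(f"unknown normalization mode {mode!r}")
    return prepared


def read_vcf(path: str | Path) -> list[VariantRecord]:
    """Read a VCF into bi-allelic :class:`VariantRecord` objects.

    Multi-allelic records are split into one record per ALT; symbolic and
    breakend alleles are skipped with a warning.
    """
    records: list[VariantRecord] = []
    with pysam.VariantFile(str(path)) as vcf:
        for rec in vcf:
            for alt in rec.alts or ():
                if not alt or any(c not in "ACGTNacgtn" for c in alt):
                    warnings.warn(
                        f"skipping non-sequence ALT {alt!r} at {rec.chrom}:{rec.pos}",
                        stacklevel=2,
                    )
                    continue
                records.append(
                    VariantRecord(
                        chrom=rec.chrom,
                        pos=rec.pos,
                        ref=rec.ref.upper(),
                        alt=alt.upper(),
                        id=rec.id,
                    )
                )
    return records


def extract_windows(
    variant: VariantRecord,
    genome: Fasta,
    motif_span: int,
    extra_flank: int = 0,
) -> tuple[str, str]:
    """REF and ALT windows around a variant for a motif of span L.

    Windows cover every motif placement overlapping the variant plus
    ``extra_flank`` bases on each side; for SNVs both windows have length
    ``2L - 1 + 2*extra_flank``.  Windows running off the contig are
    truncated with a warning.

    Raises
    ------
    VariantValidationError
        If the REF allele does not match the genome at ``pos``.
    """
    if extra_flank < 0:
        raise ValueError("extra_flank must be >= 0")
    contig = genome[variant.chrom]
    contig_len = len(contig)
    pos0 = variant.pos - 1  # 0-based start of REF allele
    if pos0 < 0 or pos0 + len(variant.ref) > contig_len:
        raise VariantValidationError(
            f"variant {variant.key}: position outside contig {variant.chrom}"
        )
    genome_ref = str(contig[pos0 : pos0 + len(variant.ref)]).upper()
    if genome_ref != variant.ref:
        raise VariantValidationError(
            f"variant {variant.key}: REF allele {variant.ref!r} does not match "
            f"genome sequence {genome_ref!r} at {variant.chrom}:{variant.pos}"
        )
    flank = motif_span - 1 + extra_flank
    start = pos0 - flank
    end = pos0 + len(variant.ref) + flank
    if start < 0 or end > contig_len:
        warnings.warn(
            f"variant {variant.key}: window truncated at contig boundary",
            stacklevel=2,
        )
        start = max(start, 0)
        end = min(end, contig_len)
    left = str(contig[start:pos0]).upper()
    right = str(contig[pos0 + len(variant.ref) : end]).upper()
    return left + variant.ref + right, left + variant.alt + right


@dataclass
class DiffMatrix:
    """Variants x motifs table of pooled, normalized ALT - REF differences."""

    data: pd.DataFrame
    metadata: dict = field(default_factory=dict)

    def write(self, path: str | Path) -> None:
        """TSV with '#key=value' metadata comment lines and an 'id' column."""
        with Path(path).open("w") as fh:
            for key, value in self.metadata.items():
                fh.write(f"#{key}={value}\n")
            self.data.to_csv(fh, sep="\t", index_label="id", na_rep="NA")

    @classmethod
    def read(cls, path: str | Path) -> "DiffMatrix":
        metadata = {}
        with Path(path).open() as fh:
            while True:
                offset = fh.tell()
                line = fh.readline()
                if line.startswith("#") and "=" in line:
                    key, value = line[1:].rstrip("\n").split("=", 1)
                    metadata[key] = value
                else:
                    fh.seek(offset)
                    break
            data = pd.read_csv(fh, sep="\t", index_col="id", na_values="NA")
        return cls(data=data, metadata=metadata)


def _pool_rows(values: np.ndarray, method: str) -> np.ndarray:
    """Row-wise pool over placements; all-masked rows give NaN."""
    finite = np.isfinite(values)
    any_finite = finite.any(axis=1)
    out = np.full(values.shape[0], np.nan)
    if method == "max":
        safe = np.where(finite, values, -np.inf)
        out[any_finite] = safe[any_finite].max(axis=1)
    else:
        safe = np.where(finite, values, 0.0)
        counts = finite.sum(axis=1)
        out[any_finite] = safe[any_finite].sum(axis=1) / counts[any_finite]
    return out


def _normalize_batch(raw: np.ndarray, motif: PreparedMotif) -> np.ndarray:
    return normalize(raw, motif.mode, dist=motif.dist, fabian=motif.fabian)


def _score_window_pair(
    ref_window: str,
    alt_window: str,
    motif: PreparedMotif,
    pooling: str,
    forward_only: bool,
) -> float:
    vals = []
    for window in (ref_window, alt_window):
        fwd, rev = scan_raw(window, motif.scan_pwm)
        strands = fwd if forward_only else np.concatenate([fwd, rev])
        vals.append(pool(_normalize_batch(strands, motif), pooling, mode=motif.mode))
    return vals[1] - vals[0]


def score_variants(
    variants: list[VariantRecord] | str | Path,
    genome: Fasta | str | Path,
    motifs: list[PreparedMotif],
    pooling: str = "max",
    extra_flank: int = 0,
    forward_only: bool = False,
) -> DiffMatrix:
    """Score every variant against every motif; return the Diff matrix.

    SNVs away from contig edges share equal-length windows and are scored
    in vectorized batches per motif; indels and edge cases fall back to a
    per-variant path.  Unscoreable variants (e.g. all-N windows) yield
    NaN entries.
    """
    if not motifs:
        raise ValueError("no motifs to score")
    mode = motifs[0].mode
    if any(m.mode != mode for m in motifs):
        raise ValueError("all prepared motifs must share one normalization mode")
    if pooling == "avg" and mode == "none":
        pool(np.array([0.0]), "avg", mode="none")  # raises with the rationale
    if isinstance(variants, (str, Path)):
        variants = read_vcf(variants)
    if isinstance(genome, (str, Path)):
        genome = Fasta(str(genome))

    max_span = max(m.span for m in motifs)
    full_len = 2 * max_span - 1 + 2 * extra_flank

    fast_idx_ref, fast_idx_alt, fast_rows = [], [], []
    slow_rows: list[int] = []
    keys = [v.key for v in variants]
    for i, variant in enumerate(variants):
        if not variant.is_snv:
            slow_rows.append(i)
            continue
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always")
            ref_w, alt_w = extract_windows(variant, genome, max_span, extra_flank)
        if caught or len(ref_w) != full_len:
            slow_rows.append(i)
            continue
        fast_rows.append(i)
        fast_idx_ref.append(encode_sequence(ref_w))
        fast_idx_alt.append(encode_sequence(alt_w))

    values = np.full((len(variants), len(motifs)), np.nan)
    if fast_rows:
        idx_ref = np.vstack(fast_idx_ref)
        idx_alt = np.vstack(fast_idx_alt)
        rows = np.array(fast_rows)
        for j, motif in enumerate(motifs):
            off = max_span - motif.span  # shrink to this motif's own window
            sub_ref = idx_ref[:, off : full_len - off]
            sub_alt = idx_alt[:, off : full_len - off]
            pooled = []
            for sub in (sub_ref, sub_alt):
                fwd = _scan_matrix(sub, motif.scan_pwm)
                if forward_only:
                    strands = fwd
                else:
                    from .motif_io import reverse_complement_motif

                    rev = _scan_matrix(sub, reverse_complement_motif(motif.scan_pwm))
                    strands = np.hstack([fwd, rev])
                pooled.append(_pool_rows(_normalize_batch(strands, motif), pooling))
            values[rows, j] = pooled[1] - pooled[0]

    for i in slow_rows:
        variant = variants[i]
        for j, motif in enumerate(motifs):
            try:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    ref_w, alt_w = extract_windows(variant, genome, motif.span, extra_flank)
            except VariantValidationError:
                raise
            values[i, j] = _score_window_pair(ref_w, alt_w, motif, pooling, forward_only)

    n_missing = int(np.isnan(values).all(axis=1).sum())
    if n_missing:
        logger.info("%d variants produced no scoreable placement", n_missing)

    data = pd.DataFrame(values, index=pd.Index(keys, name="id"), columns=[m.name for m in motifs])
    metadata = {
        "mode": mode,
        "pooling": pooling,
        "extra_flank": extra_flank,
        "forward_only": forward_only,
        "n_variants": len(variants),
        "n_motifs": len(motifs),
    }
    return DiffMatrix(data=data, metadata=metadata)


def write_diff_matrix(diff: DiffMatrix, path: str | Path) -> None:
    """Convenience alias for :meth:`DiffMatrix.write`."""
    diff.write(path)
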