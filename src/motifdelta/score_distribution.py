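"""Exact motif score distributions under a background model.

The match score of a PWM against a random background sequence is a sum of
independent per-position contributions, so its exact distribution can be
computed by a dynamic program: discretize each log-odds weight to a grid
of width ``granularity``, start from a point mass at zero, and convolve in
one position at a time.  The resulting cumulative distribution function
g(s) = P(S <= s) is the basis of the probNorm normalization: a raw match
score is mapped to the probability that a background placement scores no
higher, a monotone [0, 1] rescaling that is comparable across motifs.

Dinucleotide matrices score overlapping nucleotide pairs, so consecutive
contributions share a nucleotide; the dynamic program therefore carries
the identity of the last nucleotide as part of its state and marginalizes
it out at the end.  The background is a zero-order chain over the four
nucleotides in both cases.

Weights are discretized with round-half-to-even (``numpy.round``), and any
consumer that wants exact agreement with the distribution support must
score sequences with the same discretized weights (see
:func:`discretize_pwm`).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .motif_io import PWM, Background

#: refuse dynamic programs whose discretized support would exceed this
DEFAULT_MAX_SUPPORT = 5_000_000


class GranularityError(ValueError):
    """Raised when the requested granularity makes the support explode."""


@dataclass
class ScoreDistribution:
    """Discretized exact distribution of motif match scores.

    Attributes
    ----------
    motif_name : str
    granularity : float
        Score-bin width epsilon.
    support : ndarray
        Ascending achievable (discretized) score values.
    pmf : ndarray
        Probability mass at each support value.
    cdf : ndarray
        Cumulative sums of ``pmf``.
    """

    motif_name: str
    granularity: float
    support: np.ndarray
    pmf: np.ndarray
    cdf: np.ndarray

    def __post_init__(self) -> None:
        if abs(self.pmf.sum() - 1.0) > 1e-9:
            raise ValueError("pmf does not sum to 1")
        if np.any(np.diff(self.support) <= 0):
            raise ValueError("support must be strictly ascending")


def discretize_bins(weights: np.ndarray, granularity: float) -> np.ndarray:
    """Integer bin index of each weight (round half to even)."""
    return np.round(weights / granularity).astype(np.int64)


def discretize_pwm(pwm: PWM, granularity: float) -> PWM:
    """Copy of *pwm* with weights snapped to the discretization grid.

    Scanning with the snapped weights guarantees every placement score is
    (up to float summation error) an element of the distribution support,
    so CDF lookups are exact — in particular the consensus maps to 1.
    """
    weights = discretize_bins(pwm.weights, granularity) * granularity
    return PWM(name=pwm.name, weights=weights, alphabet=pwm.alphabet, source_pspm=pwm.source_pspm)


def _finalize(
    name: str, mass: np.ndarray, lo_bin: int, granularity: float
) -> ScoreDistribution:
    nz = np.flatnonzero(mass)
    support = (lo_bin + nz) * granularity
    pmf = mass[nz]
    pmf = pmf / pmf.sum()  # remove accumulated float drift
    return ScoreDistribution(
        motif_name=name,
        granularity=granularity,
        support=support,
        pmf=pmf,
        cdf=np.cumsum(pmf),
    )


def exact_distribution_mono(
    pwm: PWM,
    background: Background | None = None,
    granularity: float = 1e-3,
    max_support: int = DEFAULT_MAX_SUPPORT,
) -> ScoreDistribution:
    """Exact score distribution of a mononucleotide PWM.

    Convolves the four-point per-position score distributions
    ``{round(w[j][i]/eps)*eps  with prob  background[i]}`` across positions.
    Total mass is conserved at every step.
    """
    if granularity <= 0:
        raise ValueError("granularity must be > 0")
    if pwm.is_dinucleotide:
        raise ValueError("use exact_distribution_di for dinucleotide matrices")
    if background is None:
        background = Background.uniform(4)
    bg = background.probs
    bins = discretize_bins(pwm.weights, granularity)

    span = int((bins.max(axis=1) - bins.min(axis=1)).sum())
    if span + 1 > max_support:
        raise GranularityError(
            f"motif {pwm.name!r}: support size {span + 1} exceeds cap "
            f"{max_support}; use a larger granularity"
        )

    mass = np.array([1.0])
    lo_bin = 0
    for j in range(pwm.length):
        col = bins[j]
        clo, chi = int(col.min()), int(col.max())
        new = np.zeros(mass.size + chi - clo)
        for i in range(4):
            off = int(col[i]) - clo
            new[off : off + mass.size] += mass * bg[i]
        mass = new
        lo_bin += clo
    return _finalize(pwm.name, mass, lo_bin, granularity)


def exact_distribution_di(
    dipwm: PWM,
    background: Background | None = None,
    granularity: float = 1e-3,
    max_support: int = DEFAULT_MAX_SUPPORT,
) -> ScoreDistribution:
    """Exact score distribution of a dinucleotide PWM.

    State is (last nucleotide, discretized score): initialization puts each
    first nucleotide at its background probability with score 0; each
    dinucleotide position transitions (x, s) -> (y, s + w[j][xy]) with
    probability ``background[y]``; the nucleotide state is marginalized at
    the end.
    """
    if granularity <= 0:
        raise ValueError("granularity must be > 0")
    if not dipwm.is_dinucleotide:
        raise ValueError("exact_distribution_di requires a 16-column matrix")
    if background is None:
        background = Background.uniform(4)
    if background.probs.size != 4:
        raise ValueError("dinucleotide DP takes a 4-nucleotide background")
    bg = background.probs
    bins = discretize_bins(dipwm.weights, granularity)

    span = int((bins.max(axis=1) - bins.min(axis=1)).sum())
    if span + 1 > max_support:
        raise GranularityError(
            f"motif {dipwm.name!r}: support size {span + 1} exceeds cap "
            f"{max_support}; use a larger granularity"
        )

    mass = bg[:, None].copy()  # mass[x, bin]: last nucleotide x
    lo_bin = 0
    for j in range(dipwm.length):
        col = bins[j]
        clo, chi = int(col.min()), int(col.max())
        width = mass.shape[1] + chi - clo
        new = np.zeros((4, width))
        for x in range(4):
            for y in range(4):
                off = int(col[4 * x + y]) - clo
                new[y, off : off + mass.shape[1]] += mass[x] * bg[y]
        mass = new
        lo_bin += clo
    return _finalize(dipwm.name, mass.sum(axis=0), lo_bin, granularity)


def exact_distribution(
    pwm: PWM,
    background: Background | None = None,
    granularity: float = 1e-3,
    max_support: int = DEFAULT_MAX_SUPPORT,
) -> ScoreDistribution:
    """Dispatch to the mono- or dinucleotide dynamic program."""
    fn = exact_distribution_di if pwm.is_dinucleotide else exact_distribution_mono
    return fn(pwm, background, granularity, max_support)


def cdf_lookup(dist: ScoreDistribution, score) -> np.ndarray | float:
    """P(S <= score) under the background score distribution.

    Scores that fall between support values take the CDF of the largest
    support value at or below them; below the minimum the CDF is 0, at or
    above the maximum it is 1.  Vectorized over array input.  A guard far
    smaller than one bin absorbs float summation error in scores produced
    from discretized weights.
    """
    scores = np.asarray(score, dtype=float)
    guard = dist.granularity * 1e-6
    idx = np.searchsorted(dist.support, scores + guard, side="right") - 1
    out = np.where(idx >= 0, dist.cdf[np.clip(idx, 0, None)], 0.0)
    if scores.ndim == 0:
        return float(out)
    return out


def save_distribution(dist: ScoreDistribution, path: str | Path) -> None:
    """Write a distribution as a two-column (support, pmf) text table."""
    with Path(path).open("w") as fh:
        fh.write(f"#motif={dist.motif_name}\n#granularity={dist.granularity!r}\n")
        for s, p in zip(dist.support, dist.pmf):
            fh.write(f"{s:.17g}\t{p:.17g}\n")


def load_distribution(path: str | Path) -> ScoreDistribution:
    name, granularity = "", 0.0
    support, pmf = [], []
    with Path(path).open() as fh:
        for line in fh:
            line = line.strip()
            if line.startswith("#motif="):
                name = line.split("=", 1)[1]
            elif line.startswith("#granularity="):
                granularity = float(line.split("=", 1)[1])
            elif line:
                s, p = line.split("\t")
                support.append(float(s))
                pmf.append(float(p))
    pmf_arr = np.array(pmf)
    return ScoreDistribution(
        motif_name=name,
        granularity=granularity,
        support=np.array(support),
        pmf=pmf_arr,
        cdf=np.cumsum(pmf_arr),
    )
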