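"""Sequence encoding, motif scanning, normalization and pooling.

Scanning slides a PWM over a sequence and sums the per-position log-odds
for every placement — a 1-D convolution of the one-hot-encoded sequence
with the weight matrix.  Both strands are scanned by default: the reverse
strand is scored by applying the reverse-complement motif to the same
sequence, which leaves placement coordinates untouched.

Three normalizations of the raw placement scores are supported:

``none``
    Raw log-odds, untouched.
``probnorm``
    The score's percentile under the motif's exact background score
    distribution (its CDF value), a [0, 1] probability-scale quantity.
``fabian``
    A per-motif min–max rescaling: each PWM column is shifted so its
    maximum is zero; the normalization factor F is the sum of the shifted
    column minima (the worst achievable shifted score).  A placement's
    shifted score s' in [F, 0] maps to 1 - s'/F, so a perfect match scores
    1 and the worst match 0.

Pooling reduces the per-placement values of one sequence to a single
number: ``max`` is the best match anywhere on either strand, ``avg`` the
mean over all placements on both strands (an occupancy-like summary).
Averaging raw log-odds has no probabilistic interpretation, so ``avg``
is rejected when the normalization mode is ``none``.  Placements that
overlap an ambiguous base (N) are masked out of both pools.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .motif_io import PWM, reverse_complement_motif
from .score_distribution import ScoreDistribution, cdf_lookup

MODES = ("none", "fabian", "probnorm")
POOLING = ("max", "avg")

_BASE_TO_INDEX = np.full(256, 4, dtype=np.int8)
for _i, _b in enumerate("ACGT"):
    _BASE_TO_INDEX[ord(_b)] = _i
    _BASE_TO_INDEX[ord(_b.lower())] = _i

_COMPLEMENT_IDX = np.array([3, 2, 1, 0, 4], dtype=np.int8)


def encode_sequence(seq: str | np.ndarray) -> np.ndarray:
    """Map a sequence to int8 indices A=0, C=1, G=2, T=3; anything else 4."""
    if isinstance(seq, np.ndarray):
        return seq.astype(np.int8, copy=False)
    return _BASE_TO_INDEX[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def one_hot(seq: str | np.ndarray, dinucleotide: bool = False) -> np.ndarray:
    """Indicator encoding; ambiguous bases give all-zero rows.

    Mono: n x 4.  Dinucleotide: (n-1) x 16 over adjacent pairs.
    """
    idx = encode_sequence(seq)
    if dinucleotide:
        pair = 4 * idx[:-1].astype(np.int16) + idx[1:]
        valid = (idx[:-1] < 4) & (idx[1:] < 4)
        out = np.zeros((idx.size - 1, 16))
        rows = np.flatnonzero(valid)
        out[rows, pair[rows]] = 1.0
        return out
    out = np.zeros((idx.size, 4))
    rows = np.flatnonzero(idx < 4)
    out[rows, idx[rows]] = 1.0
    return out


def _extended_weights(pwm: PWM) -> np.ndarray:
    """Weights with a sentinel symbol column of -inf for ambiguous bases."""
    L, A = pwm.weights.shape
    ext = np.full((L, A + 1), -np.inf)
    ext[:, :A] = pwm.weights
    return ext


def _scan_matrix(idx: np.ndarray, pwm: PWM) -> np.ndarray:
    """Placement scores for a batch of equal-length sequences.

    Parameters
    ----------
    idx : int array of shape (n_seq, n)
        Encoded sequences.
    pwm : PWM

    Returns
    -------
    ndarray of shape (n_seq, n - span + 1); placements touching an N are
    ``-inf``.
    """
    n = idx.shape[1]
    span = pwm.span
    n_place = n - span + 1
    if n_place <= 0:
        return np.empty((idx.shape[0], 0))
    ext = _extended_weights(pwm)
    if pwm.is_dinucleotide:
        pair = np.where(
            (idx[:, :-1] < 4) & (idx[:, 1:] < 4),
            4 * idx[:, :-1].astype(np.int16) + idx[:, 1:],
            16,
        )
        scores = np.zeros((idx.shape[0], n_place))
        for j in range(pwm.length):
            scores += ext[j, pair[:, j : j + n_place]]
        return scores
    scores = np.zeros((idx.shape[0], n_place))
    for j in range(pwm.length):
        scores += ext[j, idx[:, j : j + n_place]]
    return scores


def scan_raw(seq: str | np.ndarray, pwm: PWM) -> tuple[np.ndarray, np.ndarray]:
    """Raw per-placement match scores on the forward and reverse strands.

    Both vectors are indexed by the placement's leftmost position on the
    given sequence; the reverse strand is scored with the
    reverse-complement motif.  Sequences shorter than the motif span give
    empty vectors.
    """
    idx = encode_sequence(seq)[None, :]
    fwd = _scan_matrix(idx, pwm)[0]
    rev = _scan_matrix(idx, reverse_complement_motif(pwm))[0]
    return fwd, rev


@dataclass(frozen=True)
class FabianConstants:
    """Per-motif constants for the min–max normalization.

    ``best_total`` is the sum of column maxima (the consensus raw score);
    ``factor`` is the sum of column minima after shifting each column so
    its maximum is zero — the worst achievable shifted score, <= 0.
    """

    best_total: float
    factor: float

    @classmethod
    def from_pwm(cls, pwm: PWM) -> "FabianConstants":
        col_max = pwm.weights.max(axis=1)
        shifted_min = (pwm.weights - col_max[:, None]).min(axis=1)
        return cls(best_total=float(col_max.sum()), factor=float(shifted_min.sum()))


def normalize(
    raw: np.ndarray,
    mode: str,
    dist: ScoreDistribution | None = None,
    fabian: FabianConstants | None = None,
) -> np.ndarray:
    """Normalize raw placement scores; masked (non-finite) entries stay masked.

    ``probnorm`` requires the motif's :class:`ScoreDistribution`; ``fabian``
    requires the motif's :class:`FabianConstants`.  Masked placements are
    returned as NaN so pooling can skip them.
    """
    if mode not in MODES:
        raise ValueError(f"unknown normalization mode {mode!r}; choose from {MODES}")
    raw = np.asarray(raw, dtype=float)
    if mode == "none":
        return raw.copy()
    mask = np.isfinite(raw)
    out = np.full(raw.shape, np.nan)
    if mode == "probnorm":
        if dist is None:
            raise ValueError("probnorm normalization requires a ScoreDistribution")
        out[mask] = cdf_lookup(dist, raw[mask])
        return out
    if fabian is None:
        raise ValueError("fabian normalization requires FabianConstants")
    if fabian.factor == 0.0:  # degenerate flat motif: every placement is perfect
        out[mask] = 1.0
        return out
    shifted = raw[mask] - fabian.best_total
    # clip absorbs float round-off at the endpoints (e.g. -2e-16 at the worst match)
    out[mask] = np.clip(1.0 - shifted / fabian.factor, 0.0, 1.0)
    return out


def pool(values: np.ndarray, method: str, mode: str | None = None) -> float:
    """Reduce per-placement values (any shape) to one number.

    ``max`` takes the best finite value, ``avg`` the mean of finite
    values.  Returns NaN when every placement is masked.  Average pooling
    of raw log-odds is rejected: without a probability-scale
    normalization, averaging match scores has no natural interpretation.
    """
    if method not in POOLING:
        raise ValueError(f"unknown pooling method {method!r}; choose from {POOLING}")
    if method == "avg" and mode == "none":
        raise ValueError(
            "average pooling of unnormalized scores is not supported: averaging "
            "raw log-odds has no natural interpretation; use --mode probnorm or fabian"
        )
    values = np.asarray(values, dtype=float).ravel()
    finite = values[np.isfinite(values)]
    if finite.size == 0:
        return float("nan")
    return float(finite.max() if method == "max" else finite.mean())


def scan_pool(
    seq: str | np.ndarray,
    pwm: PWM,
    mode: str = "probnorm",
    pooling: str = "max",
    dist: ScoreDistribution | None = None,
    fabian: FabianConstants | None = None,
    forward_only: bool = False,
) -> float:
    """Full single-sequence pipeline: scan both strands, normalize, pool."""
    fwd, rev = scan_raw(seq, pwm)
    strands = fwd if forward_only else np.concatenate([fwd, rev])
    return pool(normalize(strands, mode, dist=dist, fabian=fabian), pooling, mode=mode)
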