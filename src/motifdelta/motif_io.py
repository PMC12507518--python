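"""Parsing and transformation of TF motif matrices.

A transcription factor's sequence preference is modelled by a
position-specific probability matrix (PSPM): one row per motif position,
one column per symbol, each row a probability distribution.  For
mononucleotide models the symbols are A, C, G, T; dinucleotide models use
the 16 adjacent pairs AA..TT (row-major), so a matrix with D dinucleotide
positions describes sites spanning D+1 nucleotides.

Dividing each probability by its background counterpart and taking the
(natural) log turns the PSPM into a position weight matrix (PWM, also
called PSSM) of additive log-odds match scores.

The file format accepted here is the plain-text HOCOMOCO dialect: a header
line starting with ``>`` carrying the motif name, followed by L
whitespace-separated numeric rows.  Rows may hold counts or probabilities;
the two are auto-detected per record by whether rows sum to ~1.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

MONO_ALPHABET: tuple[str, ...] = ("A", "C", "G", "T")
DI_ALPHABET: tuple[str, ...] = tuple(a + b for a in MONO_ALPHABET for b in MONO_ALPHABET)

# complement permutation over A,C,G,T indices
_MONO_COMPLEMENT = np.array([3, 2, 1, 0])
# dinucleotide XY at index 4x+y reverse-complements to comp(Y)comp(X)
_DI_COMPLEMENT = np.array(
    [4 * _MONO_COMPLEMENT[i % 4] + _MONO_COMPLEMENT[i // 4] for i in range(16)]
)

_ROW_SUM_TOL = 0.01  # counts-vs-probabilities auto-detection tolerance


class MotifFormatError(ValueError):
    """Raised when a motif file violates the expected record layout."""


def _alphabet_for(size: int) -> tuple[str, ...]:
    if size == 4:
        return MONO_ALPHABET
    if size == 16:
        return DI_ALPHABET
    raise ValueError(f"alphabet_size must be 4 or 16, got {size}")


@dataclass
class PSPM:
    """Position-specific probability matrix.

    Parameters
    ----------
    name : str
        Motif identifier.
    probs : ndarray of shape (L, A)
        Per-position symbol probabilities; rows are renormalized to sum to
        one at construction.
    alphabet : tuple of str
        Ordered symbols; length 4 (mono) or 16 (dinucleotide).
    """

    name: str
    probs: np.ndarray
    alphabet: tuple[str, ...] = MONO_ALPHABET

    def __post_init__(self) -> None:
        probs = np.asarray(self.probs, dtype=float)
        if probs.ndim != 2 or probs.shape[0] < 1:
            raise ValueError(f"motif {self.name!r}: probs must be a 2-D L x A matrix")
        if probs.shape[1] != len(self.alphabet):
            raise ValueError(
                f"motif {self.name!r}: {probs.shape[1]} columns but alphabet "
                f"has {len(self.alphabet)} symbols"
            )
        if np.any(probs < 0):
            raise ValueError(f"motif {self.name!r}: negative probability entry")
        row_sums = probs.sum(axis=1)
        if np.any(row_sums <= 0):
            raise ValueError(f"motif {self.name!r}: a row sums to zero")
        self.probs = probs / row_sums[:, None]

    @property
    def length(self) -> int:
        """Number of matrix positions (dinucleotide positions for A=16)."""
        return self.probs.shape[0]

    @property
    def is_dinucleotide(self) -> bool:
        return len(self.alphabet) == 16

    def consensus(self) -> str:
        """Most probable sequence symbol per position, concatenated."""
        idx = self.probs.argmax(axis=1)
        return "".join(self.alphabet[i] for i in idx)


@dataclass
class Background:
    """Zero-order background distribution over motif symbols."""

    probs: np.ndarray

    def __post_init__(self) -> None:
        probs = np.asarray(self.probs, dtype=float)
        if probs.ndim != 1:
            raise ValueError("background must be a 1-D probability vector")
        if np.any(probs <= 0):
            raise ValueError("background probabilities must all be > 0")
        if abs(probs.sum() - 1.0) > 1e-9:
            raise ValueError("background probabilities must sum to 1")
        self.probs = probs

    @classmethod
    def uniform(cls, size: int = 4) -> "Background":
        return cls(np.full(size, 1.0 / size))

    @classmethod
    def from_pspm(cls, pspm: PSPM) -> "Background":
        """Marginal symbol frequencies of the PSPM (mean over positions)."""
        marginal = pspm.probs.mean(axis=0)
        marginal = np.clip(marginal, 1e-9, None)
        return cls(marginal / marginal.sum())

    def dinucleotide(self) -> "Background":
        """Independent-pair expansion of a 4-symbol background to 16 symbols."""
        if self.probs.size != 4:
            raise ValueError("dinucleotide expansion requires a 4-symbol background")
        return Background(np.outer(self.probs, self.probs).ravel())


@dataclass
class PWM:
    """Log-odds position weight matrix derived from a :class:`PSPM`."""

    name: str
    weights: np.ndarray
    alphabet: tuple[str, ...] = MONO_ALPHABET
    source_pspm: PSPM | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        weights = np.asarray(self.weights, dtype=float)
        if weights.ndim != 2 or weights.shape[1] != len(self.alphabet):
            raise ValueError(f"motif {self.name!r}: weights shape does not match alphabet")
        if not np.all(np.isfinite(weights)):
            raise ValueError(f"motif {self.name!r}: non-finite log-odds weight")
        self.weights = weights

    @property
    def length(self) -> int:
        return self.weights.shape[0]

    @property
    def is_dinucleotide(self) -> bool:
        return len(self.alphabet) == 16

    @property
    def span(self) -> int:
        """Number of nucleotides covered by one motif placement."""
        return self.length + 1 if self.is_dinucleotide else self.length

    def max_score(self) -> float:
        """Score of the best possible match (column maxima summed)."""
        return float(self.weights.max(axis=1).sum())

    def min_score(self) -> float:
        return float(self.weights.min(axis=1).sum())


def parse_motif_file(path: str | Path, alphabet_size: int = 4) -> list[PSPM]:
    """Parse a plain-text motif file into a list of :class:`PSPM`.

    Records are ``>name`` header lines each followed by numeric rows of
    width *alphabet_size*.  Rows summing to approximately 1 are treated as
    probabilities, anything else as counts; both are normalized per row.

    Raises
    ------
    MotifFormatError
        On a row of the wrong width or a negative entry, naming the motif
        and the offending line number.
    """
    alphabet = _alphabet_for(alphabet_size)
    path = Path(path)
    records: list[PSPM] = []
    name: str | None = None
    rows: list[list[float]] = []

    def flush() -> None:
        nonlocal name, rows
        if name is None:
            return
        if not rows:
            raise MotifFormatError(f"motif {name!r}: record has no matrix rows")
        mat = np.array(rows, dtype=float)
        records.append(PSPM(name=name, probs=mat, alphabet=alphabet))
        name, rows = None, []

    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            if line.startswith(">"):
                flush()
                name = line[1:].strip().split()[0] if line[1:].strip() else f"motif_{lineno}"
                continue
            if name is None:
                raise MotifFormatError(f"line {lineno}: matrix row before any '>' header")
            fields = line.split()
            try:
                values = [float(v) for v in fields]
            except ValueError as exc:
                raise MotifFormatError(
                    f"motif {name!r}, line {lineno}: non-numeric entry"
                ) from exc
            if len(values) != alphabet_size:
                raise MotifFormatError(
                    f"motif {name!r}, line {lineno}: expected {alphabet_size} "
                    f"columns, got {len(values)}"
                )
            if any(v < 0 for v in values):
                raise MotifFormatError(f"motif {name!r}, line {lineno}: negative entry")
            rows.append(values)
    flush()
    if not records:
        warnings.warn(f"{path}: no motif records found", stacklevel=2)
    return records


def write_motif_file(pspms: list[PSPM], path: str | Path) -> None:
    """Serialize PSPMs back to the plain-text record format (probabilities)."""
    with Path(path).open("w") as fh:
        for pspm in pspms:
            fh.write(f">{pspm.name}\n")
            for row in pspm.probs:
                fh.write("\t".join(f"{v:.10g}" for v in row) + "\n")


def to_pwm(
    pspm: PSPM,
    background: Background | None = None,
    pseudocount: float = 1e-3,
) -> PWM:
    """Convert probabilities to natural-log odds against a background.

    A uniform pseudocount mass is mixed in first:
    ``p' = p * (1 - pseudocount * A) + pseudocount`` with A the alphabet
    size, which keeps every log-odds finite when the matrix contains zeros.
    A 4-symbol background is expanded to the independent-pair 16-symbol
    background automatically for dinucleotide matrices.
    """
    A = len(pspm.alphabet)
    if background is None:
        background = Background.uniform(A)
    if background.probs.size == 4 and A == 16:
        background = background.dinucleotide()
    if background.probs.size != A:
        raise ValueError("background size does not match motif alphabet")
    if pseudocount < 0:
        raise ValueError("pseudocount must be >= 0")
    if pseudocount == 0 and np.any(pspm.probs == 0):
        raise ValueError(
            f"motif {pspm.name!r} contains zero probabilities; "
            "a pseudocount > 0 is required for finite log-odds"
        )
    adjusted = pspm.probs * (1.0 - pseudocount * A) + pseudocount
    weights = np.log(adjusted / background.probs)
    return PWM(name=pspm.name, weights=weights, alphabet=pspm.alphabet, source_pspm=pspm)


def reverse_complement_motif(pwm: PWM) -> PWM:
    """Motif scoring the reverse-complement strand.

    Positions are reversed and symbol columns permuted by the complement
    map (dinucleotide XY maps to comp(Y)comp(X)).  Applying twice is the
    identity.
    """
    perm = _DI_COMPLEMENT if pwm.is_dinucleotide else _MONO_COMPLEMENT
    weights = pwm.weights[::-1][:, perm]
    return PWM(
        name=pwm.name,
        weights=weights,
        alphabet=pwm.alphabet,
        source_pspm=pwm.source_pspm,
    )
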