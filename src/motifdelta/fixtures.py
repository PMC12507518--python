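"""Synthetic genomes, motifs, planted sites, variants, and effect labels.

Everything downstream of the scanners can be exercised end-to-end on data
generated here: an i.i.d. background genome at a chosen GC content, random
PSPMs tuned to a target per-position information content, consensus
binding sites written into the genome at recorded positions, SNVs that
either destroy a planted site (consensus base replaced by the worst base
of that column) or fall in neutral background sequence, and effect labels
that are a linear function of the true Diff features plus Gaussian noise.

Defaults mimic a small slice of a mammalian regulatory-variant study: a
100 kb contig at 41% GC, 20 motifs of length 8–12 with ~1.6 bits of
information per position (typical of curated TF models), 25 planted sites
per motif, one site-disrupting SNV per site and an equal number of
background SNVs.  What the generator does *not* emulate: chromatin
context, linkage disequilibrium, indel-rich loci, or motif co-occurrence
structure.

All outputs are deterministic functions of the seed and are valid inputs
for the parsing modules (FASTA, VCF, motif text, TSV).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from pyfaidx import Faidx

from .motif_io import MONO_ALPHABET, PSPM, write_motif_file
from .variant_scoring import DiffMatrix, VariantRecord

_BASES = "ACGT"


@dataclass
class FixtureSpec:
    """Parameters of one synthetic study; deterministic given ``seed``."""

    seed: int = 0
    genome_length: int = 100_000
    gc_content: float = 0.41
    contig_name: str = "chr1"
    n_motifs: int = 20
    motif_length_range: tuple[int, int] = (8, 12)
    information_content: float = 1.6  # bits per position
    sites_per_motif: int = 25
    n_background_variants: int = 500


@dataclass
class PlantedFixture:
    """Paths and truth for one planted-site dataset."""

    fasta: Path
    vcf: Path
    motif_file: Path
    motifs: list[PSPM]
    truth: pd.DataFrame = field(repr=False)


def _composition(gc: float) -> np.ndarray:
    return np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])


def _write_fasta(idx: np.ndarray, path: Path, name: str, width: int = 80) -> None:
    seq = "".join(_BASES[i] for i in idx)
    with path.open("w") as fh:
        fh.write(f">{name}\n")
        for start in range(0, len(seq), width):
            fh.write(seq[start : start + width] + "\n")
    Faidx(str(path))  # build the .fai alongside


def make_genome(
    path: str | Path,
    length: int = 100_000,
    gc: float = 0.41,
    seed: int = 0,
    name: str = "chr1",
) -> Path:
    """Write an i.i.d. random single-contig genome as indexed FASTA."""
    if length < 1000:
        raise ValueError("genome length must be >= 1000")
    rng = np.random.default_rng(seed)
    idx = rng.choice(4, size=length, p=_composition(gc))
    path = Path(path)
    _write_fasta(idx, path, name)
    return path


def _consensus_prob_for_ic(ic_target: float) -> float:
    """Consensus probability whose column information content hits the target.

    Column model: consensus base with probability p, the rest split
    evenly; IC(p) = 2 - H(p) rises monotonically from 0 at p = 1/4 to
    2 bits at p = 1, so bisection suffices.
    """
    ic_target = float(np.clip(ic_target, 0.0, 2.0 - 1e-6))

    def ic(p: float) -> float:
        if p >= 1.0:
            return 2.0
        q = (1.0 - p) / 3.0
        h = -p * np.log2(p) - 3 * q * np.log2(q) if q > 0 else 0.0
        return 2.0 - h

    lo, hi = 0.25, 1.0 - 1e-12
    for _ in range(60):
        mid = (lo + hi) / 2
        if ic(mid) < ic_target:
            lo = mid
        else:
            hi = mid
    return (lo + hi) / 2


def make_motif(
    length: int,
    information_content: float = 1.6,
    seed: int | np.random.Generator = 0,
    name: str = "motif",
) -> PSPM:
    """Random PSPM with per-position entropy tuned toward a target IC.

    Each column places probability p (solved from the IC target) on a
    random consensus base and splits the remainder with a Dirichlet
    jitter, so consensus and worst base are well-defined for IC > 0.
    """
    if not 4 <= length <= 20:
        raise ValueError("motif length must be in [4, 20]")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    p = _consensus_prob_for_ic(information_content)
    probs = np.zeros((length, 4))
    for j in range(length):
        consensus = rng.integers(4)
        rest = (1.0 - p) * rng.dirichlet([10.0, 10.0, 10.0])
        row = np.empty(4)
        row[consensus] = p
        row[[i for i in range(4) if i != consensus]] = rest
        probs[j] = row
    return PSPM(name=name, probs=probs, alphabet=MONO_ALPHABET)


def write_vcf(
    records: list[VariantRecord], path: str | Path, contigs: dict[str, int]
) -> Path:
    """Write a minimal valid VCF 4.2 with contig headers, sorted by position."""
    path = Path(path)
    records = sorted(records, key=lambda r: (r.chrom, r.pos))
    with path.open("w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for name, length in contigs.items():
            fh.write(f"##contig=<ID={name},length={length}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for rec in records:
            fh.write(
                f"{rec.chrom}\t{rec.pos}\t{rec.id or '.'}\t{rec.ref}\t{rec.alt}\t.\t.\t.\n"
            )
    return path


def plant_sites_and_variants(out_dir: str | Path, spec: FixtureSpec) -> PlantedFixture:
    """Build a genome with planted consensus sites and a labelled variant set.

    Consensus sequences of each motif are written into non-overlapping
    genome slots.  The VCF mixes one site-disrupting SNV per planted site
    (a consensus base replaced by the worst base of that column, expected
    Diff sign negative for the target motif) with background SNVs placed
    far from every site (expected Diff centred on zero).  The truth table
    records each variant's class, target motif and expected sign.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(spec.seed)

    lmin, lmax = spec.motif_length_range
    motifs = [
        make_motif(
            length=int(rng.integers(lmin, lmax + 1)),
            information_content=spec.information_content,
            seed=rng,
            name=f"MOTIF_{i:02d}",
        )
        for i in range(spec.n_motifs)
    ]
    max_len = max(m.length for m in motifs)

    genome = rng.choice(4, size=spec.genome_length, p=_composition(spec.gc_content))

    # non-overlapping slots keep sites, variants and their scan windows apart
    slot_pitch = 3 * max_len + 10
    margin = 4 * max_len
    slots = np.arange(margin, spec.genome_length - margin - slot_pitch, slot_pitch)
    n_sites = spec.n_motifs * spec.sites_per_motif
    n_needed = n_sites + spec.n_background_variants
    if len(slots) < n_needed:
        raise ValueError(
            f"genome of {spec.genome_length} bp has room for {len(slots)} sites, "
            f"but {n_needed} are requested"
        )
    chosen = rng.choice(slots, size=n_needed, replace=False)
    site_slots, bg_slots = chosen[:n_sites], chosen[n_sites:]

    variants: list[VariantRecord] = []
    truth_rows = []
    for k, slot in enumerate(site_slots):
        motif = motifs[k % spec.n_motifs]
        consensus = motif.probs.argmax(axis=1)
        genome[slot : slot + motif.length] = consensus
        j = int(rng.integers(motif.length))
        ref_i = int(consensus[j])
        alt_i = int(motif.probs[j].argmin())
        if alt_i == ref_i:  # near-flat column; any other base will do
            alt_i = (ref_i + 1) % 4
        vid = f"dis_{motif.name}_{k:05d}"
        variants.append(
            VariantRecord(
                chrom=spec.contig_name,
                pos=int(slot + j + 1),
                ref=_BASES[ref_i],
                alt=_BASES[alt_i],
                id=vid,
            )
        )
        truth_rows.append(
            {
                "id": vid,
                "class": "site_disrupting",
                "motif": motif.name,
                "expected_sign": -1,
                "site_start": int(slot + 1),
            }
        )
    for k, slot in enumerate(bg_slots):
        j = int(rng.integers(max_len))
        pos0 = int(slot + j)
        ref_i = int(genome[pos0])
        alt_i = int(rng.choice([i for i in range(4) if i != ref_i]))
        vid = f"bg_{k:05d}"
        variants.append(
            VariantRecord(
                chrom=spec.contig_name,
                pos=pos0 + 1,
                ref=_BASES[ref_i],
                alt=_BASES[alt_i],
                id=vid,
            )
        )
        truth_rows.append(
            {
                "id": vid,
                "class": "background",
                "motif": "",
                "expected_sign": 0,
                "site_start": -1,
            }
        )

    fasta_path = out_dir / "genome.fa"
    _write_fasta(genome, fasta_path, spec.contig_name)
    vcf_path = write_vcf(
        variants, out_dir / "variants.vcf", {spec.contig_name: spec.genome_length}
    )
    motif_path = out_dir / "motifs.txt"
    write_motif_file(motifs, motif_path)
    truth = pd.DataFrame(truth_rows)
    truth.to_csv(out_dir / "truth.tsv", sep="\t", index=False)
    return PlantedFixture(
        fasta=fasta_path, vcf=vcf_path, motif_file=motif_path, motifs=motifs, truth=truth
    )


def make_labels(
    diff: DiffMatrix | pd.DataFrame,
    weights: np.ndarray,
    noise_sd: float,
    seed: int = 0,
) -> pd.DataFrame:
    """Effect labels linear in the Diff features: ``effect = Diff @ w + noise``."""
    data = diff.data if isinstance(diff, DiffMatrix) else diff
    weights = np.asarray(weights, dtype=float)
    if weights.size != data.shape[1]:
        raise ValueError(
            f"weight vector length {weights.size} != motif count {data.shape[1]}"
        )
    rng = np.random.default_rng(seed)
    effect = data.fillna(0.0).to_numpy() @ weights + rng.normal(0.0, noise_sd, len(data))
    return pd.DataFrame({"id": data.index, "effect": effect})


def make_linear_task(
    n: int = 2000,
    n_features: int = 200,
    n_informative: int = 10,
    r_squared: float = 0.5,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Sparse linear regression task with a known population R².

    Features are i.i.d. standard normal; ``n_informative`` coefficients
    are ±1 and the noise SD is set so the population R² matches
    ``r_squared``.  Returns (X, y, true support indices).
    """
    rng = np.random.default_rng(seed)
    X = rng.standard_normal((n, n_features))
    support = rng.choice(n_features, size=n_informative, replace=False)
    w = np.zeros(n_features)
    w[support] = rng.choice([-1.0, 1.0], size=n_informative)
    signal_var = float(n_informative)
    noise_sd = np.sqrt(signal_var * (1 - r_squared) / r_squared)
    y = X @ w + rng.normal(0.0, noise_sd, n)
    return X, y, np.sort(support)
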