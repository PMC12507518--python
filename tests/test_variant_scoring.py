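"""Window extraction, Diff-matrix algebra and serialization."""

import numpy as np
import pandas as pd
import pytest
from pyfaidx import Fasta

from motifdelta.fixtures import make_genome, make_motif
from motifdelta.scanning import scan_pool
from motifdelta.variant_scoring import (
    DiffMatrix,
    VariantRecord,
    VariantValidationError,
    extract_windows,
    prepare_motifs,
    score_variants,
)


@pytest.fixture(scope="module")
def genome_path(tmp_path_factory):
    return make_genome(tmp_path_factory.mktemp("g") / "genome.fa", length=5000, seed=3)


@pytest.fixture(scope="module")
def genome(genome_path):
    return Fasta(str(genome_path))


def _variant_at(genome, pos, alt=None):
    ref = str(genome["chr1"][pos - 1]).upper()
    if alt is None:
        alt = {"A": "C", "C": "G", "G": "T", "T": "A"}[ref]
    return VariantRecord(chrom="chr1", pos=pos, ref=ref, alt=alt)


class TestExtractWindows:
    def test_snv_window_length_is_2l_minus_1(self, genome):
        v = _variant_at(genome, 1000)
        ref_w, alt_w = extract_windows(v, genome, motif_span=5)
        assert len(ref_w) == len(alt_w) == 9
        assert ref_w[4] == v.ref and alt_w[4] == v.alt
        assert ref_w[:4] == alt_w[:4] and ref_w[5:] == alt_w[5:]

    def test_extra_flank_widens_symmetrically(self, genome):
        v = _variant_at(genome, 1000)
        ref_w, _ = extract_windows(v, genome, motif_span=5, extra_flank=3)
        assert len(ref_w) == 15

    def test_ref_mismatch_raises_naming_variant(self, genome):
        ref = str(genome["chr1"][499]).upper()
        wrong = {"A": "G", "G": "A", "C": "T", "T": "C"}[ref]
        v = VariantRecord(chrom="chr1", pos=500, ref=wrong, alt="A")
        with pytest.raises(VariantValidationError, match=v.key):
            extract_windows(v, genome, motif_span=5)

    def test_deletion_windows_by_string_surgery(self, genome):
        # 2-bp deletion (VCF-padded: 3-bp REF, 1-bp ALT anchor), L=5:
        # REF window 4+3+4=11 bp, ALT window 4+1+4=9 bp, identical flanks
        pos = 700
        ref_allele = str(genome["chr1"][pos - 1 : pos + 2]).upper()
        v = VariantRecord(chrom="chr1", pos=pos, ref=ref_allele, alt=ref_allele[0])
        ref_w, alt_w = extract_windows(v, genome, motif_span=5)
        assert len(ref_w) == 11 and len(alt_w) == 9
        assert ref_w[:4] == alt_w[:4] and ref_w[-4:] == alt_w[-4:]
        assert ref_w == str(genome["chr1"][pos - 5 : pos + 6]).upper()
        assert alt_w == ref_w[:4] + v.alt + ref_w[-4:]

    def test_contig_edge_truncates_with_warning(self, genome):
        v = _variant_at(genome, 2)
        with pytest.warns(UserWarning, match="truncated"):
            ref_w, _ = extract_windows(v, genome, motif_span=6)
        assert len(ref_w) == 7  # 1 left base available + ref + 5 right

    def test_window_slicing_preserves_variant_overlapping_scores(self, genome):
        """Enlarging extra_flank only adds placements; the central ones keep
        their scores, so under max pooling any Diff change comes from
        placements that do not overlap the variant."""
        from motifdelta.scanning import scan_raw

        motif = make_motif(8, seed=5, name="m")
        (prep,) = prepare_motifs([motif], mode="probnorm")
        v = _variant_at(genome, 1500)
        w0, _ = extract_windows(v, genome, motif_span=prep.span)
        w5, _ = extract_windows(v, genome, motif_span=prep.span, extra_flank=5)
        f0, r0 = scan_raw(w0, prep.scan_pwm)
        f5, r5 = scan_raw(w5, prep.scan_pwm)
        np.testing.assert_array_equal(f5[5:-5], f0)
        np.testing.assert_array_equal(r5[5:-5], r0)


class TestScoreVariants:
    @pytest.fixture(scope="class")
    @staticmethod
    def motifs():
        return [make_motif(int(l), seed=i, name=f"m{i}") for i, l in enumerate([6, 8, 10])]

    def test_identical_alleles_give_exact_zero_row(self, genome_path, genome, motifs):
        v = _variant_at(genome, 1200)
        v = VariantRecord(chrom="chr1", pos=v.pos, ref=v.ref, alt=v.ref)
        prepared = prepare_motifs(motifs, mode="probnorm")
        diff = score_variants([v], genome_path, prepared)
        np.testing.assert_array_equal(diff.data.to_numpy(), np.zeros((1, 3)))

    def test_allele_swap_negates_exactly(self, genome_path, genome, motifs):
        variants = [_variant_at(genome, p) for p in range(900, 1000, 10)]
        swapped = [
            VariantRecord(chrom=v.chrom, pos=v.pos, ref=v.alt, alt=v.ref)
            for v in variants
        ]
        prepared = prepare_motifs(motifs, mode="probnorm")
        fwd = score_variants(variants, genome_path, prepared)
        # swapped REF no longer matches the genome, so score from windows
        for v, s in zip(variants, swapped):
            for prep in prepared:
                ref_w, alt_w = extract_windows(v, genome, prep.span)
                a = scan_pool(alt_w, prep.scan_pwm, dist=prep.dist) - scan_pool(
                    ref_w, prep.scan_pwm, dist=prep.dist
                )
                assert fwd.data.loc[v.key, prep.name] == a
                # swapping the roles of the windows negates the Diff exactly
                b = scan_pool(ref_w, prep.scan_pwm, dist=prep.dist) - scan_pool(
                    alt_w, prep.scan_pwm, dist=prep.dist
                )
                assert b == -a

    @pytest.mark.parametrize(
        "mode,pooling",
        [("probnorm", "max"), ("probnorm", "avg"), ("fabian", "max"), ("none", "max")],
    )
    def test_destroying_planted_consensus_is_destructive(
        self, tmp_path, genome_path, mode, pooling
    ):
        motif = make_motif(9, information_content=1.8, seed=7, name="target")
        consensus = motif.consensus()
        genome = Fasta(str(genome_path))
        seq = str(genome["chr1"][:]).upper()
        start = 2000
        edited = seq[:start] + consensus + seq[start + len(consensus) :]
        fa = tmp_path / f"edited_{mode}_{pooling}.fa"
        fa.write_text(">chr1\n" + edited + "\n")
        j = 4  # central motif position
        ref = consensus[j]
        alt = "ACGT"[int(np.argmin(motif.probs[j]))]
        v = VariantRecord(chrom="chr1", pos=start + j + 1, ref=ref, alt=alt)
        prepared = prepare_motifs([motif], mode=mode)
        diff = score_variants([v], fa, prepared, pooling=pooling)
        assert diff.data.loc[v.key, "target"] < 0

    def test_batched_and_slow_paths_agree(self, genome_path, genome, motifs):
        """Edge-adjacent SNVs take the per-variant path; interior ones the
        vectorized path. Scores must not depend on the path taken."""
        interior = _variant_at(genome, 2500)
        prepared = prepare_motifs(motifs, mode="probnorm")
        batched = score_variants([interior], genome_path, prepared)
        for prep in prepared:
            ref_w, alt_w = extract_windows(interior, genome, prep.span)
            expected = scan_pool(alt_w, prep.scan_pwm, dist=prep.dist) - scan_pool(
                ref_w, prep.scan_pwm, dist=prep.dist
            )
            assert batched.data.loc[interior.key, prep.name] == pytest.approx(
                expected, abs=1e-12
            )

    def test_avg_pooling_with_raw_mode_rejected(self, genome_path, genome, motifs):
        prepared = prepare_motifs(motifs, mode="none")
        with pytest.raises(ValueError, match="no natural interpretation"):
            score_variants([_variant_at(genome, 1100)], genome_path, prepared, pooling="avg")


class TestDiffMatrixIO:
    def test_round_trip_and_na_serialization(self, tmp_path):
        data = pd.DataFrame(
            [[0.123456789012345, np.nan, -1e-7], [1.0, 0.0, 0.5]],
            index=pd.Index(["v1", "v2"], name="id"),
            columns=["mA", "mB", "mC"],
        )
        diff = DiffMatrix(data=data, metadata={"mode": "probnorm", "pool": "max"})
        path = tmp_path / "diff.tsv"
        diff.write(path)
        text = path.read_text()
        assert text.startswith("#mode=probnorm\n#pool=max\n")
        assert "NA" in text
        back = DiffMatrix.read(path)
        assert back.metadata["mode"] == "probnorm"
        assert list(back.data.columns) == ["mA", "mB", "mC"]
        assert back.data.shape == (2, 3)
        np.testing.assert_allclose(
            back.data.to_numpy(), data.to_numpy(), atol=1e-12, equal_nan=True
        )
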