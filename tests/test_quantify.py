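import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mareta import quantify
from mareta.quantify import (
    AVOGADRO,
    BP_MOLAR_MASS_G,
    ContigRecord,
    build_abundance_matrix,
    copies_per_liter,
    filter_alignments,
)

from conftest import make_alignments


class TestFilterAlignments:
    def test_strict_identity_boundary(self):
        """A read at exactly the cutoff is dropped: the rule is strictly >90%."""
        aln = make_alignments([
            ("r1", "c1", "s1", 0.95),
            ("r2", "c1", "s1", 0.90),
        ])
        counts = filter_alignments(aln, 0.90)
        assert counts.set_index(["contig_id", "sample_id"])["mapped_reads"].to_dict() == {
            ("c1", "s1"): 1
        }

    def test_counts_enumerate_passing_records(self):
        aln = make_alignments(
            [(f"r{i}", "c1", "s1", 0.80) for i in range(4)]
            + [(f"q{i}", "c1", "s1", 0.91) for i in range(6)]
        )
        counts = filter_alignments(aln)
        assert counts["mapped_reads"].tolist() == [6]

    def test_unknown_contig_named_in_error(self):
        aln = make_alignments([("r1", "cX", "s1", 0.99)])
        with pytest.raises(ValueError, match="cX"):
            filter_alignments(aln, known_contigs={"c1"})

    def test_identity_out_of_range_rejected(self):
        aln = make_alignments([("r1", "c1", "s1", 1.5)])
        with pytest.raises(ValueError, match="identity"):
            filter_alignments(aln)

    @given(cut_lo=st.floats(0.0, 0.5), delta=st.floats(0.0, 0.5))
    @settings(max_examples=50, deadline=None)
    def test_monotone_in_threshold(self, cut_lo, delta):
        """Lowering the identity cutoff never loses reads."""
        rng = np.random.default_rng(0)
        aln = make_alignments(
            [(f"r{i}", "c1", "s1", float(x)) for i, x in enumerate(rng.uniform(0, 1, 100))]
        )
        hi = min(1.0, cut_lo + delta)
        n_lo = filter_alignments(aln, cut_lo)["mapped_reads"].sum()
        n_hi = filter_alignments(aln, hi)["mapped_reads"].sum() if \
            len(filter_alignments(aln, hi)) else 0
        assert n_lo >= n_hi


class TestCopiesPerLiter:
    def test_printed_constants_worked_example(self):
        """1 ng DNA, 1e3 of 1e6 reads, 1 Mbp target, 1 L -> ~977.27 copies/L."""
        v = copies_per_liter(1e-9, 1000, 10**6, 10**6, 1.0)
        assert v == pytest.approx(977.27, abs=0.005)
        # direct arithmetic with the same constants, written independently
        assert v == pytest.approx(1e-9 * 1e-3 * 6.02e23 / (616 * 1e6))

    def test_zero_mapped_reads(self):
        assert copies_per_liter(1e-9, 0, 10**6, 10**6, 1.0) == 0.0

    @given(
        dna=st.floats(1e-12, 1e-6),
        mapped=st.integers(0, 1000),
        length=st.integers(100, 10**7),
        vol=st.floats(0.1, 100),
    )
    @settings(max_examples=100, deadline=None)
    def test_homogeneity(self, dna, mapped, length, vol):
        """Linear in DNA mass and mapped reads; halving volume doubles it."""
        base = copies_per_liter(dna, mapped, 10**6, length, vol)
        assert copies_per_liter(2 * dna, mapped, 10**6, length, vol) == pytest.approx(2 * base)
        if mapped <= 500:
            assert copies_per_liter(dna, 2 * mapped, 10**6, length, vol) == pytest.approx(2 * base)
        assert copies_per_liter(dna, mapped, 10**6, length, vol / 2) == pytest.approx(2 * base)

    def test_validation(self):
        with pytest.raises(ValueError):
            copies_per_liter(1e-9, 10, 100, 0, 1.0)
        with pytest.raises(ValueError):
            copies_per_liter(1e-9, 10, 100, 1000, 0.0)
        with pytest.raises(ValueError):
            copies_per_liter(1e-9, 200, 100, 1000, 1.0)  # mapped > total


class TestBuildAbundanceMatrix:
    def test_zero_count_cell(self, two_samples):
        counts = pd.DataFrame({"contig_id": [], "sample_id": [], "mapped_reads": []})
        m = build_abundance_matrix(two_samples[:1], [ContigRecord("c1", 100)], counts)
        assert m.shape == (1, 1) and m.iloc[0, 0] == 0.0

    def test_cells_match_scalar_formula(self, two_samples, three_contigs):
        """Matrix equals cell-by-cell application of copies_per_liter."""
        counts = pd.DataFrame(
            {"contig_id": ["c1", "c2", "c3"], "sample_id": ["s1", "s2", "s1"],
             "mapped_reads": [10, 5, 7]}
        )
        m = build_abundance_matrix(two_samples, three_contigs, counts)
        smeta = {s.sample_id: s for s in two_samples}
        cmeta = {c.contig_id: c for c in three_contigs}
        lookup = {(r.contig_id, r.sample_id): r.mapped_reads for r in counts.itertuples()}
        for cid in m.index:
            for sid in m.columns:
                s = smeta[sid]
                expected = copies_per_liter(
                    s.total_dna_g, lookup.get((cid, sid), 0), s.total_reads,
                    cmeta[cid].length_bp, s.water_volume_L,
                )
                assert m.loc[cid, sid] == pytest.approx(expected)

    def test_top_n_rank_and_tiebreak(self, two_samples, three_contigs):
        """Ties in total mapped count break by lexicographic contig id."""
        counts = pd.DataFrame(
            {"contig_id": ["c2", "c1", "c3"], "sample_id": ["s1", "s1", "s1"],
             "mapped_reads": [10, 5, 5]}
        )
        m = build_abundance_matrix(two_samples, three_contigs, counts, top_n=2)
        assert list(m.index) == ["c2", "c1"]

    def test_order_invariance(self, two_samples, three_contigs):
        counts = pd.DataFrame(
            {"contig_id": ["c1", "c2", "c3"], "sample_id": ["s1", "s2", "s1"],
             "mapped_reads": [3, 4, 5]}
        )
        m1 = build_abundance_matrix(two_samples, three_contigs, counts)
        shuffled = counts.sample(frac=1, random_state=1)
        m2 = build_abundance_matrix(two_samples[::-1], three_contigs[::-1], shuffled)
        pd.testing.assert_frame_equal(m1, m2)

    def test_samples_ordered_by_date(self, two_samples, three_contigs):
        counts = pd.DataFrame(
            {"contig_id": ["c1"], "sample_id": ["s1"], "mapped_reads": [1]}
        )
        m = build_abundance_matrix(two_samples[::-1], three_contigs, counts)
        assert list(m.columns) == ["s1", "s2"]

    def test_missing_sample_metadata_listed(self, two_samples, three_contigs):
        counts = pd.DataFrame(
            {"contig_id": ["c1"], "sample_id": ["sX"], "mapped_reads": [1]}
        )
        with pytest.raises(ValueError, match="sX"):
            build_abundance_matrix(two_samples, three_contigs, counts)


def test_metadata_roundtrip(tmp_path, two_samples):
    """Sample TSV stores DNA in ng; loader converts to grams."""
    path = tmp_path / "samples.tsv"
    pd.DataFrame(
        [(s.sample_id, s.station, s.date.isoformat(), s.depth_layer, s.filter_fraction,
          s.water_volume_L, s.total_dna_g * 1e9, s.total_reads) for s in two_samples],
        columns=["sample_id", "station", "date", "depth_layer", "filter_fraction",
                 "water_volume_L", "total_dna_ng", "total_reads"],
    ).to_csv(path, sep="\t", index=False)
    loaded = quantify.read_sample_metadata(path)
    for got, want in zip(loaded, two_samples):
        assert (got.sample_id, got.station, got.date, got.total_reads) == (
            want.sample_id, want.station, want.date, want.total_reads
        )
        assert got.total_dna_g == pytest.approx(want.total_dna_g)
        assert got.water_volume_L == pytest.approx(want.water_volume_L)


def test_read_contigs_fasta(tmp_path):
    fa = tmp_path / "contigs.fa"
    fa.write_text(">c1\nACGTACGT\n>c2\nACGT\n")
    recs = quantify.read_contigs(fa)
    assert [(r.contig_id, r.length_bp) for r in recs] == [("c1", 8), ("c2", 4)]


def test_sam_identity_extraction(tmp_path):
    """NM tag over the alignment span gives the identity fraction."""
    sam = tmp_path / "a.sam"
    sam.write_text(
        "@HD\tVN:1.6\tSO:unknown\n"
        "@SQ\tSN:c1\tLN:100\n"
        "r1\t0\tc1\t1\t60\t10M\t*\t0\t0\tACGTACGTAC\t*\tNM:i:0\n"
        "r2\t0\tc1\t1\t60\t10M\t*\t0\t0\tACGTACGTAC\t*\tNM:i:2\n"
        "r3\t4\t*\t0\t0\t*\t*\t0\t0\tACGT\t*\n"
    )
    df = quantify.read_alignment_sam(sam, "s1")
    by_read = df.set_index("read_id")["identity"]
    assert by_read["r1"] == pytest.approx(1.0)
    assert by_read["r2"] == pytest.approx(0.8)
    assert "r3" not in by_read.index
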