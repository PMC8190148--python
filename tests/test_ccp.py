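import numpy as np
import pandas as pd
import pytest

from mareta.ccp import (
    CCPAssignment,
    PfamProfile,
    ReferenceEntry,
    aggregate_mag_profile,
    annotation_agreement,
    build_reference_db,
    ccp_classify,
    load_reference_db,
    parse_pfam_hits,
    save_reference_db,
)


def _hits(pairs):
    return pd.DataFrame(pairs, columns=["seq_id", "pfam_accession"])


TAX = {"gA": ("Bacteria", "P1", "G1", "S1"), "gB": ("Viruses", "V1", "G2", "S2")}


class TestBuildReferenceDb:
    def test_counts_aggregate(self):
        db = build_reference_db(
            {"gA": _hits([("p1", "PF00001"), ("p2", "PF00001"), ("p1", "PF00002")])},
            {"gA": TAX["gA"]},
        )
        assert db[0].profile.counts == {"PF00001": 2, "PF00002": 1}
        assert db[0].profile.total_domains == 3

    def test_zero_hit_genome_flagged(self):
        db = build_reference_db({"gA": _hits([])}, {"gA": TAX["gA"]})
        assert db[0].zero_domain and db[0].profile.total_domains == 0

    def test_split_tables_summed(self):
        """Two hit tables for one genome behave like their concatenation."""
        t1 = _hits([("p1", "PF00001")])
        t2 = _hits([("p2", "PF00001"), ("p2", "PF00003")])
        split = build_reference_db([("gA", t1), ("gA", t2)], {"gA": TAX["gA"]})
        merged = build_reference_db(
            {"gA": _hits([("p1", "PF00001"), ("p2", "PF00001"), ("p2", "PF00003")])},
            {"gA": TAX["gA"]},
        )
        assert split[0].profile.counts == merged[0].profile.counts

    def test_missing_taxonomy_listed(self):
        with pytest.raises(ValueError, match="gA"):
            build_reference_db({"gA": _hits([("p", "PF00001")])}, {})


class TestParsePfamHits:
    def test_simplified_tsv(self, tmp_path):
        p = tmp_path / "hits.tsv"
        p.write_text("seq_id\tpfam_accession\nc1\tPF00001.12\nc2\tPF00002\n")
        df = parse_pfam_hits(p)
        assert df["pfam_accession"].tolist() == ["PF00001", "PF00002"]

    def test_pfam_scan_style(self, tmp_path):
        p = tmp_path / "scan.txt"
        p.write_text(
            "# pfam_scan.pl output\n"
            "c1   10  50  10  50 PF00001.21  Name  Domain 1 40 0.5 30.1 1e-5 1 No_clan\n"
        )
        df = parse_pfam_hits(p)
        assert df.iloc[0].tolist() == ["c1", "PF00001"]

    def test_malformed_row_has_line_number(self, tmp_path):
        p = tmp_path / "bad.tsv"
        p.write_text("seq_id\tpfam_accession\nonlyonefield\n")
        with pytest.raises(ValueError, match=":2"):
            parse_pfam_hits(p)


class TestAggregateMagProfile:
    def test_sums_member_contigs(self):
        hits = _hits([("c1", "PF1"), ("c2", "PF1"), ("c2", "PF1"), ("c2", "PF2"),
                      ("c9", "PF9")])
        profile = aggregate_mag_profile(hits, ["c1", "c2"])
        assert profile.counts == {"PF1": 3, "PF2": 1}

    def test_hitless_mag_empty(self):
        profile = aggregate_mag_profile(_hits([("cX", "PF1")]), ["c1", "c2"])
        assert len(profile) == 0


def _brute_force_union_pearson(q: dict, ref: dict) -> float:
    """Dense-vector oracle: materialize the union explicitly."""
    keys = sorted(set(q) | set(ref))
    a = np.array([q.get(k, 0) for k in keys], float)
    b = np.array([ref.get(k, 0) for k in keys], float)
    return float(np.corrcoef(a, b)[0, 1])


class TestCcpClassify:
    def setup_method(self):
        self.db = [
            ReferenceEntry("A", ("Bacteria", "P", "G", "Sa"),
                           PfamProfile({"PF1": 10, "PF3": 5})),
            ReferenceEntry("B", ("Viruses", "V", "H", "Sb"),
                           PfamProfile({"PF2": 8, "PF3": 2})),
        ]

    def test_self_match_r_one(self):
        a = ccp_classify(self.db[0].profile, self.db)
        assert a.best_genome_id == "A" and a.r_best == pytest.approx(1.0)

    def test_derived_example_matches_oracle(self):
        query = PfamProfile({"PF1": 9, "PF2": 1, "PF3": 4})
        rA = _brute_force_union_pearson(query.counts, self.db[0].profile.counts)
        rB = _brute_force_union_pearson(query.counts, self.db[1].profile.counts)
        assert rA > rB
        a = ccp_classify(query, self.db)
        assert a.best_genome_id == "A"
        assert a.r_best == pytest.approx(rA)

    def test_scale_invariance(self):
        query = PfamProfile({"PF1": 9, "PF2": 1, "PF3": 4})
        scaled = PfamProfile({k: 10 * v for k, v in query.counts.items()})
        a, b = ccp_classify(query, self.db), ccp_classify(scaled, self.db)
        assert a.best_genome_id == b.best_genome_id
        assert a.r_best == pytest.approx(b.r_best)

    def test_min_domains_floor(self):
        a = ccp_classify(PfamProfile({"PF1": 2, "PF3": 1}), self.db, min_domains=5)
        assert a.best_genome_id == "unclassified" and not a.classified

    def test_tie_broken_by_shared_then_id(self):
        """Identical references: documented tie rule picks lexicographic id."""
        twin = [
            ReferenceEntry("Z", ("Bacteria",), PfamProfile({"PF1": 10, "PF3": 5})),
            ReferenceEntry("Y", ("Bacteria",), PfamProfile({"PF1": 10, "PF3": 5})),
        ]
        a = ccp_classify(PfamProfile({"PF1": 10, "PF3": 5}), twin)
        assert a.best_genome_id == "Y"

    def test_empty_db_error(self):
        with pytest.raises(ValueError):
            ccp_classify(PfamProfile({"PF1": 9}), [])

    def test_runners_up_ordered(self, pfam_sim):
        refs, queries, _ = pfam_sim
        a = ccp_classify(queries[0], refs, top_k=5)
        rs = [r for _, r in a.runners_up]
        assert all(a.r_best >= r for r in rs)
        assert rs == sorted(rs, reverse=True)

    def test_union_matches_oracle_on_fixture(self, pfam_sim):
        refs, queries, _ = pfam_sim
        for q in queries[:10]:
            a = ccp_classify(q, refs[:10])
            best_oracle = max(
                refs[:10],
                key=lambda e: _brute_force_union_pearson(q.counts, e.profile.counts),
            )
            assert a.best_genome_id == best_oracle.genome_id


class TestAnnotationAgreement:
    def _ccp(self, mag_id, lineage):
        return CCPAssignment(mag_id, "g", 0.9, lineage, 10)

    def test_identical_lists(self):
        ccp = [self._ccp("m1", ("Bacteria", "P")), self._ccp("m2", ("Viruses", "V"))]
        blast = [("m1", ("Bacteria", "P")), ("m2", ("Viruses", "V"))]
        frac, _ = annotation_agreement(ccp, blast)
        assert frac == 1.0

    def test_partial_agreement_counts(self):
        ccp = [self._ccp(f"m{i}", ("Bacteria",)) for i in range(4)]
        blast = [("m0", ("Bacteria",)), ("m1", ("Bacteria",)),
                 ("m2", ("Bacteria",)), ("m3", ("Eukaryota",))]
        frac, table = annotation_agreement(ccp, blast)
        assert frac == 0.75
        assert table.loc["Bacteria", "Eukaryota"] == 1

    def test_one_sided_annotations_excluded(self):
        """A MAG annotated by only one method never enters the denominator."""
        ccp = [self._ccp("m1", ("Bacteria",)),
               CCPAssignment("m2", "unclassified", float("nan"), (), 0)]
        blast = [("m1", ("Bacteria",)), ("m3", ("Viruses",))]
        frac, _ = annotation_agreement(ccp, blast)
        assert frac == 1.0

    def test_virus_rank_binary(self):
        ccp = [self._ccp("m1", ("Viruses", "X")), self._ccp("m2", ("Bacteria", "Y"))]
        blast = [("m1", ("Viruses", "Z")), ("m2", ("Eukaryota", "W"))]
        frac, _ = annotation_agreement(ccp, blast, rank="virus")
        assert frac == 1.0  # virus vs cellular agrees on both

    def test_empty_intersection(self):
        with pytest.raises(ValueError, match="no co-annotated"):
            annotation_agreement([self._ccp("m1", ("Bacteria",))], [("m9", ("Bacteria",))])


def test_db_roundtrip_bit_identical(tmp_path, pfam_sim):
    refs, _, _ = pfam_sim
    p1, p2 = tmp_path / "db1.json", tmp_path / "db2.json"
    save_reference_db(refs, p1)
    reloaded = load_reference_db(p1)
    save_reference_db(reloaded, p2)
    assert p1.read_bytes() == p2.read_bytes()
    assert [e.genome_id for e in reloaded] == sorted(e.genome_id for e in refs)
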