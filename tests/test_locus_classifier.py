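"""Host-gene classification, ORF scanning, and domain attachment."""

import pytest

from intronscan.formats_io import TabularHit
from intronscan.locus_classifier import (DomainRow, IntronLocus, ProteinHit,
                                         attach_domains, classify_host,
                                         find_orfs, parse_domain_table,
                                         scan_intron_orfs)
from intronscan.synthetic_genomes import (_random_intron, _rand_seq,
                                          make_host_fixture)

LOCUS = IntronLocus("i1", "g1", 10_000, 10_400)


def _tbl(model, start0, end, target="g1"):
    return TabularHit(target_id=target, model=model, start=start0 + 1, stop=end,
                      strand="+", score=50.0, evalue=1e-10)


class TestClassifyHost:
    def test_rrna_both_sides(self):
        hits = [_tbl("RF00177", 9_200, 10_000), _tbl("RF00177", 10_400, 11_100)]
        hc = classify_host(LOCUS, rrna_hits=hits)
        assert hc.category == "rRNA"
        assert {e.side for e in hc.evidence} == {"5'", "3'"}

    def test_rrna_one_side_only_is_unknown(self):
        hc = classify_host(LOCUS, rrna_hits=[_tbl("RF00177", 9_200, 10_000)])
        assert hc.category == "unknown"

    def test_rrna_needs_same_model_both_sides(self):
        hits = [_tbl("RF00177", 9_200, 10_000), _tbl("RF02541", 10_400, 11_100)]
        assert classify_host(LOCUS, rrna_hits=hits).category == "unknown"

    def test_rrna_hit_outside_flank_ignored(self):
        hits = [_tbl("RF00177", 8_000, 8_900), _tbl("RF00177", 10_400, 11_100)]
        assert classify_host(LOCUS, rrna_hits=hits).category == "unknown"

    def test_tmrna_both_sides(self):
        hits = [_tbl("RF00023", 9_700, 10_000), _tbl("RF00023", 10_400, 10_520)]
        assert classify_host(LOCUS, tmrna_hits=hits).category == "tmRNA"

    def test_tmrna_partial_evidence_flagged(self):
        hits = [_tbl("RF00023", 9_700, 9_990), _tbl("RF00023", 10_405, 10_440)]
        hc = classify_host(LOCUS, tmrna_hits=hits)
        assert hc.category == "tmRNA" and "partial" in hc.note

    def test_cds_same_subject_both_sides(self):
        hits = [ProteinHit("g1", "flagellin", 7_000, 9_800),
                ProteinHit("g1", "flagellin", 10_500, 13_000)]
        assert classify_host(LOCUS, cds_hits=hits).category == "CDS"

    def test_cds_different_subjects_not_enough(self):
        hits = [ProteinHit("g1", "protA", 7_000, 9_800),
                ProteinHit("g1", "protB", 10_500, 13_000)]
        assert classify_host(LOCUS, cds_hits=hits).category == "unknown"

    def test_tnpb_in_vicinity_is_istron_like(self):
        hits = [ProteinHit("g1", "TnpB", 11_200, 12_400)]
        hc = classify_host(LOCUS, tnpb_hits=hits)
        assert hc.category == "IStron-like"

    def test_no_hits_unknown(self):
        hc = classify_host(LOCUS)
        assert hc.category == "unknown" and hc.evidence == ()

    def test_trna_priority_overrides_everything(self):
        hits = [_tbl("RF00177", 9_200, 10_000), _tbl("RF00177", 10_400, 11_100)]
        hc = classify_host(LOCUS, rrna_hits=hits, is_trna=True)
        assert hc.category == "tRNA"

    def test_conflict_resolves_to_higher_priority(self, caplog):
        rrna = [_tbl("RF00177", 9_200, 10_000), _tbl("RF00177", 10_400, 11_100)]
        tnpb = [ProteinHit("g1", "TnpB", 11_200, 12_400)]
        with caplog.at_level("INFO"):
            hc = classify_host(LOCUS, rrna_hits=rrna, tnpb_hits=tnpb)
        assert hc.category == "rRNA"
        assert any("conflicting" in r.message for r in caplog.records)

    def test_planted_categories_fully_recovered(self):
        fx = make_host_fixture(10, seed=17)
        got = {l.intron_id: classify_host(l, fx.rrna_hits, fx.tmrna_hits,
                                          fx.cds_hits, fx.tnpb_hits).category
               for l in fx.loci}
        assert got == fx.truth


def orf_oracle(seq, min_len):
    """Independent three-frame scan."""
    out = set()
    for frame in range(3):
        codons = [seq[i:i + 3] for i in range(frame, len(seq) - 2, 3)]
        start = None
        for k, c in enumerate(codons):
            if start is None and c in ("ATG", "GTG", "TTG"):
                start = frame + 3 * k
            elif start is not None and c in ("TAA", "TAG", "TGA"):
                end = frame + 3 * k + 3
                if end - start >= min_len:
                    out.add((start, end))
                start = None
        if start is not None:
            end = start + (len(seq) - start) // 3 * 3
            if end - start >= min_len:
                out.add((start, end))
    return out


class TestFindOrfs:
    def test_agrees_with_three_frame_oracle(self, rng):
        for _ in range(25):
            seq = _rand_seq(rng, int(rng.integers(100, 2000)))
            got = {(o.start, o.end) for o in find_orfs(seq, 60)}
            assert got == orf_oracle(seq, 60)

    def test_planted_orf_recovered_exactly(self, rng):
        for _ in range(10):
            intron, orf = _random_intron(rng, 700, trap=False, orf_len=330)
            hits = find_orfs(intron, 300)
            assert orf in {(o.start, o.end) for o in hits}

    def test_no_start_codon_no_orfs(self):
        assert find_orfs("CCC" * 200, 60) == []

    def test_sorted_by_length_desc(self, rng):
        seq = _rand_seq(rng, 1500)
        lens = [o.length for o in find_orfs(seq, 30)]
        assert lens == sorted(lens, reverse=True)

    def test_length_gate_for_group1(self, rng):
        intron, _ = _random_intron(rng, 400, trap=False, orf_len=330)
        assert scan_intron_orfs(intron, "groupI") == []       # <= 500 bp: skipped
        long_intron, orf = _random_intron(rng, 700, trap=False, orf_len=330)
        assert scan_intron_orfs(long_intron, "groupI")
        assert scan_intron_orfs(intron, "groupII")            # group II: always


class TestDomains:
    @pytest.fixture()
    def orfs(self, rng):
        intron, _ = _random_intron(rng, 700, trap=False, orf_len=330)
        return find_orfs(intron, 300)

    def test_hnh_label_attached_below_threshold(self, orfs):
        table = [DomainRow(orfs[0].orf_id, "PF01844", "HNH", 1e-10)]
        out = attach_domains(orfs, table)
        assert out[0].domain_label == "HNH"

    def test_above_threshold_ignored(self, orfs):
        table = [DomainRow(orfs[0].orf_id, "PF01844", "HNH", 0.5)]
        out = attach_domains(orfs, table)
        assert out[0].domain_label == ""

    def test_empty_table_no_labels(self, orfs):
        assert all(o.domain_label == "" for o in attach_domains(orfs, []))

    def test_unknown_orf_id_logged_and_skipped(self, orfs, caplog):
        table = [DomainRow("nonexistent", "PF03161", "LAGLIDADG", 1e-12)]
        with caplog.at_level("WARNING"):
            out = attach_domains(orfs, table)
        assert all(o.domain_label == "" for o in out)
        assert any("unknown ORF" in r.message for r in caplog.records)

    @pytest.mark.parametrize("acc,family", [
        ("PF03161", "LAGLIDADG"), ("PF11645", "PD-(D/E)XK"),
        ("PF01844", "HNH"), ("PF00078", "RT")])
    def test_family_mapping(self, orfs, acc, family):
        out = attach_domains(orfs, [DomainRow(orfs[0].orf_id, acc, "x", 1e-9)])
        assert out[0].domain_label == family

    def test_parse_domain_table(self, tmp_path):
        p = tmp_path / "dom.tbl"
        p.write_text("# hmmscan tblout\nHNH PF01844.28 orf1 - 1e-12 55.1\n")
        rows = parse_domain_table(p)
        assert rows == [DomainRow("orf1", "PF01844", "HNH", 1e-12)]
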