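"""Splice-frame enumeration, homolog arbitration, and round-trip integrity."""

import pytest

from intronscan.boundary_resolver import (ExternalPrediction,
                                          IntronCandidate, adjust_external_call,
                                          assign_cau_identity, candidate_from_hit,
                                          enumerate_boundaries, extract_context,
                                          flanking_trna_check, group2_trna_overlap,
                                          resolve)
from intronscan.formats_io import GenomeRecord, revcomp
from intronscan.short_align import TrnaRef
from intronscan.synthetic_genomes import (make_locus_fixture, make_survey,
                                          make_trna, insert_intron, _rand_seq)

PAIRS = {("A", "T"), ("T", "A"), ("G", "C"), ("C", "G"), ("G", "T"), ("T", "G")}


def oracle_frames(context, cand, window=10, min_intron=50):
    """Independent brute force over every (a, b) in the window.

    Re-implements the boundary rules from scratch: exon1 ends in T, intron
    ends in G, and the spliced product folds into a cloverleaf (own pairing
    arithmetic, not the package's) with the junction inside the 7-nt loop.
    """
    def paired(seq, i, j):
        return (seq[i], seq[j]) in PAIRS

    def folds_with_junction(seq, j):
        out = False
        for loop_start in range(j - 6, j):
            if loop_start < 0:
                continue
            for ds in (3, 4):
                for dl in range(7, 12):
                    start = loop_start - (7 + 2 + 2 * ds + dl + 1 + 5)
                    if start < 0:
                        continue
                    for var in range(3, 24):
                        end = loop_start + 7 + 5 + var + 5 + 7 + 5 + 7
                        if end > len(seq):
                            continue
                        region = seq[start:end]
                        if "N" in region[loop_start - start:loop_start - start + 7]:
                            continue
                        # stem intervals relative to start
                        iv = {}
                        p = 0
                        iv["acc5"] = (p, p + 7); p += 7 + 2
                        iv["d5"] = (p, p + ds); p += ds
                        p += dl
                        iv["d3"] = (p, p + ds); p += ds + 1
                        iv["ac5"] = (p, p + 5); p += 5 + 7
                        iv["ac3"] = (p, p + 5); p += 5 + var
                        iv["t5"] = (p, p + 5); p += 5 + 7
                        iv["t3"] = (p, p + 5); p += 5
                        iv["acc3"] = (p, p + 7)
                        ok = True
                        for a5, a3, need in (("acc5", "acc3", 6), ("d5", "d3", ds - 1),
                                             ("ac5", "ac3", 4), ("t5", "t3", 4)):
                            s5, s3 = iv[a5], iv[a3]
                            if "N" in region[s5[0]:s5[1]] + region[s3[0]:s3[1]]:
                                ok = False
                                break
                            n_pair = sum(
                                paired(region, s5[0] + k, s3[1] - 1 - k)
                                for k in range(s5[1] - s5[0]))
                            if n_pair < need:
                                ok = False
                                break
                        if ok:
                            out = True
        return out

    cs, ce = cand
    frames = set()
    for a in range(cs - window, cs + window + 1):
        for b in range(ce - window, ce + window + 1):
            if a < 1 or b > len(context) or b - a < min_intron:
                continue
            if context[a - 1] != "T" or context[b - 1] != "G":
                continue
            spliced = context[:a] + context[b:]
            if folds_with_junction(spliced, a):
                frames.add((a, b))
    return frames


class TestExtractContext:
    def test_plus_strand_arithmetic(self):
        genome = GenomeRecord("g", "A" * 2000)
        cand = IntronCandidate("g", 1000, 1300, "+", "RF00028")
        ctx = extract_context(cand, genome, 400)
        assert (ctx.genome_start, ctx.genome_end) == (600, 1700)
        assert ctx.cand == (400, 700)
        assert not ctx.truncated_5 and not ctx.truncated_3

    def test_minus_strand_round_trip(self, rng):
        seq = _rand_seq(rng, 2000)
        genome = GenomeRecord("g", seq)
        cand = IntronCandidate("g", 1000, 1300, "-", "RF00028")
        ctx = extract_context(cand, genome, 400)
        assert ctx.seq == revcomp(seq[600:1700])
        # the candidate interval maps back onto itself
        assert ctx.to_genome(ctx.cand) == (1000, 1300)
        # and an arbitrary sub-interval round-trips through the sequence
        sub = (410, 450)
        gs, ge = ctx.to_genome(sub)
        assert revcomp(seq[gs:ge]) == ctx.seq[sub[0]:sub[1]]

    def test_contig_end_truncation_flagged(self):
        genome = GenomeRecord("g", "A" * 600)
        cand = IntronCandidate("g", 50, 250, "+", "RF00028")
        ctx = extract_context(cand, genome, 400)
        assert ctx.genome_start == 0 and ctx.truncated_5


class TestFlankingCheck:
    def test_planted_locus_has_trna_both_sides(self, asn_fixture):
        ctx = extract_context(candidate_from_hit(asn_fixture.hit),
                              asn_fixture.genome)
        ok, sides = flanking_trna_check(ctx, asn_fixture.full_db)
        assert ok and sides["5'"] and sides["3'"]

    def test_intron_in_random_sequence_fails(self, rng):
        genome = GenomeRecord("g", _rand_seq(rng, 2000))
        cand = IntronCandidate("g", 800, 1100, "+", "RF00028")
        ctx = extract_context(cand, genome)
        refs = [TrnaRef("r", "Asn", "GTT", make_trna("GTT", 3).seq)]
        ok, _ = flanking_trna_check(ctx, refs)
        assert not ok

    def test_one_sided_fragment_reports_side(self, rng):
        """A 5'-exon fragment without a 3' exon fails, with the side named."""
        t = make_trna("GTT", 8)
        planted = insert_intron(t, "35/36", 300, 9)
        frag = planted.pre_seq[: planted.b]        # exon1 + intron, no exon2
        genome = GenomeRecord("g", _rand_seq(rng, 700) + frag + _rand_seq(rng, 700))
        cand = IntronCandidate("g", 700 + planted.a, 700 + planted.b, "+", "RF00028")
        ctx = extract_context(cand, genome)
        refs = [TrnaRef("r", "Asn", "GTT", t.seq)]
        ok, sides = flanking_trna_check(ctx, refs)
        assert not ok and sides["5'"] == ["r"] and sides["3'"] == []


class TestEnumerateBoundaries:
    def test_planted_frame_found_at_zero_shift(self, asn_fixture):
        ctx = extract_context(candidate_from_hit(asn_fixture.hit),
                              asn_fixture.genome)
        hyps = enumerate_boundaries(ctx.seq, ctx.cand)
        frames = {(h.a - ctx.cand[0], h.b - ctx.cand[1]) for h in hyps}
        assert (0, 0) in frames
        planted = [h for h in hyps if (h.a, h.b) == ctx.cand][0]
        assert planted.site == "35/36" and planted.anticodon == "GTT"

    def test_trap_fixture_contains_both_frames(self):
        fx = make_locus_fixture(21, site="35/36", anticodon="GTT", trap=True,
                                jitter=0, strand="+")
        ctx = extract_context(candidate_from_hit(fx.hit), fx.genome)
        hyps = enumerate_boundaries(ctx.seq, ctx.cand)
        by_frame = {(h.a - ctx.cand[0], h.b - ctx.cand[1]): h for h in hyps}
        assert (0, 0) in by_frame and (-2, -2) in by_frame
        assert by_frame[(0, 0)].site == "35/36"
        assert by_frame[(0, 0)].anticodon == "GTT"
        assert by_frame[(-2, -2)].site == "33/34"
        assert by_frame[(-2, -2)].anticodon == "TGT"

    def test_non_trna_context_yields_nothing(self, rng):
        ctx_seq = _rand_seq(rng, 1000)
        assert enumerate_boundaries(ctx_seq, (400, 700)) == []

    def test_matches_brute_force_oracle(self):
        for seed in range(8):
            fx = make_locus_fixture(seed, jitter=2, strand="+")
            ctx = extract_context(candidate_from_hit(fx.hit), fx.genome)
            hyps = enumerate_boundaries(ctx.seq, ctx.cand)
            assert {(h.a, h.b) for h in hyps} == oracle_frames(ctx.seq, ctx.cand)

    def test_window_monotonicity(self, asn_fixture):
        ctx = extract_context(candidate_from_hit(asn_fixture.hit),
                              asn_fixture.genome)
        small = {(h.a, h.b) for h in enumerate_boundaries(ctx.seq, ctx.cand, 4)}
        large = {(h.a, h.b) for h in enumerate_boundaries(ctx.seq, ctx.cand, 10)}
        assert small <= large


class TestResolve:
    def test_planted_call_recovered(self, asn_fixture):
        call = resolve(candidate_from_hit(asn_fixture.hit), asn_fixture.genome,
                       asn_fixture.full_db)
        t = asn_fixture.truth
        assert call is not None
        assert (call.site, call.anticodon, call.amino_acid) == ("35/36", "GTT", "Asn")
        assert (call.intron_start, call.intron_end) == (t.intron_start, t.intron_end)

    def test_excision_round_trip(self, asn_fixture):
        call = resolve(candidate_from_hit(asn_fixture.hit), asn_fixture.genome,
                       asn_fixture.full_db)
        sub = asn_fixture.genome.seq[call.gene_start:call.gene_end]
        if call.strand == "-":
            sub = revcomp(sub)
        k = call.exon1_len
        assert call.trna_seq[:k] + call.intron_seq + call.trna_seq[k:] == sub

    def test_minus_strand_recovery(self):
        fx = make_locus_fixture(33, site="34/35", anticodon="TAA",
                                jitter=2, strand="-", db_identity=0.92)
        call = resolve(candidate_from_hit(fx.hit), fx.genome, fx.full_db)
        assert call is not None and call.strand == "-"
        assert (call.intron_start, call.intron_end) == (fx.truth.intron_start,
                                                        fx.truth.intron_end)
        assert call.anticodon == "TAA" and call.site == "34/35"

    def test_trap_flips_with_db_content(self):
        fx = make_locus_fixture(44, site="35/36", anticodon="GTT", trap=True,
                                jitter=0)
        full = resolve(candidate_from_hit(fx.hit), fx.genome, fx.full_db)
        ablated = resolve(candidate_from_hit(fx.hit), fx.genome, fx.ablated_db)
        assert (full.site, full.anticodon) == ("35/36", "GTT")
        assert (ablated.site, ablated.anticodon) == ("33/34", "TGT")
        assert full.ambiguous_boundary_resolved

    def test_wrong_genome_is_hard_error(self, asn_fixture):
        other = GenomeRecord("other", asn_fixture.genome.seq)
        with pytest.raises(KeyError):
            resolve(candidate_from_hit(asn_fixture.hit), other,
                    asn_fixture.full_db)

    def test_no_homolog_coverage_returns_none(self, asn_fixture):
        truncated_db = [TrnaRef("frag", "Asn", "GTT",
                                asn_fixture.true_ref.seq[:30])]
        call = resolve(candidate_from_hit(asn_fixture.hit), asn_fixture.genome,
                       truncated_db)
        assert call is None


class TestAdjustExternal:
    def _pred(self, fx, a_off=0, b_off=0):
        t = fx.truth
        genome = fx.genome
        sub = genome.seq[t.gene_start:t.gene_end]
        if t.strand == "-":
            sub = revcomp(sub)
        a = (t.intron_start - t.gene_start if t.strand == "+"
             else t.gene_end - t.intron_end)
        b = a + t.intron_length
        return ExternalPrediction(genome_id=t.genome_id, context_seq=sub,
                                  a=a + a_off, b=b + b_off)

    def test_correct_call_accepted_unchanged(self, asn_fixture):
        pred = self._pred(asn_fixture)
        call = adjust_external_call(pred, asn_fixture.full_db)
        assert call.status == "accepted"
        assert (call.intron_start, call.intron_end) == (pred.a, pred.b)

    def test_shifted_miscall_corrected(self):
        """A Thr(UGU)@33/34-style miscall on a trap locus is corrected to
        Asn(GUU)@35/36 when the database holds the true homolog."""
        fx = make_locus_fixture(55, site="35/36", anticodon="GTT", trap=True,
                                jitter=0, strand="+")
        pred = self._pred(fx, a_off=-2, b_off=-2)      # the shifted frame
        call = adjust_external_call(pred, fx.full_db)
        assert call.status == "adjusted"
        assert (call.site, call.anticodon) == ("35/36", "GTT")

    def test_miscall_with_ablated_db_stays_shifted(self):
        fx = make_locus_fixture(55, site="35/36", anticodon="GTT", trap=True,
                                jitter=0, strand="+")
        pred = self._pred(fx, a_off=-2, b_off=-2)
        call = adjust_external_call(pred, fx.ablated_db)
        assert call.status == "accepted"
        assert (call.site, call.anticodon) == ("33/34", "TGT")

    def test_no_homolog_reports_unverified(self, asn_fixture):
        pred = self._pred(asn_fixture)
        junk_db = [TrnaRef("j", "Gly", "GCC", "ACGT" * 18)]
        call = adjust_external_call(pred, junk_db)
        assert call.status == "unverified"


class TestCauIdentity:
    def _cau_call(self, db_amino):
        fx = make_locus_fixture(66, site="33/34", anticodon="CAT", jitter=0)
        db = [TrnaRef(fx.true_ref.id, db_amino, "CAT", fx.true_ref.seq),
              *fx.decoys]
        call = resolve(candidate_from_hit(fx.hit), fx.genome, db)
        return call, db

    @pytest.mark.parametrize("amino", ["Met", "fMet", "Ile2"])
    def test_identity_copied_from_top_homolog(self, amino):
        call, db = self._cau_call(amino)
        assert call.anticodon == "CAT" and not call.cau_resolved
        resolved = assign_cau_identity(call, db)
        assert resolved.amino_acid == amino and resolved.cau_resolved

    def test_without_cau_reference_left_unresolved(self):
        call, db = self._cau_call("fMet")
        no_cau = [r for r in db if r.anticodon != "CAT"]
        out = assign_cau_identity(call, no_cau)
        assert out.amino_acid == "Met?" and not out.cau_resolved

    def test_non_cau_call_is_precondition_error(self, asn_fixture):
        call = resolve(candidate_from_hit(asn_fixture.hit), asn_fixture.genome,
                       asn_fixture.full_db)
        with pytest.raises(ValueError):
            assign_cau_identity(call, asn_fixture.full_db)


@pytest.fixture(scope="module")
def survey():
    return make_survey(30, seed=5, jitter=0, db_identity=0.95)


class TestGroupII:
    def test_overlapping_pair_yields_group2_call(self, survey):
        calls = group2_trna_overlap(survey.aragorn_introns, survey.rf00029_hits,
                                    survey.genomes, survey.trna_db)
        g2_truth = survey.truth[survey.truth.intron_class == "groupII"]
        assert len(calls) == len(g2_truth) > 0
        assert all(c.intron_class == "groupII" for c in calls)

    def test_sites_match_truth_including_dloop(self, survey):
        calls = group2_trna_overlap(survey.aragorn_introns, survey.rf00029_hits,
                                    survey.genomes, survey.trna_db)
        g2_truth = survey.truth[survey.truth.intron_class == "groupII"]
        got = sorted((c.genome_id, c.site) for c in calls)
        want = sorted(zip(g2_truth.genome_id, g2_truth.site))
        assert got == want

    def test_no_model_overlap_no_call(self, survey):
        calls = group2_trna_overlap(survey.aragorn_introns, [], survey.genomes,
                                    survey.trna_db)
        assert calls == []
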