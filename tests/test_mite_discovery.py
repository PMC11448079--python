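"""Structural MITE discovery: repeats, TSD, TIR, ORFs, folding, linkage."""

import numpy as np
import pytest

from mobilome import mite_discovery as md
from mobilome import element_catalog as ec
from mobilome.genome_io import GenomeRecord, revcomp
from mobilome.synthetic_data import TIR_SEED

from conftest import random_dna

STOPS = {"TAA", "TAG", "TGA"}


def _plant_with_tsd(rng, elem, n, tsd_len=8, flank=3000):
    """Backbone with n copies of elem, each flanked by a duplicated
    target 8-mer, random strands."""
    parts = []
    for _ in range(n):
        fl = random_dna(rng, flank)
        tsd = fl[-tsd_len:] if tsd_len else ""
        e = elem if rng.random() < 0.5 else revcomp(elem)
        parts.append(fl + e + tsd)
    parts.append(random_dna(rng, flank))
    return GenomeRecord("g", "".join(parts))


class TestFindHighCopyRepeats:
    def test_fixture_mite_recovered_with_copy_count(self, small_sim):
        reps = md.find_high_copy_repeats(small_sim.genome_b, min_copies=5)
        mites = [r for r in reps if r.length == 187]
        assert len(mites) == 1
        cand = mites[0]
        assert cand.copy_number == 8
        assert cand.seq in (small_sim.mite_seq, revcomp(small_sim.mite_seq))
        truth = small_sim.truth_elements.query(
            "genome == 'mutant' and element == 'MITE187'"
        )
        assert sorted((l.start, l.end) for l in cand.loci) == sorted(
            zip(truth.start, truth.end)
        )

    def test_random_genome_has_no_repeats(self, rng):
        genome = GenomeRecord("g", random_dna(rng, 100_000))
        assert md.find_high_copy_repeats(genome, min_copies=5) == []

    def test_single_copy_is_not_a_repeat(self, rng):
        genome = GenomeRecord("g", random_dna(rng, 200))
        assert md.find_high_copy_repeats(genome, min_copies=5) == []

    def test_parameter_validation(self, rng):
        genome = GenomeRecord("g", random_dna(rng, 1000))
        with pytest.raises(ValueError):
            md.find_high_copy_repeats(genome, min_len=10)
        with pytest.raises(ValueError):
            md.find_high_copy_repeats(genome, min_copies=1)


class TestDetectTSD:
    def test_constructed_duplication(self, rng):
        left = random_dna(rng, 50) + "ACGTACGT"
        elem = random_dna(rng, 100)
        right = "ACGTACGT" + random_dna(rng, 50)
        genome = GenomeRecord("g", left + elem + right)
        call = md.detect_tsd(genome, (58, 158))
        assert call.present and call.length == 8 and call.seq == "ACGTACGT"
        assert call.left_interval == (50, 58) and call.right_interval == (158, 166)

    def test_absent_when_flanks_unrelated(self):
        genome = GenomeRecord("g", "A" * 20 + "GGGG" + "C" * 20)
        assert not md.detect_tsd(genome, (20, 24)).present

    def test_insufficient_flank_is_an_error_not_absent(self, rng):
        genome = GenomeRecord("g", random_dna(rng, 100))
        with pytest.raises(md.InsufficientFlankError):
            md.detect_tsd(genome, (5, 50))

    def test_fixture_sbp_locus_has_8nt_tsd(self, small_sim):
        row = small_sim.truth_diffs.query(
            "element == 'MITE187' and context == 'intragenic'"
        ).iloc[0]
        start = row.call_start + row.call_end - row.call_start - 187  # element start
        call = md.detect_tsd(small_sim.genome_b, (start, start + 187))
        assert call.present and call.length == 8


def _brute_tir(seq, min_len=7, max_mismatch=2):
    best = None
    for L in range(min_len, len(seq) // 2 + 1):
        a, b = seq[:L], revcomp(seq[-L:])
        mm = sum(x != y for x, y in zip(a, b))
        if mm <= max_mismatch and a[-1] == b[-1] and (best is None or L > best[0]):
            best = (L, mm)
    return best


class TestDetectTIR:
    def test_mite_terminal_seed(self, rng):
        elem = TIR_SEED + random_dna(rng, 150) + revcomp(TIR_SEED)
        call = md.detect_tir(elem)
        assert call.present and call.length >= 9 and call.mismatches == 0

    def test_poly_a_has_no_tir(self):
        assert not md.detect_tir("A" * 100).present

    def test_agrees_with_brute_force(self, rng):
        for _ in range(100):
            seq = random_dna(rng, int(rng.integers(20, 80)))
            call = md.detect_tir(seq)
            brute = _brute_tir(seq)
            if brute is None:
                assert not call.present
            else:
                assert (call.length, call.mismatches) == brute

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            md.detect_tir("ACGTACGTAC", min_len=7)


class TestScanORFs:
    def test_30nt_boundary_orf(self):
        seq = "ATG" + "GCA" * 8 + "TAA"  # exactly 30 nt
        (orf,) = md.scan_orfs(seq, 30)
        assert orf.span_nt == 30 and len(orf.peptide) == 9

    def test_29nt_below_threshold(self):
        seq = "ATG" + "GCA" * 7 + "TAAAA"  # longest ORF span 27 < 30
        assert md.scan_orfs(seq, 30) == []

    def test_minus_strand_coordinates_reversed(self):
        # ORF on the minus strand reports start > end (element residues)
        seq = revcomp("ATG" + "GCA" * 10 + "TAA")
        (orf,) = md.scan_orfs(seq, 30)
        assert orf.strand == "-" and orf.start > orf.end
        assert orf.start == len(seq) and orf.end == 1

    def test_agrees_with_six_frame_oracle(self, rng):
        for _ in range(50):
            seq = random_dna(rng, 300)
            got = {(o.strand, o.frame, o.start, o.end) for o in md.scan_orfs(seq, 30)}
            assert got == _six_frame_oracle(seq, 30)


def _six_frame_oracle(seq, min_len):
    """Exhaustive stop-partition scan, written independently."""
    out = set()
    n = len(seq)
    for strand in "+-":
        s = seq if strand == "+" else revcomp(seq)
        for off in range(3):
            codons = [(i, s[i : i + 3]) for i in range(off, n - 2, 3)]
            segment = []
            for i, c in codons:
                if c in STOPS:
                    atgs = [j for j, cc in segment if cc == "ATG"]
                    if atgs:
                        a, b = atgs[0], i + 3
                        if b - a >= min_len:
                            if strand == "+":
                                out.add((strand, off + 1, a + 1, b))
                            else:
                                out.add((strand, off + 1, n - a, n - b + 1))
                    segment = []
                else:
                    segment.append((i, c))
    return out


def _brute_fold(seq):
    """Exponential enumeration of nested structures (oracle, n <= 14)."""
    pairs = {("A", "T"), ("T", "A"), ("G", "C"), ("C", "G"), ("G", "T"), ("T", "G")}

    def best(i, j):
        if j - i < 4:
            return 0
        score = best(i + 1, j)
        for k in range(i + 4, j + 1):
            if (seq[i], seq[k]) in pairs:
                score = max(score, 1 + best(i + 1, k - 1) + best(k + 1, j))
        return score

    return best(0, len(seq) - 1)


class TestFoldScore:
    def test_simple_hairpin(self):
        assert md.fold_score("GGGAAACCC")[0] == 3

    def test_poly_a_unpaired(self):
        pairs, frac = md.fold_score("A" * 50)
        assert pairs == 0 and frac == 0.0

    def test_perfect_stem(self, rng):
        stem = random_dna(rng, 20)
        seq = stem + "AAAAA" + revcomp(stem)
        assert md.fold_score(seq)[0] == 20

    def test_agrees_with_brute_force(self, rng):
        for _ in range(60):
            n = int(rng.integers(10, 15))
            seq = random_dna(rng, n)
            pairs, frac = md.fold_score(seq)
            assert pairs == _brute_fold(seq)
            assert frac == pytest.approx(2 * pairs / n)


class TestClassifyAndLink:
    def test_fixture_mite_verdict_and_linkage(self, small_sim, small_hits_b):
        reps = md.find_high_copy_repeats(small_sim.genome_b, min_copies=5)
        cand = [r for r in reps if r.length == 187][0]
        md.attach_structure(cand, small_sim.genome_b)
        md.classify_mite(cand)
        assert cand.verdict == "MITE"
        assert cand.tir.length == 9 and cand.tir.mismatches == 1
        assert md.modal_tsd_length(cand.loci) == 8
        assert all(o.span_nt < 600 for o in cand.orfs)
        assert cand.pairing_fraction > 0.5  # hairpin-forming
        fams = {e.name: e.family for e in small_sim.library}
        md.link_family(cand, small_hits_b, small_sim.genome_b, fams)
        assert cand.linked_family == "ISL3" and not cand.linked_ambiguous

    def test_autonomous_element_rejected_as_coding(self, rng, small_sim):
        isl3 = small_sim.element_seqs["ISL3like"]  # 1,215 nt with long ORF
        genome = _plant_with_tsd(rng, isl3, 5)
        loci = []
        pos = 0
        while True:
            pos = genome.seq.find(isl3, pos)
            if pos < 0:
                break
            loci.append(md.RepeatLocus("g", pos, pos + len(isl3), "+"))
            pos += 1
        for p in _find_rc(genome.seq, isl3):
            loci.append(md.RepeatLocus("g", p, p + len(isl3), "-"))
        cand = md.MITECandidate(seq=isl3, loci=loci)
        md.attach_structure(cand, genome)
        md.classify_mite(cand)
        assert cand.verdict == "rejected(coding)"
        assert max(o.span_nt for o in cand.orfs) >= 1000

    def test_tirless_repeat_rejected(self, small_sim, rng):
        is200 = small_sim.element_seqs["IS200like"]
        genome = _plant_with_tsd(rng, is200, 5, tsd_len=0)
        cand = md.MITECandidate(
            seq=is200, loci=[md.RepeatLocus("g", 3000, 3000 + len(is200), "+")]
        )
        md.attach_structure(cand, genome)
        md.classify_mite(cand)
        assert cand.verdict == "rejected(no_TIR)"

    def test_low_copy_rejected(self, rng):
        elem = TIR_SEED + random_dna(rng, 150) + revcomp(TIR_SEED)
        genome = _plant_with_tsd(rng, elem, 2)
        pos = genome.seq.find(elem)
        if pos < 0:
            pos = genome.seq.find(revcomp(elem))
        cand = md.MITECandidate(
            seq=elem, loci=[md.RepeatLocus("g", pos, pos + len(elem), "+")]
        )
        md.attach_structure(cand, genome)
        md.classify_mite(cand, min_copies=5)
        assert cand.verdict == "rejected(low_copy)"

    def test_decoy_family_with_wrong_tsd_not_linked(self, rng):
        """A transposase sharing the TIR seed but with a 4-nt TSD must
        not be linked: the TSD length is the family fingerprint."""
        mite = TIR_SEED + random_dna(rng, 150) + revcomp(TIR_SEED)
        decoy = TIR_SEED + random_dna(rng, 1000) + revcomp(TIR_SEED)
        parts = []
        for _ in range(5):
            fl = random_dna(rng, 2000)
            parts.append(fl + mite + fl[-8:])
        fl = random_dna(rng, 2000)
        parts.append(fl + decoy + fl[-4:] + random_dna(rng, 2000))
        genome = GenomeRecord("g", "".join(parts))
        reps = md.find_high_copy_repeats(genome, min_copies=5)
        cand = [r for r in reps if r.length == len(mite)][0]
        md.attach_structure(cand, genome)
        md.classify_mite(cand)
        hits = ec.match_library(
            genome, [ec.ISElement("decoy", "ISdecoy", decoy)]
        )
        md.link_family(cand, hits, genome, {"decoy": "ISdecoy"})
        assert cand.linked_family is None

    def test_no_shared_seed_means_no_link(self, small_sim, small_hits_b):
        reps = md.find_high_copy_repeats(small_sim.genome_b, min_copies=5)
        cand = [r for r in reps if r.length == 187][0]
        md.attach_structure(cand, small_sim.genome_b)
        fams = {e.name: e.family for e in small_sim.library}
        hits_no_isl3 = [h for h in small_hits_b if h.element != "ISL3like"]
        md.link_family(cand, hits_no_isl3, small_sim.genome_b, fams)
        assert cand.linked_family is None

    def test_mite_verdict_recheck_independent(self, small_sim):
        """Each MITE verdict must satisfy all four criteria on re-check."""
        for cand in md.discover_mites(small_sim.genome_b, min_copies=5):
            if cand.verdict != "MITE":
                continue
            assert cand.tir.present
            assert any(l.tsd.present for l in cand.loci if l.tsd)
            assert all(o.span_nt < 600 for o in cand.orfs)
            assert cand.copy_number >= 5


def _find_rc(hay, elem):
    rc = revcomp(elem)
    out, pos = [], 0
    while True:
        pos = hay.find(rc, pos)
        if pos < 0:
            return out
        out.append(pos)
        pos += 1


class TestStrandInvariance:
    def test_tsd_and_tir_invariant_under_genome_revcomp(self, rng):
        elem = TIR_SEED + random_dna(rng, 120) + revcomp(TIR_SEED)
        left = random_dna(rng, 500)
        tsd = left[-8:]
        genome = GenomeRecord("g", left + elem + tsd + random_dna(rng, 500))
        s, e = 500, 500 + len(elem)
        fwd = md.detect_tsd(genome, (s, e))
        rc_genome = GenomeRecord("g", revcomp(genome.seq))
        n = len(genome.seq)
        mirrored = md.detect_tsd(rc_genome, (n - e, n - s))
        assert fwd.present and mirrored.present
        assert fwd.length == mirrored.length
        assert mirrored.seq == revcomp(fwd.seq)
        t1 = md.detect_tir(elem)
        t2 = md.detect_tir(revcomp(elem))
        assert (t1.present, t1.length, t1.mismatches) == (t2.present, t2.length, t2.mismatches)
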