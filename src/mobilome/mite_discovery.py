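"""De-novo MITE discovery by structural criteria.

A MITE (miniature inverted-repeat transposable element) is a short,
high-copy, non-autonomous element: it carries terminal inverted repeats
(TIRs) and is flanked by target-site duplications (TSDs), but encodes
no transposase of its own. Discovery here follows those structural
criteria directly:

1. mine high-copy identical repeats within a length window,
2. call the TSD at each occurrence (host sequence duplicated on both
   sides of the element; the element interval EXCLUDES the TSD copies),
3. call the TIR (5' prefix vs reverse complement of the 3' suffix),
4. scan ORFs (ATG-only starts, six frames) to rule out coding capacity,
5. score hairpin-forming potential by base-pair maximization,
6. link the MITE to a candidate mobilizing transposase family through
   shared terminal seeds and a matching TSD length.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

from .element_catalog import ElementHit, count_copies
from .genome_io import GenomeRecord, complement_base, revcomp, translate_cds

STOP_CODONS = {"TAA", "TAG", "TGA"}

# Watson-Crick plus the GU wobble (T stands in for U): the fold score
# models the element's RNA hairpin, mirroring how mFOLD is used on MITEs.
_PAIRS = {("A", "T"), ("T", "A"), ("G", "C"), ("C", "G"), ("G", "T"), ("T", "G")}

MIN_LOOP = 3


@dataclass
class TSDCall:
    present: bool
    length: int = 0
    seq: str = ""
    left_interval: tuple[int, int] | None = None
    right_interval: tuple[int, int] | None = None


@dataclass
class TIRCall:
    present: bool
    length: int = 0
    mismatches: int = 0
    left_seq: str = ""
    right_seq: str = ""


@dataclass
class ORFCall:
    """An ORF within an element; 1-based inclusive residue coordinates.

    The span includes the stop codon; on the minus strand start > end
    (ORFfinder's convention, e.g. "starts at residue 38 and ends at
    residue 3").
    """

    strand: str
    frame: int
    start: int
    end: int
    peptide: str

    @property
    def span_nt(self) -> int:
        return abs(self.end - self.start) + 1


@dataclass
class RepeatLocus:
    genome_id: str
    start: int
    end: int
    strand: str
    tsd: TSDCall | None = None


@dataclass
class MITECandidate:
    seq: str
    loci: list[RepeatLocus] = field(default_factory=list)
    tir: TIRCall | None = None
    orfs: list[ORFCall] = field(default_factory=list)
    fold_pairs: int = 0
    pairing_fraction: float = 0.0
    verdict: str = "unclassified"
    linked_family: str | None = None
    linked_ambiguous: bool = False

    @property
    def length(self) -> int:
        return len(self.seq)

    @property
    def copy_number(self) -> int:
        return len(self.loci)


class InsufficientFlankError(ValueError):
    """The locus sits too close to a genome end to evaluate a TSD."""


def find_high_copy_repeats(
    genome: GenomeRecord,
    min_len: int = 80,
    max_len: int = 500,
    min_copies: int = 5,
    k: int = 21,
) -> list[MITECandidate]:
    """Maximal identical repeats in [min_len, max_len] with >= min_copies
    occurrences over both strands, longest first.

    Mining is exact: a 21-mer seed occurring often enough (forward plus
    reverse-complement occurrences) is extended outward while every
    occurrence stays identical. Identical-copy mining is the right model
    for a young MITE family; diverged cross-strain homologs are found by
    element_catalog.match_library at a relaxed identity instead.
    """
    if not (50 <= min_len <= max_len <= 1000):
        raise ValueError("require 50 <= min_len <= max_len <= 1000")
    if min_copies < 2:
        raise ValueError("min_copies must be >= 2")
    seq = genome.seq
    n = len(seq)
    if n < min_len:
        return []

    positions: dict[str, list[int]] = {}
    for i in range(n - k + 1):
        positions.setdefault(seq[i : i + k], []).append(i)

    # Seeds in descending occurrence order: a k-mer straddling a copy's
    # TSD junction is shared by the subset of copies whose TSDs happen to
    # end alike, and extending such a fragment first would shadow the
    # element's own (higher-copy) seeds.
    seeds: list[tuple[int, int, str]] = []
    for kmer, fwd in positions.items():
        rc_kmer = revcomp(kmer)
        if rc_kmer < kmer and rc_kmer in positions:
            continue  # counted at its canonical partner
        rev = positions.get(rc_kmer, []) if rc_kmer != kmer else []
        total = len(fwd) + len(rev)
        if total >= min_copies:
            seeds.append((-total, fwd[0], kmer))
    seeds.sort()

    processed: set[str] = set()
    found: dict[str, MITECandidate] = {}
    for _, _, kmer in seeds:
        if kmer in processed:
            continue
        fwd = positions[kmer]
        rc_kmer = revcomp(kmer)
        rev = positions.get(rc_kmer, []) if rc_kmer != kmer else []
        occ = [(p, "+") for p in fwd] + [(p, "-") for p in rev]
        left, right = _extend_identical(seq, occ, k, max_total=max_len + 1)
        length = k + left + right
        # Mark the repeat's own k-mers so each repeat is reported once.
        p0, s0 = occ[0]
        rep = (
            seq[p0 - left : p0 + k + right]
            if s0 == "+"
            else revcomp(seq[p0 - right : p0 + k + left])
        )
        for i in range(len(rep) - k + 1):
            processed.add(rep[i : i + k])
            processed.add(revcomp(rep[i : i + k]))
        if not (min_len <= length <= max_len):
            continue
        canonical = min(rep, revcomp(rep))
        if canonical in found:
            continue
        loci = []
        for p, strand in occ:
            if strand == "+":
                loci.append(RepeatLocus(genome.id, p - left, p + k + right, "+"))
            else:
                loci.append(RepeatLocus(genome.id, p - right, p + k + left, "-"))
        loci.sort(key=lambda l: l.start)
        found[canonical] = MITECandidate(seq=rep, loci=loci)

    # Suppress junction fragments: a candidate whose sequence contains
    # (or is contained in) a higher-copy candidate is redundant.
    kept: list[MITECandidate] = []
    for cand in sorted(
        found.values(), key=lambda c: (-c.copy_number, -c.length, c.seq)
    ):
        c_rc = revcomp(cand.seq)
        redundant = any(
            cand.seq in k.seq or c_rc in k.seq or k.seq in cand.seq or k.seq in c_rc
            for k in kept
        )
        if not redundant:
            kept.append(cand)
    return sorted(kept, key=lambda c: (-c.length, c.seq))


def _extend_identical(
    seq: str, occ: list[tuple[int, str]], k: int, max_total: int
) -> tuple[int, int]:
    """Extend a seed in element coordinates while all occurrences agree."""

    def char_at(p: str, strand: str, offset: int) -> str | None:
        # offset in element coordinates relative to the seed's first base
        pos = p + offset if strand == "+" else p + k - 1 - offset
        if pos < 0 or pos >= len(seq):
            return None
        c = seq[pos]
        return c if strand == "+" else complement_base(c)

    left = right = 0
    while k + left + right < max_total:
        chars = {char_at(p, s, -(left + 1)) for p, s in occ}
        if None in chars or len(chars) != 1 or "N" in chars:
            break
        left += 1
    while k + left + right < max_total:
        chars = {char_at(p, s, k + right) for p, s in occ}
        if None in chars or len(chars) != 1 or "N" in chars:
            break
        right += 1
    return left, right


def detect_tsd(
    genome: GenomeRecord,
    locus: tuple[int, int],
    w_min: int = 2,
    w_max: int = 16,
) -> TSDCall:
    """Largest w in [w_min, w_max] with identical flanks on both sides.

    The element interval excludes the TSD copies; the left copy is the
    w bases immediately 5' of the locus, the right copy the w bases
    immediately 3'. Insufficient flank is an error, distinct from a
    negative call.
    """
    start, end = locus
    if start < w_max or end + w_max > len(genome.seq):
        raise InsufficientFlankError(
            f"locus ({start}, {end}) needs {w_max} nt of flank on both sides"
        )
    for w in range(w_max, w_min - 1, -1):
        left = genome.seq[start - w : start]
        right = genome.seq[end : end + w]
        if left == right and "N" not in left:
            return TSDCall(
                present=True,
                length=w,
                seq=left,
                left_interval=(start - w, start),
                right_interval=(end, end + w),
            )
    return TSDCall(present=False)


def detect_tir(elem_seq: str, min_len: int = 7, max_mismatch: int = 2) -> TIRCall:
    """Longest ungapped alignment of the 5' prefix against the reverse
    complement of the 3' suffix with <= max_mismatch substitutions.

    The innermost aligned position must be a match: terminal mismatches
    carry no evidence of a repeat and are trimmed, which keeps the
    reported length at the biological TIR boundary.
    """
    if len(elem_seq) < 2 * min_len:
        raise ValueError("element too short for TIR detection")
    best: TIRCall | None = None
    for length in range(min_len, len(elem_seq) // 2 + 1):
        prefix = elem_seq[:length]
        target = revcomp(elem_seq[-length:])
        mism = sum(a != b for a, b in zip(prefix, target))
        if mism <= max_mismatch and prefix[-1] == target[-1]:
            if best is None or length > best.length:
                best = TIRCall(
                    present=True,
                    length=length,
                    mismatches=mism,
                    left_seq=prefix,
                    right_seq=elem_seq[-length:],
                )
    return best if best is not None else TIRCall(present=False)


def scan_orfs(seq: str, min_len_nt: int = 30) -> list[ORFCall]:
    """ATG-initiated ORFs in all six frames, stop codon included in span.

    Per stop codon only the longest ORF (earliest in-frame ATG after the
    previous stop) is reported; ORFs shorter than min_len_nt or lacking
    a stop within the sequence are excluded. Coordinates are 1-based
    residues within the element, start > end on the minus strand.
    """
    if min_len_nt < 6:
        raise ValueError("min_len_nt must be >= 6")
    n = len(seq)
    calls: list[ORFCall] = []
    for strand in "+-":
        s = seq if strand == "+" else revcomp(seq)
        for offset in range(3):
            atg: int | None = None
            for i in range(offset, n - 2, 3):
                codon = s[i : i + 3]
                if codon == "ATG" and atg is None:
                    atg = i
                if codon in STOP_CODONS:
                    if atg is not None and i + 3 - atg >= min_len_nt:
                        calls.append(_make_orf(s, strand, offset, atg, i + 3, n))
                    atg = None
    calls.sort(key=lambda o: (-o.span_nt, o.strand, o.frame, o.start))
    return calls


def _make_orf(s: str, strand: str, offset: int, a: int, b: int, n: int) -> ORFCall:
    peptide = translate_cds(s[a:b])[:-1]
    if strand == "+":
        start, end = a + 1, b
    else:
        # map back to the original orientation: rc position i -> n - i
        start, end = n - a, n - b + 1
    return ORFCall(strand=strand, frame=offset + 1, start=start, end=end, peptide=peptide)


def fold_score(seq: str) -> tuple[int, float]:
    """Maximum nested Watson-Crick + GU pairs (Nussinov), min loop 3.

    Returns (max_pairs, pairing_fraction = 2*max_pairs/len). A stand-in
    for full thermodynamic folding: a MITE's hairpin shows up as a high
    pairing fraction without needing an energy model.
    """
    n = len(seq)
    if n == 0:
        raise ValueError("empty sequence")
    if n < MIN_LOOP + 2:  # cannot form any pair
        return 0, 0.0
    dp = [[0] * n for _ in range(n)]
    for span in range(MIN_LOOP + 1, n):
        for i in range(n - span):
            j = i + span
            best = max(dp[i + 1][j], dp[i][j - 1])
            if (seq[i], seq[j]) in _PAIRS:
                best = max(best, dp[i + 1][j - 1] + 1)
            for t in range(i + 1, j):
                cand = dp[i][t] + dp[t + 1][j]
                if cand > best:
                    best = cand
            dp[i][j] = best
    pairs = dp[0][n - 1]
    return pairs, 2 * pairs / n


def attach_structure(
    candidate: MITECandidate,
    genome: GenomeRecord,
    tir_min_len: int = 7,
    tir_max_mismatch: int = 2,
    tsd_w_min: int = 2,
    tsd_w_max: int = 16,
    orf_min_len_nt: int = 30,
) -> MITECandidate:
    """Populate TSD calls, TIR, ORFs and fold score for a candidate."""
    for locus in candidate.loci:
        try:
            locus.tsd = detect_tsd(genome, (locus.start, locus.end), tsd_w_min, tsd_w_max)
        except InsufficientFlankError:
            locus.tsd = TSDCall(present=False)
    candidate.tir = detect_tir(candidate.seq, tir_min_len, tir_max_mismatch)
    candidate.orfs = scan_orfs(candidate.seq, orf_min_len_nt)
    candidate.fold_pairs, candidate.pairing_fraction = fold_score(candidate.seq)
    return candidate


def modal_tsd_length(loci: Sequence[RepeatLocus]) -> int:
    lengths = [l.tsd.length for l in loci if l.tsd is not None and l.tsd.present]
    if not lengths:
        return 0
    return max(set(lengths), key=lambda x: (lengths.count(x), x))


def classify_mite(
    candidate: MITECandidate,
    transposase_orf_min_nt: int = 600,
    min_copies: int = 5,
) -> MITECandidate:
    """Apply the MITE verdict rule.

    MITE iff: TIR present AND >= 1 TSD-positive locus AND no ORF long
    enough to encode a transposase AND enough copies. Otherwise rejected
    with the first failed criterion.
    """
    if candidate.tir is None:
        raise ValueError("candidate structure not populated; call attach_structure")
    if not candidate.tir.present:
        candidate.verdict = "rejected(no_TIR)"
    elif not any(l.tsd is not None and l.tsd.present for l in candidate.loci):
        candidate.verdict = "rejected(no_TSD)"
    elif any(o.span_nt >= transposase_orf_min_nt for o in candidate.orfs):
        candidate.verdict = "rejected(coding)"
    elif candidate.copy_number < min_copies:
        candidate.verdict = "rejected(low_copy)"
    else:
        candidate.verdict = "MITE"
    return candidate


def _hamming(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


def link_family(
    mite: MITECandidate,
    element_hits: Sequence[ElementHit],
    genome: GenomeRecord,
    families: dict[str, str],
    seed_len: int = 9,
    max_mismatch: int = 1,
    tsd_w_min: int = 2,
    tsd_w_max: int = 16,
) -> MITECandidate:
    """Assign the transposase family likely to mobilize the MITE.

    A family qualifies when at least one of its hits carries termini
    matching the MITE's TIR seeds (<= max_mismatch at each end, element
    orientation) AND that hit's own TSD length equals the MITE's modal
    TSD length. Several qualifying families are all reported, flagged
    ambiguous.
    """
    mite_5p = mite.seq[:seed_len]
    mite_3p = mite.seq[-seed_len:]
    mite_tsd = modal_tsd_length(mite.loci)
    qualifying: list[str] = []
    for hit in element_hits:
        family = families.get(hit.element, "unknown")
        if family in qualifying:
            continue
        if hit.strand == "+":
            left = genome.seq[hit.start : hit.start + seed_len]
            right = genome.seq[hit.end - seed_len : hit.end]
        else:
            left = revcomp(genome.seq[hit.end - seed_len : hit.end])
            right = revcomp(genome.seq[hit.start : hit.start + seed_len])
        if _hamming(left, mite_5p) > max_mismatch or _hamming(right, mite_3p) > max_mismatch:
            continue
        try:
            tsd = detect_tsd(genome, (hit.start, hit.end), tsd_w_min, tsd_w_max)
        except InsufficientFlankError:
            continue
        if tsd.present and tsd.length == mite_tsd:
            qualifying.append(family)
    if len(qualifying) == 1:
        mite.linked_family = qualifying[0]
        mite.linked_ambiguous = False
    elif qualifying:
        mite.linked_family = ",".join(sorted(qualifying))
        mite.linked_ambiguous = True
    else:
        mite.linked_family = None
    return mite


def discover_mites(
    genome: GenomeRecord,
    element_hits: Sequence[ElementHit] = (),
    families: dict[str, str] | None = None,
    min_len: int = 80,
    max_len: int = 500,
    min_copies: int = 5,
    transposase_orf_min_nt: int = 600,
) -> list[MITECandidate]:
    """End-to-end MITE discovery on one genome."""
    candidates = find_high_copy_repeats(genome, min_len, max_len, min_copies)
    out = []
    for cand in candidates:
        attach_structure(cand, genome)
        classify_mite(cand, transposase_orf_min_nt, min_copies)
        if cand.verdict == "MITE" and element_hits and families:
            link_family(cand, element_hits, genome, families)
        out.append(cand)
    return out


def count_mite_copies(genome: GenomeRecord, mite_seq: str) -> int:
    """Exact-copy count of a MITE sequence (both strands, non-overlapping)."""
    return count_copies(genome, mite_seq, mode="exact")
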