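"""Anchor-based structural comparison of two near-identical assemblies.

Instead of full whole-genome alignment, the comparison rests on k-mers
that are unique in both genomes (counting both strands). In a pair of
assemblies that are ~99.9% identical, unique k-mers tile essentially
every non-repetitive position, and the repeats — the mobile elements of
interest — fall between anchors by construction. Maximal co-diagonal
runs of matched unique k-mers become anchors; inversions appear as runs
of inverted-orientation anchors, and strain-specific insertions appear
as one-sided gaps between adjacent same-orientation anchors.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .element_catalog import count_copies
from .genome_io import GenomeRecord, revcomp

_CODE = np.full(256, -1, dtype=np.int64)
for i, b in enumerate(b"ACGT"):
    _CODE[b] = i


def _kmer_values(seq: str, k: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(forward values, revcomp values, validity mask) for all k-mers."""
    codes = _CODE[np.frombuffer(seq.encode(), dtype=np.uint8)]
    n = len(codes)
    if n < k:
        empty = np.empty(0, dtype=np.int64)
        return empty, empty, np.empty(0, dtype=bool)
    valid_base = codes >= 0
    codes_clipped = np.where(valid_base, codes, 0)
    powers = 4 ** np.arange(k - 1, -1, -1, dtype=np.int64)
    windows = np.lib.stride_tricks.sliding_window_view(codes_clipped, k)
    vals = windows @ powers
    rc_windows = np.lib.stride_tricks.sliding_window_view(3 - codes_clipped, k)
    rcvals = rc_windows @ powers[::-1]
    # a window is valid iff it contains no N
    ok = (
        np.lib.stride_tricks.sliding_window_view(valid_base.astype(np.int64), k).sum(
            axis=1
        )
        == k
    )
    return vals, rcvals, ok


def _unique_canonical(seq: str, k: int):
    """Map canonical k-mer value -> (position, strand) for k-mers whose
    combined forward+revcomp occurrence count in the genome is exactly 1."""
    vals, rcvals, ok = _kmer_values(seq, k)
    canon = np.minimum(vals, rcvals)
    strand_fwd = vals <= rcvals
    canon_ok = canon[ok]
    uniq, counts = np.unique(canon_ok, return_counts=True)
    unique_set = uniq[counts == 1]
    pos = np.nonzero(ok)[0]
    mask = np.isin(canon_ok, unique_set)
    return canon_ok[mask], pos[mask], strand_fwd[ok][mask]


@dataclass
class Anchor:
    """A maximal co-linear run of matched unique k-mers."""

    start_a: int
    end_a: int
    start_b: int
    end_b: int
    orientation: str  # same | inverted

    @property
    def length(self) -> int:
        return self.end_a - self.start_a


@dataclass
class InversionCall:
    interval_a: tuple[int, int]
    interval_b: tuple[int, int]
    length: int
    flank_repeat_len: int
    flank_copy_number_a: int | None
    flank_copy_number_b: int | None


@dataclass
class InsertionDiff:
    carrier: str  # "A" | "B"
    site_in_other: int
    interval_in_carrier: tuple[int, int]
    inserted_seq: str
    matched_element: str | None = None

    @property
    def length(self) -> int:
        return self.interval_in_carrier[1] - self.interval_in_carrier[0]


@dataclass
class ComplexRegion:
    """A gap pair failing the insertion asymmetry rule; not forced into
    either the insertion or the substitution class."""

    interval_a: tuple[int, int]
    interval_b: tuple[int, int]


@dataclass
class DuplicationCall:
    genome_id: str
    interval_1: tuple[int, int]
    interval_2: tuple[int, int]
    length: int
    identity: float


@dataclass
class GenomeDiff:
    anchors: list[Anchor]
    inversions: list[InversionCall]
    insertions: list[InsertionDiff]
    complex_regions: list[ComplexRegion]


def build_anchors(genome_a: GenomeRecord, genome_b: GenomeRecord, k: int = 21) -> list[Anchor]:
    """Match k-mers unique in both genomes; merge into maximal runs.

    Runs merge only while consecutive matches sit on the same diagonal
    (same orientation) or anti-diagonal (inverted) and their windows
    overlap or abut, so the full anchor string is guaranteed identical.
    """
    if k % 2 == 0:
        raise ValueError("k must be odd (avoids strand-palindromic k-mers)")
    ca, pa, sa = _unique_canonical(genome_a.seq, k)
    cb, pb, sb = _unique_canonical(genome_b.seq, k)
    common, ia, ib = np.intersect1d(ca, cb, return_indices=True)
    if common.size == 0:
        return []
    pos_a, pos_b = pa[ia], pb[ib]
    same = sa[ia] == sb[ib]
    order = np.argsort(pos_a)
    pos_a, pos_b, same = pos_a[order], pos_b[order], same[order]

    a_seq, b_seq = genome_a.seq, genome_b.seq
    anchors: list[Anchor] = []
    cur_start = 0
    for i in range(1, len(pos_a) + 1):
        if i < len(pos_a):
            da = pos_a[i] - pos_a[i - 1]
            on_diagonal = (
                same[i] == same[i - 1]
                and da > 0
                and (
                    (same[i] and pos_b[i] - pos_b[i - 1] == da)
                    or (not same[i] and pos_b[i - 1] - pos_b[i] == da)
                )
            )
            contiguous = on_diagonal and da <= k
            if on_diagonal and da > k:
                # bridge a non-unique (repeat) stretch on the same diagonal
                # only if the intervening sequence is truly identical
                ga0, ga1 = int(pos_a[i - 1]) + k, int(pos_a[i])
                if same[i]:
                    gb0 = int(pos_b[i - 1]) + k
                    identical = a_seq[ga0:ga1] == b_seq[gb0 : gb0 + (ga1 - ga0)]
                else:
                    gb1 = int(pos_b[i - 1])
                    identical = a_seq[ga0:ga1] == revcomp(
                        b_seq[gb1 - (ga1 - ga0) : gb1]
                    )
                contiguous = identical
            if contiguous:
                continue
        first, last = cur_start, i - 1
        if same[first]:
            anchors.append(
                Anchor(
                    start_a=int(pos_a[first]),
                    end_a=int(pos_a[last]) + k,
                    start_b=int(pos_b[first]),
                    end_b=int(pos_b[last]) + k,
                    orientation="same",
                )
            )
        else:
            anchors.append(
                Anchor(
                    start_a=int(pos_a[first]),
                    end_a=int(pos_a[last]) + k,
                    start_b=int(pos_b[last]),
                    end_b=int(pos_b[first]) + k,
                    orientation="inverted",
                )
            )
        cur_start = i
    return anchors


def _flank_repeat(seq: str, start: int, end: int, max_len: int = 100_000) -> str:
    """Maximal R with seq[start-|R|:start] == seq[end:end+|R|] == R.

    Longest prefix of the right flank that is also a suffix of the left
    flank, via the KMP prefix function (linear time; a naive per-length
    scan would be quadratic in the ~10 kb cassettes seen here).
    """
    lmax = min(start, len(seq) - end, max_len)
    if lmax <= 0:
        return ""
    p = seq[end : end + lmax]
    t = seq[start - lmax : start]
    s = p + "#" + t
    pi = [0] * len(s)
    j = 0
    for i in range(1, len(s)):
        while j > 0 and s[i] != s[j]:
            j = pi[j - 1]
        if s[i] == s[j]:
            j += 1
        pi[i] = j
    return p[: pi[-1]]


def call_inversions(
    anchors: Sequence[Anchor],
    genome_a: GenomeRecord,
    genome_b: GenomeRecord,
    min_len: int = 10_000,
    min_flank_for_count: int = 50,
) -> list[InversionCall]:
    """Maximal runs of inverted anchors >= min_len become calls.

    Breakpoints are placed at the outermost anchored base. The flanking
    repeat is the maximal sequence identical between the two breakpoint
    flanks of genome A; its genome-wide copy number (exact occurrences)
    is counted in both genomes when it is long enough to be meaningful.
    """
    calls: list[InversionCall] = []
    run: list[Anchor] = []

    def close_run() -> None:
        if not run:
            return
        sa, ea = run[0].start_a, run[-1].end_a
        sb = min(a.start_b for a in run)
        eb = max(a.end_b for a in run)
        if ea - sa >= min_len:
            flank = _flank_repeat(genome_a.seq, sa, ea)
            if len(flank) >= min_flank_for_count:
                cn_a = count_copies(genome_a, flank, mode="exact")
                cn_b = count_copies(genome_b, flank, mode="exact")
            else:
                cn_a = cn_b = None
            calls.append(
                InversionCall(
                    interval_a=(sa, ea),
                    interval_b=(sb, eb),
                    length=ea - sa,
                    flank_repeat_len=len(flank),
                    flank_copy_number_a=cn_a,
                    flank_copy_number_b=cn_b,
                )
            )
        run.clear()

    for anchor in anchors:
        if anchor.orientation == "inverted":
            run.append(anchor)
        else:
            close_run()
    close_run()
    return calls


def scan_gaps(
    anchors: Sequence[Anchor],
    genome_a: GenomeRecord,
    genome_b: GenomeRecord,
    min_len: int = 50,
    max_other_gap: int = 10,
    catalogs: dict[str, str] | None = None,
) -> tuple[list[InsertionDiff], list[ComplexRegion]]:
    """Classify gaps between adjacent same-orientation anchors.

    A gap >= min_len in exactly one genome and <= max_other_gap in the
    other is an insertion in the gapped genome. Anchor overlap caused by
    a target-site duplication is trimmed leftward, so an insertion with
    a TSD is called at the 5' copy of the duplication and spans one TSD
    copy plus the element. Gap pairs failing the asymmetry rule are
    reported as complex regions.
    """
    insertions: list[InsertionDiff] = []
    complexes: list[ComplexRegion] = []
    same_anchors = [a for a in anchors if a.orientation == "same"]
    inverted_starts = sorted(a.start_a for a in anchors if a.orientation == "inverted")
    from bisect import bisect_left as _bl

    def contains_inverted(lo: int, hi: int) -> bool:
        i = _bl(inverted_starts, lo)
        return i < len(inverted_starts) and inverted_starts[i] < hi

    for prev, nxt in zip(same_anchors, same_anchors[1:]):
        if contains_inverted(prev.end_a, nxt.start_a):
            continue  # the gap is an inversion, reported separately
        gap_a = nxt.start_a - prev.end_a
        gap_b = nxt.start_b - prev.end_b
        trim = max(0, -min(gap_a, gap_b))
        ea, eb = prev.end_a - trim, prev.end_b - trim
        ga, gb = nxt.start_a - ea, nxt.start_b - eb
        if ga == gb and genome_a.seq[ea : ea + ga] == genome_b.seq[eb : eb + gb]:
            continue  # identical unanchored repeat stretch, not a difference
        if gb >= min_len and ga <= max_other_gap:
            seq = genome_b.seq[eb : nxt.start_b]
            insertions.append(
                InsertionDiff(
                    carrier="B",
                    site_in_other=ea,
                    interval_in_carrier=(eb, nxt.start_b),
                    inserted_seq=seq,
                    matched_element=_lookup_element(seq, catalogs),
                )
            )
        elif ga >= min_len and gb <= max_other_gap:
            seq = genome_a.seq[ea : nxt.start_a]
            insertions.append(
                InsertionDiff(
                    carrier="A",
                    site_in_other=eb,
                    interval_in_carrier=(ea, nxt.start_a),
                    inserted_seq=seq,
                    matched_element=_lookup_element(seq, catalogs),
                )
            )
        elif max(ga, gb) >= min_len:
            complexes.append(
                ComplexRegion(interval_a=(ea, nxt.start_a), interval_b=(eb, nxt.start_b))
            )
    return insertions, complexes


def _lookup_element(inserted_seq: str, catalogs: dict[str, str] | None) -> str | None:
    """Name the catalog element contained in an inserted sequence.

    Exact containment (either strand) first; then a 90%-identity edlib
    check for diverged copies. Longest matching element wins.
    """
    if not catalogs:
        return None
    import edlib

    best: tuple[int, str] | None = None
    for name, seq in catalogs.items():
        found = seq in inserted_seq or revcomp(seq) in inserted_seq
        if not found and abs(len(inserted_seq) - len(seq)) <= 0.5 * len(seq):
            k = int(0.10 * len(seq))
            for q in (seq, revcomp(seq)):
                if edlib.align(q, inserted_seq, mode="HW", k=k)["editDistance"] >= 0:
                    found = True
                    break
        if found and (best is None or len(seq) > best[0]):
            best = (len(seq), name)
    return best[1] if best else None


def call_indels(
    anchors: Sequence[Anchor],
    genome_a: GenomeRecord,
    genome_b: GenomeRecord,
    min_len: int = 50,
    max_other_gap: int = 10,
    catalogs: dict[str, str] | None = None,
) -> list[InsertionDiff]:
    """Strain-specific insertions between adjacent same-orientation anchors."""
    insertions, _ = scan_gaps(anchors, genome_a, genome_b, min_len, max_other_gap, catalogs)
    return insertions


def find_self_duplication(
    genome: GenomeRecord,
    min_len: int = 20_000,
    k: int = 21,
    max_copy_count: int = 6,
    merge_gap: int = 5_000,
) -> list[DuplicationCall]:
    """Maximal direct intra-genome duplications >= min_len, longest first.

    Duplicate k-mers (2..max_copy_count forward occurrences) are paired,
    grouped by diagonal, and merged into runs; gaps along a diagonal (a
    nested higher-copy repeat inside the duplication) are bridged up to
    merge_gap and the merged intervals are verified by direct comparison
    (edit-distance identity if not exact). Only calls at >= 99% identity
    are reported.
    """
    vals, _, ok = _kmer_values(genome.seq, k)
    order = np.argsort(vals[ok], kind="stable")
    pos_all = np.nonzero(ok)[0][order]
    vals_sorted = vals[ok][order]
    pairs: list[tuple[int, int]] = []  # (diagonal, start position)
    i = 0
    n = len(vals_sorted)
    while i < n:
        j = i
        while j < n and vals_sorted[j] == vals_sorted[i]:
            j += 1
        count = j - i
        if 2 <= count <= max_copy_count:
            ps = sorted(int(p) for p in pos_all[i:j])
            for x in range(len(ps)):
                for y in range(x + 1, len(ps)):
                    pairs.append((ps[y] - ps[x], ps[x]))
        i = j
    pairs.sort()
    calls: list[DuplicationCall] = []
    idx = 0
    while idx < len(pairs):
        diag = pairs[idx][0]
        run_start = pairs[idx][1]
        run_end = run_start + k
        j = idx + 1
        while j < len(pairs) and pairs[j][0] == diag and pairs[j][1] <= run_end + merge_gap:
            run_end = max(run_end, pairs[j][1] + k)
            j += 1
        length = run_end - run_start
        if length >= min_len and length <= diag:  # non-overlapping copies
            s1 = genome.seq[run_start:run_end]
            s2 = genome.seq[run_start + diag : run_end + diag]
            if s1 == s2:
                identity = 1.0
            else:
                import edlib

                d = edlib.align(s1, s2, mode="NW")["editDistance"]
                identity = 1.0 - d / length
            if identity >= 0.99:
                calls.append(
                    DuplicationCall(
                        genome_id=genome.id,
                        interval_1=(run_start, run_end),
                        interval_2=(run_start + diag, run_end + diag),
                        length=length,
                        identity=identity,
                    )
                )
        idx = j
    calls.sort(key=lambda c: -c.length)
    # suppress sub-calls contained in a longer call
    kept: list[DuplicationCall] = []
    for c in calls:
        if not any(
            c.interval_1[0] >= k0.interval_1[0] and c.interval_1[1] <= k0.interval_1[1]
            for k0 in kept
        ):
            kept.append(c)
    return kept


def anchored_fraction(anchors: Sequence[Anchor], genome_len: int) -> float:
    """Fraction of genome-A positions covered by anchors."""
    covered = 0
    last = 0
    for a in sorted(anchors, key=lambda x: x.start_a):
        s, e = max(a.start_a, last), a.end_a
        if e > s:
            covered += e - s
            last = e
    return covered / genome_len if genome_len else 0.0


def diff_genomes(
    genome_a: GenomeRecord,
    genome_b: GenomeRecord,
    k: int = 21,
    inversion_min_len: int = 10_000,
    indel_min_len: int = 50,
    catalogs: dict[str, str] | None = None,
) -> GenomeDiff:
    """Full structural comparison: anchors, inversions, insertions."""
    anchors = build_anchors(genome_a, genome_b, k)
    inversions = call_inversions(anchors, genome_a, genome_b, inversion_min_len)
    insertions, complexes = scan_gaps(
        anchors, genome_a, genome_b, indel_min_len, catalogs=catalogs
    )
    return GenomeDiff(
        anchors=anchors,
        inversions=inversions,
        insertions=insertions,
        complex_regions=complexes,
    )
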