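"""In-silico PCR: primer annealing sites and predicted amplicon sizes.

Product length follows the gel-facing convention: the amplicon runs
from the forward primer's 5' base through the reverse primer's 5' base,
inclusive of both primer footprints. Primers default to exact matching
(validation primers are designed to template), with an optional
mismatch budget and a 3'-end region that must match exactly (polymerase
extension requires an annealed 3' terminus).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .genome_io import GenomeRecord, revcomp


@dataclass
class PrimerPair:
    fwd: str
    rev: str
    max_mismatch: int = 0
    three_prime_exact: int = 3

    def __post_init__(self) -> None:
        self.fwd = self.fwd.upper()
        self.rev = self.rev.upper()
        for p in (self.fwd, self.rev):
            if not (15 <= len(p) <= 35):
                raise ValueError(f"primer length {len(p)} outside 15-35 nt")
            if self.three_prime_exact > len(p):
                raise ValueError("three_prime_exact exceeds primer length")


@dataclass
class PrimerSite:
    start: int
    end: int
    strand: str  # + : primer anneals to minus strand template, extends rightward
    mismatches: int


@dataclass
class Amplicon:
    genome_id: str
    start: int
    end: int
    fwd_mismatches: int
    rev_mismatches: int

    @property
    def length(self) -> int:
        return self.end - self.start


def _scan(genome_bytes: np.ndarray, primer: str, max_mismatch: int, three_prime_exact: int,
          tail_at_end: bool) -> list[tuple[int, int]]:
    """(position, mismatches) of primer occurrences on the plus-strand text.

    tail_at_end: whether the primer's 3' tail corresponds to the last
    (True, plus-strand annealing) or first (False, written revcomp)
    bases of the scanned word.
    """
    m = len(primer)
    n = len(genome_bytes)
    if n < m:
        return []
    pb = np.frombuffer(primer.encode(), dtype=np.uint8)
    mism = np.zeros(n - m + 1, dtype=np.int32)
    for j in range(m):
        mism += genome_bytes[j : n - m + 1 + j] != pb[j]
    if three_prime_exact > 0:
        tail = range(m - three_prime_exact, m) if tail_at_end else range(three_prime_exact)
        tail_mism = np.zeros(n - m + 1, dtype=np.int32)
        for j in tail:
            tail_mism += genome_bytes[j : n - m + 1 + j] != pb[j]
        good = (mism <= max_mismatch) & (tail_mism == 0)
    else:
        good = mism <= max_mismatch
    return [(int(i), int(mism[i])) for i in np.nonzero(good)[0]]


def find_primer_sites(
    genome: GenomeRecord,
    primer: str,
    max_mismatch: int = 0,
    three_prime_exact: int = 3,
) -> list[PrimerSite]:
    """All annealing sites of a primer on both strands.

    A '+' site is a plus-strand match (primer extends rightward); a '-'
    site is a match of the primer's reverse complement on the plus
    strand (the primer anneals to the plus strand and extends leftward).
    """
    primer = primer.upper()
    gb = np.frombuffer(genome.seq.encode(), dtype=np.uint8)
    sites = [
        PrimerSite(start=i, end=i + len(primer), strand="+", mismatches=mm)
        for i, mm in _scan(gb, primer, max_mismatch, three_prime_exact, tail_at_end=True)
    ]
    sites += [
        PrimerSite(start=i, end=i + len(primer), strand="-", mismatches=mm)
        for i, mm in _scan(
            gb, revcomp(primer), max_mismatch, three_prime_exact, tail_at_end=False
        )
    ]
    sites.sort(key=lambda s: (s.start, s.strand))
    return sites


def predict_amplicons(
    genome: GenomeRecord,
    pair: PrimerPair,
    max_product_len: int = 10_000,
) -> list[Amplicon]:
    """Every (plus-strand forward site, downstream minus-strand reverse
    site) pairing within max_product_len, both primer orientations
    searched, duplicates collapsed."""
    products: dict[tuple[int, int], Amplicon] = {}
    for fwd, rev in ((pair.fwd, pair.rev), (pair.rev, pair.fwd)):
        fsites = [
            s
            for s in find_primer_sites(genome, fwd, pair.max_mismatch, pair.three_prime_exact)
            if s.strand == "+"
        ]
        rsites = [
            s
            for s in find_primer_sites(genome, rev, pair.max_mismatch, pair.three_prime_exact)
            if s.strand == "-"
        ]
        for fs in fsites:
            for rs in rsites:
                length = rs.end - fs.start
                if 0 < length <= max_product_len and rs.start >= fs.start:
                    key = (fs.start, rs.end)
                    amp = Amplicon(
                        genome_id=genome.id,
                        start=fs.start,
                        end=rs.end,
                        fwd_mismatches=fs.mismatches,
                        rev_mismatches=rs.mismatches,
                    )
                    if key not in products:
                        products[key] = amp
    return sorted(products.values(), key=lambda a: (a.start, a.end))
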