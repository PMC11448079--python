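"""Genic impact of insertion differences.

Classification is done against the annotation of the genome that does
NOT carry the insertion: the insertion site is a single position there,
and "intragenic" means strictly inside a CDS. Insertions at an exact
CDS boundary are intergenic with distance 0, matching how elements
"situated before" genes are described in comparative mobilome work.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

from .genome_diff import InsertionDiff
from .genome_io import Feature, translate_cds
from .mite_discovery import STOP_CODONS


@dataclass
class NeighborGene:
    gene_id: str
    distance: int
    strand: str


@dataclass
class ImpactReport:
    diff: InsertionDiff
    context: str  # intragenic | intergenic
    hit_genes: list[str] = field(default_factory=list)
    ambiguous: bool = False
    upstream_gene: NeighborGene | None = None
    downstream_gene: NeighborGene | None = None

    @property
    def hit_gene(self) -> str | None:
        return self.hit_genes[0] if self.hit_genes else None


def classify_insertion(diff: InsertionDiff, features: Sequence[Feature]) -> ImpactReport:
    """Intragenic iff the site lies strictly inside a CDS.

    Overlapping CDS at the site are all reported with an ambiguity flag.
    Intergenic sites get their nearest left/right CDS neighbors with
    distances; a featureless genome yields no neighbors. Deterministic
    and invariant to feature input order.
    """
    site = diff.site_in_other
    cds = sorted(
        (f for f in features if f.ftype == "CDS"), key=lambda f: (f.start, f.end)
    )
    inside = [f for f in cds if f.start < site < f.end]
    if inside:
        return ImpactReport(
            diff=diff,
            context="intragenic",
            hit_genes=[f.gene_id or "?" for f in inside],
            ambiguous=len(inside) > 1,
        )
    left = [f for f in cds if f.end <= site]
    right = [f for f in cds if f.start >= site]
    upstream = (
        NeighborGene(left[-1].gene_id or "?", site - left[-1].end, left[-1].strand)
        if left
        else None
    )
    downstream = (
        NeighborGene(right[0].gene_id or "?", right[0].start - site, right[0].strand)
        if right
        else None
    )
    return ImpactReport(
        diff=diff,
        context="intergenic",
        upstream_gene=upstream,
        downstream_gene=downstream,
    )


@dataclass
class SplitProducts:
    lengths_aa: list[int]
    run_through: bool = False


def _first_orf_product(transcript: str) -> tuple[int, int | None, bool]:
    """(aa length before first in-frame stop, index past the stop, run_through)."""
    for i in range(0, len(transcript) - 2, 3):
        if transcript[i : i + 3] in STOP_CODONS:
            return i // 3, i + 3, False
    return len(transcript) // 3, None, True


def split_products(
    cds_seq: str, insertion_offset_nt: int, inserted_seq: str, min_orf_nt: int = 30
) -> SplitProducts:
    """Protein products of a CDS interrupted by an insertion.

    Product 1: translation from the original start to the first in-frame
    stop at or after the junction. Product 2: the longest ATG-initiated
    ORF (>= min_orf_nt, forward frames — the transcript is single-
    stranded) in the remainder of the interrupted transcript. Lengths in
    aa exclude stops; a missing stop flags the product as run-through.
    """
    if not (0 <= insertion_offset_nt <= len(cds_seq)):
        raise ValueError("insertion offset outside CDS")
    transcript = cds_seq[:insertion_offset_nt] + inserted_seq + cds_seq[insertion_offset_nt:]
    p1_aa, after_stop, run_through = _first_orf_product(transcript)
    lengths = [p1_aa]
    if after_stop is not None:
        remainder = transcript[after_stop:]
        best = 0
        for frame in range(3):
            atg = None
            for i in range(frame, len(remainder) - 2, 3):
                codon = remainder[i : i + 3]
                if codon == "ATG" and atg is None:
                    atg = i
                elif codon in STOP_CODONS and atg is not None:
                    span = i + 3 - atg
                    if span >= min_orf_nt:
                        best = max(best, span // 3 - 1)
                    atg = None
        if best:
            lengths.append(best)
    return SplitProducts(lengths_aa=lengths, run_through=run_through)


def cds_delta(
    cds_seq: str,
    insertion_offset_nt: int,
    inserted_seq: str,
    downstream_seq: str = "",
) -> int:
    """Signed change in CDS length caused by an insertion.

    The coding frame is re-run from the original start through the
    mutated sequence (CDS plus downstream context, insertion applied)
    until the first in-frame stop; the delta is new minus old length,
    both including the stop codon. An insertion wholly past the stop
    codon leaves the CDS unchanged (delta 0); one that ablates the stop
    extends the frame into the insertion/downstream sequence.
    """
    if len(cds_seq) % 3 != 0:
        raise ValueError("CDS length must be divisible by 3")
    extended = cds_seq + downstream_seq
    if not (0 <= insertion_offset_nt <= len(extended)):
        raise ValueError("insertion offset outside provided sequence")
    mutated = extended[:insertion_offset_nt] + inserted_seq + extended[insertion_offset_nt:]
    _, after_stop, run_through = _first_orf_product(mutated)
    if run_through:
        new_len = len(mutated) - len(mutated) % 3
    else:
        new_len = after_stop
    return new_len - len(cds_seq)


def product_summary(cds_seq: str) -> int:
    """Protein length (aa) of an intact CDS, stop excluded."""
    protein = translate_cds(cds_seq)
    return len(protein) - 1 if protein.endswith("*") else len(protein)
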