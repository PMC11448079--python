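"""Locate known IS elements in a genome and count element copies.

Significance is expressed as identity+coverage thresholds instead of
BLAST e-values: matching is seed-and-extend with exact 13-mer seeds and
a banded semi-global (edlib "HW") extension, which is deterministic and
self-contained. On >90%-identity targets in a few-Mb genome this finds
the same hits a default BLASTn run reports as significant.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import edlib

from .genome_io import GenomeRecord, read_fasta, revcomp

SEED_K = 13


@dataclass
class ISElement:
    """A reference insertion-sequence element (one library entry)."""

    name: str
    family: str
    seq: str

    def __len__(self) -> int:
        return len(self.seq)


@dataclass
class ElementHit:
    """A located, stranded match of a library element."""

    element: str
    genome_id: str
    start: int
    end: int
    strand: str
    identity: float
    coverage: float

    @property
    def span(self) -> int:
        return self.end - self.start


def read_library(path: str | Path) -> list[ISElement]:
    """Read an element library FASTA with ``>name|family`` headers.

    A header without ``|`` gets family "unknown".
    """
    out = []
    for rec in read_fasta(path):
        name, _, family = rec.id.partition("|")
        out.append(ISElement(name=name, family=family or "unknown", seq=rec.seq))
    names = [e.name for e in out]
    if len(set(names)) != len(names):
        raise ValueError("duplicate element names in library")
    return out


def write_library(library: Iterable[ISElement], path: str | Path) -> None:
    from .genome_io import write_fasta

    write_fasta(
        [GenomeRecord(id=f"{e.name}|{e.family}", seq=e.seq) for e in library], path
    )


def _find_all_exact(haystack: str, needle: str) -> list[int]:
    positions = []
    i = haystack.find(needle)
    while i != -1:
        positions.append(i)
        i = haystack.find(needle, i + 1)
    return positions


class _SeedIndex:
    """Exact k-mer index of a genome, built once per match_library call."""

    def __init__(self, seq: str, k: int = SEED_K):
        self.k = k
        self.seq = seq
        index: dict[str, list[int]] = {}
        for i in range(len(seq) - k + 1):
            index.setdefault(seq[i : i + k], []).append(i)
        self.index = index

    def candidate_starts(self, query: str, stride: int) -> list[int]:
        """Putative alignment start positions (query pos 0) in the genome."""
        starts: list[int] = []
        for qpos in range(0, len(query) - self.k + 1, stride):
            for gpos in self.index.get(query[qpos : qpos + self.k], ()):
                starts.append(gpos - qpos)
        return starts


def _cluster_starts(starts: list[int], band: int) -> list[int]:
    """Collapse nearby candidate starts to one representative each."""
    reps: list[int] = []
    for s in sorted(starts):
        if not reps or s - reps[-1] > band:
            reps.append(s)
    return reps


def _align_candidate(
    genome: GenomeRecord,
    elem: ISElement,
    query: str,
    strand: str,
    start: int,
    min_identity: float,
) -> ElementHit | None:
    pad = max(30, len(query) // 10)
    lo = max(0, start - pad)
    hi = min(len(genome.seq), start + len(query) + pad)
    max_dist = int(len(query) * (1.0 - min_identity)) + 1
    res = edlib.align(query, genome.seq[lo:hi], mode="HW", task="locations", k=max_dist)
    if res["editDistance"] < 0:
        return None
    loc0, loc1 = res["locations"][0]
    identity = max(0.0, 1.0 - res["editDistance"] / len(query))
    hit_start, hit_end = lo + loc0, lo + loc1 + 1
    coverage = min(1.0, (hit_end - hit_start) / len(elem.seq))
    return ElementHit(
        element=elem.name,
        genome_id=genome.id,
        start=hit_start,
        end=hit_end,
        strand=strand,
        identity=identity,
        coverage=coverage,
    )


def _match_element(
    genome: GenomeRecord,
    elem: ISElement,
    seed_index: _SeedIndex,
    min_identity: float,
    min_coverage: float,
) -> list[ElementHit]:
    hits: dict[tuple[int, int, str], ElementHit] = {}
    for strand in "+-":
        query = elem.seq if strand == "+" else revcomp(elem.seq)
        # Exact fast path first; approximate pass catches diverged copies.
        exact = set(_find_all_exact(genome.seq, query))
        for pos in exact:
            hits[(pos, pos + len(query), strand)] = ElementHit(
                element=elem.name,
                genome_id=genome.id,
                start=pos,
                end=pos + len(query),
                strand=strand,
                identity=1.0,
                coverage=1.0,
            )
        band = max(20, len(query) // 20)
        stride = max(1, (len(query) - SEED_K) // 40) if len(query) > SEED_K else 1
        candidates = _cluster_starts(
            [s for s in seed_index.candidate_starts(query, stride) if s not in exact],
            band,
        )
        for start in candidates:
            hit = _align_candidate(genome, elem, query, strand, start, min_identity)
            if hit is None:
                continue
            key = (hit.start, hit.end, strand)
            if key not in hits or hits[key].identity < hit.identity:
                hits[key] = hit
    # Drop near-duplicate hits of the same element from adjacent seeds.
    kept: list[ElementHit] = []
    for hit in sorted(
        hits.values(), key=lambda h: (-h.span, -h.identity, h.start, h.strand)
    ):
        if all(
            _overlap(hit, other) < 0.5 * min(hit.span, other.span) for other in kept
        ):
            kept.append(hit)
    return [
        h
        for h in kept
        if h.identity >= min_identity and h.coverage >= min_coverage
    ]


def _overlap(a: ElementHit, b: ElementHit) -> int:
    return max(0, min(a.end, b.end) - max(a.start, b.start))


def match_library(
    genome: GenomeRecord,
    library: Sequence[ISElement],
    min_identity: float = 0.90,
    min_coverage: float = 0.5,
) -> list[ElementHit]:
    """All hits of library elements on both strands above the thresholds.

    Hits are sorted by (genome_id, start). An empty genome simply yields
    no hits.
    """
    if not library:
        raise ValueError("element library is empty")
    if not (0 < min_identity <= 1 and 0 < min_coverage <= 1):
        raise ValueError("thresholds must be in (0, 1]")
    if not genome.seq:
        return []
    seed_index = _SeedIndex(genome.seq)
    hits: list[ElementHit] = []
    for elem in library:
        hits.extend(_match_element(genome, elem, seed_index, min_identity, min_coverage))
    hits.sort(key=lambda h: (h.genome_id, h.start, h.end, h.strand))
    return hits


def dedupe_overlaps(
    hits: Sequence[ElementHit], containment_frac: float = 0.5
) -> list[ElementHit]:
    """Remove the shorter of two hits overlapping by >= containment_frac
    of the shorter hit's span.

    Priority for keeping: longer span, then higher identity, then
    leftmost start. Idempotent by construction (greedy over a total
    order).
    """
    genomes = {h.genome_id for h in hits}
    if len(genomes) > 1:
        raise ValueError("dedupe_overlaps expects hits on a single genome")
    ordered = sorted(hits, key=lambda h: (-h.span, -h.identity, h.start, h.end, h.strand))
    kept: list[ElementHit] = []
    for hit in ordered:
        if all(
            _overlap(hit, other) < containment_frac * min(hit.span, other.span)
            for other in kept
        ):
            kept.append(hit)
    kept.sort(key=lambda h: (h.start, h.end, h.strand))
    return kept


def count_copies(
    genome: GenomeRecord,
    element_seq: str,
    mode: str = "exact",
    min_identity: float = 0.90,
    min_coverage: float = 0.5,
) -> int:
    """Count copies of an element sequence in a genome.

    exact mode: distinct non-overlapping occurrences of the sequence or
    its reverse complement, leftmost-greedy; a palindromic element is
    not double-counted. approximate mode: deduped seed-and-extend hits
    at the given thresholds.
    """
    if not element_seq:
        raise ValueError("element_seq is empty")
    if mode == "exact":
        rc = revcomp(element_seq)
        positions = set(_find_all_exact(genome.seq, element_seq))
        if rc != element_seq:
            positions |= set(_find_all_exact(genome.seq, rc))
        count, last_end = 0, -1
        for pos in sorted(positions):
            if pos >= last_end:
                count += 1
                last_end = pos + len(element_seq)
        return count
    if mode == "approximate":
        elem = ISElement(name="query", family="query", seq=element_seq)
        hits = match_library(genome, [elem], min_identity, min_coverage)
        return len(dedupe_overlaps(hits))
    raise ValueError(f"unknown mode {mode!r}")


def hits_to_features(hits: Iterable[ElementHit], families: dict[str, str] | None = None):
    """Render hits as `mobile_genetic_element` Features for GFF3 export."""
    from .genome_io import Feature

    feats = []
    for i, h in enumerate(hits):
        attrs = {
            "ID": f"mge_{i:04d}",
            "Name": h.element,
            "identity": f"{h.identity:.4f}",
            "coverage": f"{h.coverage:.4f}",
        }
        if families and h.element in families:
            attrs["family"] = families[h.element]
        feats.append(
            Feature(
                genome_id=h.genome_id,
                start=h.start,
                end=h.end,
                strand=h.strand,
                ftype="mobile_genetic_element",
                attributes=attrs,
                source="mobilome",
            )
        )
    return feats
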