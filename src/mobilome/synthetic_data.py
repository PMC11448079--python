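"""Synthetic genome pairs with planted mobile elements and expression.

The generator emits two strains of one species — "wildtype" (genome A)
and "mutant" (genome B) — that share an i.i.d. backbone with planted
genes and differ by a known inventory of mobile-element events: shared
and strain-specific IS/MITE insertions (with target-site duplication),
one large inversion flanked by a multi-kilobase cassette present in
three copies, and expression effects on genes downstream of the
strain-specific insertions. Every planted feature is recorded in truth
tables using the same coordinate conventions the discovery modules
emit, so end-to-end recovery can be asserted exactly.

All randomness flows from the single spec seed through independent
child streams (one per component), so enabling or resizing one
component does not perturb the draws of another.
"""

from __future__ import annotations

from bisect import bisect_left, bisect_right
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .element_catalog import ISElement
from .genome_io import Feature, GenomeRecord, revcomp
from .insilico_pcr import PrimerPair
from .mite_discovery import detect_tir

SENSE_CODONS = sorted(
    {
        a + b + c
        for a in "ACGT"
        for b in "ACGT"
        for c in "ACGT"
    }
    - {"TAA", "TAG", "TGA"}
)

TIR_SEED = "GGCTCTTCG"  # shared MITE/ISL3 terminal seed


class SimulationError(RuntimeError):
    """Infeasible packing or a failed structural validation."""


@dataclass
class ElementPlan:
    """One planted element family and its copy numbers per strain."""

    name: str
    family: str
    length: int
    tsd_len: int
    shared_copies: int
    extra_a: int = 0  # strain-specific copies in the wildtype (A)
    extra_b: int = 0  # strain-specific copies in the mutant (B)
    tir_seed: str | None = None
    has_orf: bool = True
    in_library: bool = True


@dataclass
class InversionPlan:
    segment_len: int = 200_000
    cassette_len: int = 10_000
    cassette_copies: int = 3  # two flanking the segment, the rest elsewhere


@dataclass
class ExpressionPlan:
    """Lognormal TPM baselines with multiplicative effects and noise.

    n_replicates defaults to 5: forty libraries over two strains and
    four timepoints. Effects are constant across timepoints.
    """

    meanlog: float = 3.2
    sdlog: float = 1.0
    cv: float = 0.1
    n_replicates: int = 5
    timepoints: tuple[str, ...] = ("T1", "T10", "T7", "T8")


@dataclass
class SimSpec:
    seed: int
    backbone_len: int = 1_000_000
    gc: float = 0.42
    n_genes: int = 260
    mite: ElementPlan = field(
        default_factory=lambda: ElementPlan(
            name="MITE187",
            family="MITE",
            length=187,
            tsd_len=8,
            shared_copies=31,
            extra_b=2,
            tir_seed=TIR_SEED,
            has_orf=False,
            in_library=False,
        )
    )
    elements: tuple[ElementPlan, ...] = (
        ElementPlan("ISL3like", "ISL3", 1215, 8, shared_copies=2, tir_seed=TIR_SEED),
        ElementPlan("IS1634like", "IS1634", 1746, 6, shared_copies=8, extra_b=2),
        ElementPlan("IS200like", "IS200/IS605", 444, 0, shared_copies=14, extra_a=2),
        ElementPlan("IS1like", "IS1", 737, 8, shared_copies=5, extra_a=1),
    )
    inversion: InversionPlan = field(default_factory=InversionPlan)
    expr: ExpressionPlan = field(default_factory=ExpressionPlan)


def pcc7806_mimic_spec(seed: int = 0) -> SimSpec:
    """The default 1-Mb fixture: 187-nt MITE at 33/31 copies, IS1634-like
    at 10/8, IS200-like at 14/16, IS1-like at 5/6, ISL3-like at 2/2, and
    a 200-kb inversion flanked by a 10-kb cassette in 3 copies."""
    return SimSpec(seed=seed)


def small_spec(seed: int = 0) -> SimSpec:
    """A 120-kb fixture with the same structure at reduced copy numbers,
    for fast tests."""
    return SimSpec(
        seed=seed,
        backbone_len=120_000,
        n_genes=55,
        mite=ElementPlan(
            "MITE187", "MITE", 187, 8, shared_copies=6, extra_b=2,
            tir_seed=TIR_SEED, has_orf=False, in_library=False,
        ),
        elements=(
            ElementPlan("ISL3like", "ISL3", 1215, 8, shared_copies=2, tir_seed=TIR_SEED),
            ElementPlan("IS1634like", "IS1634", 1746, 6, shared_copies=2, extra_b=1),
            ElementPlan("IS200like", "IS200/IS605", 444, 0, shared_copies=4, extra_a=1),
            ElementPlan("IS1like", "IS1", 737, 8, shared_copies=2, extra_a=1),
        ),
        inversion=InversionPlan(segment_len=25_000, cassette_len=3_000),
    )


@dataclass
class GenePlan:
    gene_id: str
    start: int  # backbone coordinates
    end: int
    strand: str
    designed: bool = False


@dataclass
class _Event:
    pos: int  # insertion point in backbone coordinates
    ins: str


class _EventMap:
    """Backbone -> final coordinates under a sorted set of insertions."""

    def __init__(self, events: list[_Event]):
        self.positions = [e.pos for e in events]
        self.cum = [0]
        for e in events:
            self.cum.append(self.cum[-1] + len(e.ins))

    def map(self, x: int) -> int:
        """Final coordinate of backbone position x (insertions at x land
        before x)."""
        return x + self.cum[bisect_right(self.positions, x)]

    def map_left(self, x: int) -> int:
        """Like map(), but an insertion exactly at x does not shift x."""
        return x + self.cum[bisect_left(self.positions, x)]


@dataclass
class SimResult:
    spec: SimSpec
    genome_a: GenomeRecord  # wildtype
    genome_b: GenomeRecord  # mutant
    features_a: list[Feature]
    features_b: list[Feature]
    genes: list[GenePlan]
    library: list[ISElement]
    mite_seq: str
    cassette_seq: str
    element_seqs: dict[str, str]
    truth_elements: pd.DataFrame
    truth_diffs: pd.DataFrame
    truth_inversion: dict
    truth_effects: pd.DataFrame
    primers: PrimerPair
    expected_amplicons: dict[str, int]


def _random_dna(rng: np.random.Generator, n: int, gc: float) -> str:
    p_at, p_gc = (1 - gc) / 2, gc / 2
    return "".join(
        np.array(list("ATGC"))[rng.choice(4, size=n, p=[p_at, p_at, p_gc, p_gc])]
    )


def _random_cds(rng: np.random.Generator, length: int) -> str:
    """ATG + sense codons + stop; length must be a multiple of 3 >= 9."""
    if length % 3 or length < 9:
        raise ValueError("CDS length must be a multiple of 3, >= 9")
    n_sense = length // 3 - 2
    body = "".join(rng.choice(SENSE_CODONS, size=n_sense))
    stop = ["TAA", "TGA", "TAG"][int(rng.integers(3))]
    return "ATG" + body + stop


def _build_mite(rng: np.random.Generator, length: int, seed: str, gc: float) -> str:
    """A MITE: perfect 5' TIR seed, one internal substitution in the 3'
    TIR (imperfect), and interior bases chosen so the TIR cannot extend
    past the seed length under a 2-mismatch budget."""
    t = len(seed)
    right = list(revcomp(seed))
    mid = t // 2
    orig = right[mid]
    right[mid] = {"A": "C", "C": "A", "G": "T", "T": "G"}[orig]
    interior = list(_random_dna(rng, length - 2 * t, gc))
    elem = list(seed) + interior + right
    # block TIR extension: force mismatches just inside both termini
    comp = {"A": "T", "T": "A", "G": "C", "C": "G"}
    for off in range(4):
        i = t + off
        j = length - 1 - t - off
        if elem[i] == comp[elem[j]]:
            elem[i] = {"A": "G", "G": "A", "C": "T", "T": "C"}[elem[i]]
    seq = "".join(elem)
    tir = detect_tir(seq)
    if not (tir.present and tir.length == t and tir.mismatches == 1):
        raise SimulationError("MITE TIR construction failed")
    return seq


def _build_element(rng: np.random.Generator, plan: ElementPlan, gc: float) -> str:
    """An autonomous element: optional TIR-seed termini and a long
    transposase-like ORF filling the interior."""
    margin = len(plan.tir_seed) if plan.tir_seed else 6
    for _ in range(50):
        left = plan.tir_seed or _random_dna(rng, margin, gc)
        right = revcomp(plan.tir_seed) if plan.tir_seed else _random_dna(rng, margin, gc)
        interior_len = plan.length - 2 * margin
        if plan.has_orf:
            orf_len = interior_len - interior_len % 3
            interior = _random_cds(rng, orf_len) + _random_dna(rng, interior_len - orf_len, gc)
        else:
            interior = _random_dna(rng, interior_len, gc)
        seq = left + interior + right
        if plan.tir_seed is None and detect_tir(seq).present:
            continue  # a TIR-less family must not look like a MITE
        return seq
    raise SimulationError(f"could not build element {plan.name}")


def _place_genes(
    rng: np.random.Generator,
    backbone_len: int,
    n_genes: int,
    designed: list[GenePlan],
    exclusions: list[tuple[int, int]],
) -> list[GenePlan]:
    occupied = sorted(
        [(g.start - 60, g.end + 60) for g in designed] + list(exclusions)
    )
    starts = [o[0] for o in occupied]

    def overlaps(s: int, e: int) -> bool:
        # occupied intervals are short (< 3.4 kb), so a bounded lookback
        # from the insertion index is exhaustive
        i = bisect_right(starts, e)
        return any(o[1] > s for o in occupied[max(0, i - 24) : i] if o[0] < e)

    genes = list(designed)
    attempts = 0
    placed = 0
    while placed < n_genes:
        attempts += 1
        if attempts > 80 * n_genes:
            raise SimulationError("infeasible gene packing")
        length = 300 + 3 * int(rng.integers(0, 901))
        start = int(rng.integers(200, backbone_len - length - 200))
        if overlaps(start - 60, start + length + 60):
            continue
        strand = "+" if rng.random() < 0.5 else "-"
        genes.append(GenePlan(f"g{placed:04d}", start, start + length, strand))
        iv = (start - 60, start + length + 60)
        j = bisect_right(starts, iv[0])
        occupied.insert(j, iv)
        starts.insert(j, iv[0])
        placed += 1
    genes.sort(key=lambda g: g.start)
    return genes


def _merge_intervals(intervals: list[tuple[int, int]]) -> list[tuple[int, int]]:
    merged: list[tuple[int, int]] = []
    for s, e in sorted(intervals):
        if merged and s <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], e))
        else:
            merged.append((s, e))
    return merged


def _tsd_clean(bb: str, p: int, t: int, w_max: int = 16) -> bool:
    """True if an element planted at p with a t-nt TSD will be called
    with TSD length exactly t (no accidental longer duplication)."""
    if p - w_max < 0 or p + w_max + t > len(bb):
        return False
    h = bb[p : p + t]
    for w in range(t + 1, w_max + 1):
        left = bb[p - (w - t) : p] + h
        right = h + bb[p + t : p + w]
        if left == right:
            return False
    return True


def _sample_sites(
    rng: np.random.Generator,
    bb: str,
    n: int,
    tsd_len: int,
    blocked: list[tuple[int, int]],
    taken: list[int],
    lo: int = 300,
    hi: int | None = None,
    min_gap: int = 150,
) -> list[int]:
    hi = hi if hi is not None else len(bb) - 300
    sites: list[int] = []
    tries = 0
    merged = _merge_intervals(blocked)
    starts = [b[0] for b in merged]
    while len(sites) < n:
        tries += 1
        if tries > 4000 * max(n, 1):
            raise SimulationError("infeasible element site packing")
        p = int(rng.integers(lo, hi))
        j = bisect_right(starts, p) - 1
        if j >= 0 and p <= merged[j][1]:
            continue
        if any(abs(p - q) < min_gap for q in taken) or any(
            abs(p - q) < min_gap for q in sites
        ):
            continue
        if not _tsd_clean(bb, p, tsd_len):
            continue
        sites.append(p)
    return sites


def simulate_genome_pair(spec: SimSpec) -> SimResult:
    """Generate the strain pair, annotations and truth tables.

    Deterministic for a fixed seed; raises SimulationError before
    emitting anything if the requested features cannot be packed.
    """
    ss = np.random.SeedSequence(spec.seed)
    (
        rng_backbone,
        rng_genes,
        rng_elements,
        rng_sites,
        rng_strands,
        rng_misc,
    ) = [np.random.default_rng(c) for c in ss.spawn(6)]

    L = spec.backbone_len
    inv = spec.inversion
    bb = list(_random_dna(rng_backbone, L, spec.gc))

    # --- cassette positions and sequence -------------------------------
    if inv is not None:
        c1 = int(0.25 * L)
        c2 = c1 + inv.segment_len
        c_extra = [int((0.90 + 0.03 * i) * L) for i in range(inv.cassette_copies - 2)]
        # Terminal bases fixed so no prefix of the cassette equals the
        # reverse complement of its suffix: otherwise the planted
        # inversion breakpoint would be ambiguous by that overlap.
        cassette = "A" + _random_dna(rng_elements, inv.cassette_len - 2, spec.gc) + "A"
        # the flanking repeat must not extend past the cassette by accident
        if bb[c1 - 1] + cassette == cassette + bb[c2]:
            bb[c2] = {"A": "C", "C": "A", "G": "T", "T": "G"}[bb[c2]]
        cassette_sites = [c1, c2, *c_extra]
    else:
        cassette, cassette_sites, c_extra = "", [], []
        c1 = c2 = -10_000  # sentinels: no inversion zone

    # --- designed gene clusters ----------------------------------------
    sbp0 = int(0.62 * L)
    sbp_names = ["sbp", "cysT", "cysW", "cysA", "cysR"]
    sbp_lens = [1044, 900, 900, 900, 900]
    designed: list[GenePlan] = []
    pos = sbp0
    for name, ln in zip(sbp_names, sbp_lens):
        designed.append(GenePlan(name, pos, pos + ln, "+", designed=True))
        pos += ln + 150
    lip0 = int(0.72 * L)
    lip_names = ["flv", "lipo", "duf1995", "samMT"]
    pos = lip0
    for name in lip_names:
        designed.append(GenePlan(name, pos, pos + 750, "+", designed=True))
        pos += 750 + 120
    mbl0 = int(0.80 * L)
    for name, ln in zip(["unch", "mbl"], [600, 750]):
        designed.append(GenePlan(name, mbl0, mbl0 + ln, "+", designed=True))
        mbl0 += ln + 120

    site_is1634 = lip0 + 750 + 60  # intergenic, upstream of lipo/duf1995/samMT
    site_is1 = int(0.80 * L) - 200  # intergenic, before unch/mbl

    exclusions = [
        (c1 - 80, c1 + 80),
        (c2 - 80, c2 + 80),
        *[(c - 80, c + 80) for c in c_extra],
        (site_is1634 - 40, site_is1634 + 40),
        (site_is1 - 40, site_is1 + 40),
    ]
    genes = _place_genes(rng_genes, L, spec.n_genes, designed, exclusions)

    # write CDS content into the backbone
    for g in genes:
        cds = _random_cds(rng_genes, (g.end - g.start) - (g.end - g.start) % 3)
        cds = cds + "".join(bb[g.start + len(cds) : g.end])  # pad leftover
        if g.strand == "-":
            cds = revcomp(cds)
        bb[g.start : g.end] = list(cds)
    bb_str = "".join(bb)

    # --- element sequences ---------------------------------------------
    mite_seq = _build_mite(rng_elements, spec.mite.length, spec.mite.tir_seed, spec.gc)
    element_seqs: dict[str, str] = {spec.mite.name: mite_seq}
    for plan in spec.elements:
        element_seqs[plan.name] = _build_element(rng_elements, plan, spec.gc)
    library = [
        ISElement(p.name, p.family, element_seqs[p.name])
        for p in spec.elements
        if p.in_library
    ]

    # --- choose sites ----------------------------------------------------
    gene_blocks = [(g.start - 30, g.end + 30) for g in genes]
    cassette_blocks = [(c - 60, c + 60) for c in cassette_sites]
    blocked_all = sorted(gene_blocks + cassette_blocks)
    if inv is not None:
        blocked_outside_inv = sorted(blocked_all + [(c1 - 200, c2 + 200)])
    else:
        blocked_outside_inv = blocked_all

    taken: list[int] = [*cassette_sites, site_is1634, site_is1]
    plans = [spec.mite, *spec.elements]
    shared_sites: dict[str, list[int]] = {}
    extra_a_sites: dict[str, list[int]] = {}
    extra_b_sites: dict[str, list[int]] = {}
    sbp_gene = next(g for g in genes if g.gene_id == "sbp")
    site_sbp_mite = sbp_gene.start + 858

    # intragenic target for the wildtype-specific IS200 copy
    trk_candidates = [
        g
        for g in genes
        if not g.designed
        and g.strand == "+"
        and g.end - g.start >= 900
        and (g.end < c1 - 2000 or g.start > c2 + 2000)
    ]
    if not trk_candidates:
        raise SimulationError("no intragenic target gene available")
    trk_gene = trk_candidates[0]
    site_trk = trk_gene.start + ((trk_gene.end - trk_gene.start) // 2 // 3) * 3

    for plan in plans:
        shared_sites[plan.name] = _sample_sites(
            rng_sites, bb_str, plan.shared_copies, plan.tsd_len, blocked_all, taken
        )
        taken += shared_sites[plan.name]
    # strain-specific sites stay outside the inversion segment
    for plan in plans:
        n_a, n_b = plan.extra_a, plan.extra_b
        fixed_a: list[int] = []
        fixed_b: list[int] = []
        if plan.name == spec.mite.name and n_b:
            if not _tsd_clean(bb_str, site_sbp_mite, plan.tsd_len):
                raise SimulationError("sbp MITE site fails TSD validation")
            fixed_b.append(site_sbp_mite)
            n_b -= 1
        if plan.name == "IS1634like" and n_b:
            if not _tsd_clean(bb_str, site_is1634, plan.tsd_len):
                raise SimulationError("IS1634 site fails TSD validation")
            fixed_b.append(site_is1634)
            n_b -= 1
        if plan.name == "IS200like" and n_a:
            fixed_a.append(site_trk)
            n_a -= 1
        if plan.name == "IS1like" and n_a:
            if not _tsd_clean(bb_str, site_is1, plan.tsd_len):
                raise SimulationError("IS1 site fails TSD validation")
            fixed_a.append(site_is1)
            n_a -= 1
        extra_a_sites[plan.name] = fixed_a + _sample_sites(
            rng_sites, bb_str, n_a, plan.tsd_len, blocked_outside_inv, taken
        )
        taken += extra_a_sites[plan.name]
        extra_b_sites[plan.name] = fixed_b + _sample_sites(
            rng_sites, bb_str, n_b, plan.tsd_len, blocked_outside_inv, taken
        )
        taken += extra_b_sites[plan.name]

    # --- build events -----------------------------------------------------
    def element_event(plan: ElementPlan, p: int) -> tuple[_Event, str]:
        strand = "+" if rng_strands.random() < 0.5 else "-"
        oriented = element_seqs[plan.name] if strand == "+" else revcomp(element_seqs[plan.name])
        t = plan.tsd_len
        if t:
            return _Event(pos=p + t, ins=oriented + bb_str[p : p + t]), strand
        return _Event(pos=p, ins=oriented), strand

    events_a: list[_Event] = []
    events_b: list[_Event] = []
    records: list[dict] = []  # (plan, site, strand, origin)
    for plan in plans:
        for origin, sites in (
            ("shared", shared_sites[plan.name]),
            ("extra_a", extra_a_sites[plan.name]),
            ("extra_b", extra_b_sites[plan.name]),
        ):
            for p in sorted(sites):
                ev, strand = element_event(plan, p)
                if origin in ("shared", "extra_a"):
                    events_a.append(ev)
                if origin in ("shared", "extra_b"):
                    events_b.append(ev)
                records.append(
                    {"plan": plan, "site": p, "strand": strand, "origin": origin}
                )
    for c in cassette_sites:
        ev = _Event(pos=c, ins=cassette)
        events_a.append(ev)
        events_b.append(ev)

    events_a.sort(key=lambda e: e.pos)
    events_b.sort(key=lambda e: e.pos)
    map_a, map_b = _EventMap(events_a), _EventMap(events_b)

    def compose(events: list[_Event]) -> str:
        parts = []
        last = 0
        for e in events:
            parts.append(bb_str[last : e.pos])
            parts.append(e.ins)
            last = e.pos
        parts.append(bb_str[last:])
        return "".join(parts)

    seq_a = compose(events_a)
    seq_b_linear = compose(events_b)

    if inv is not None:
        inv_a = (map_a.map(c1), map_a.map_left(c2))
        inv_b = (map_b.map(c1), map_b.map_left(c2))
        s_b, e_b = inv_b
        seq_b = seq_b_linear[:s_b] + revcomp(seq_b_linear[s_b:e_b]) + seq_b_linear[e_b:]
    else:
        inv_a = inv_b = None
        s_b = e_b = -1  # flip_b becomes the identity
        seq_b = seq_b_linear

    genome_a = GenomeRecord(id="wildtype", seq=seq_a)
    genome_b = GenomeRecord(id="mutant", seq=seq_b)

    def flip_b(interval: tuple[int, int]) -> tuple[int, int]:
        s, e = interval
        if s >= s_b and e <= e_b:
            return (s_b + e_b - e, s_b + e_b - s)
        return interval

    flip = {"+": "-", "-": "+"}

    # --- truth: element occurrences --------------------------------------
    elem_rows = []
    for rec in records:
        plan, p, strand, origin = rec["plan"], rec["site"], rec["strand"], rec["origin"]
        t = plan.tsd_len
        tsd_seq = bb_str[p : p + t]
        for gm, mp, here in (
            ("wildtype", map_a, origin in ("shared", "extra_a")),
            ("mutant", map_b, origin in ("shared", "extra_b")),
        ):
            if not here:
                continue
            start = mp.map_left(p) + t
            end = start + plan.length
            st = strand
            if gm == "mutant":
                s2, e2 = flip_b((start, end))
                if (s2, e2) != (start, end):
                    st = flip[strand]
                start, end = s2, e2
            elem_rows.append(
                {
                    "genome": gm,
                    "element": plan.name,
                    "family": plan.family,
                    "start": start,
                    "end": end,
                    "strand": st,
                    "tsd_len": t,
                    "tsd_seq": tsd_seq,
                    "origin": origin,
                }
            )
    truth_elements = pd.DataFrame(elem_rows).sort_values(
        ["genome", "start"], ignore_index=True
    )

    # --- truth: strain-specific insertion calls ---------------------------
    # An insertion whose last base equals the preceding backbone base is
    # ambiguous in placement; calls are left-normalized, so the truth is too.
    diff_rows = []
    for rec in records:
        plan, p, strand, origin = rec["plan"], rec["site"], rec["strand"], rec["origin"]
        if origin == "shared":
            continue
        carrier = "A" if origin == "extra_a" else "B"
        mp_car = map_a if carrier == "A" else map_b
        mp_oth = map_b if carrier == "A" else map_a
        t = plan.tsd_len
        oriented = element_seqs[plan.name] if strand == "+" else revcomp(element_seqs[plan.name])
        ins_str = bb_str[p : p + t] + oriented
        p_call = p
        while p_call > 0 and ins_str[-1] == bb_str[p_call - 1]:
            ins_str = bb_str[p_call - 1] + ins_str[:-1]
            p_call -= 1
        start = mp_car.map_left(p_call)
        context = "intergenic"
        hit_gene = ""
        for g in genes:
            if g.start < p < g.end:
                context, hit_gene = "intragenic", g.gene_id
                break
        diff_rows.append(
            {
                "diff_id": f"{plan.name}_{origin}_{p}",
                "element": plan.name,
                "family": plan.family,
                "carrier": carrier,
                "backbone_pos": p,
                "site_in_other": mp_oth.map_left(p_call),
                "call_start": start,
                "call_end": start + t + plan.length,
                "call_len": t + plan.length,
                "strand": strand,
                "context": context,
                "hit_gene": hit_gene,
            }
        )
    diff_columns = [
        "diff_id", "element", "family", "carrier", "backbone_pos",
        "site_in_other", "call_start", "call_end", "call_len", "strand",
        "context", "hit_gene",
    ]
    truth_diffs = pd.DataFrame(diff_rows, columns=diff_columns).sort_values(
        "call_start", ignore_index=True
    )

    if inv is not None:
        truth_inversion = {
            "interval_a": inv_a,
            "interval_b": inv_b,
            "length_a": inv_a[1] - inv_a[0],
            "flank_repeat_len": inv.cassette_len,
            "flank_copy_number": inv.cassette_copies,
        }
    else:
        truth_inversion = {}

    # --- truth: expression effects ----------------------------------------
    effect_rows = [
        {"gene_id": n, "strain": "mutant", "factor": 4.0, "diff_id": "sbp_cluster"}
        for n in sbp_names
    ]
    effect_rows += [
        {"gene_id": n, "strain": "mutant", "factor": 0.25, "diff_id": "is1634_operon"}
        for n in ["lipo", "duf1995", "samMT"]
    ]
    effect_rows += [
        {"gene_id": n, "strain": "wildtype", "factor": 0.1, "diff_id": "is1_mbl"}
        for n in ["unch", "mbl"]
    ]
    truth_effects = pd.DataFrame(effect_rows)

    # --- features ----------------------------------------------------------
    def features_for(gm: str, mp: _EventMap, events: list[_Event]) -> list[Feature]:
        ev_pos = [e.pos for e in events]
        feats = []
        for g in genes:
            start, end = mp.map_left(g.start), mp.map(g.end)
            strand = g.strand
            interrupted = any(g.start < q < g.end for q in ev_pos)
            if gm == "mutant":
                s2, e2 = flip_b((start, end))
                if (s2, e2) != (start, end):
                    strand = flip[strand]
                start, end = s2, e2
            attrs_gene = {"ID": f"gene-{g.gene_id}"}
            attrs_cds = {"ID": g.gene_id, "Parent": f"gene-{g.gene_id}"}
            if interrupted:
                attrs_cds["note"] = "interrupted"
            feats.append(
                Feature(gm, start, end, strand, "gene", attrs_gene, source="sim")
            )
            feats.append(
                Feature(gm, start, end, strand, "CDS", attrs_cds, source="sim")
            )
        feats.sort(key=lambda f: (f.start, f.ftype))
        return feats

    features_a = features_for("wildtype", map_a, events_a)
    features_b = features_for("mutant", map_b, events_b)

    # --- validation primers around the sbp MITE ----------------------------
    site_a = map_a.map_left(site_sbp_mite)
    f0 = site_a - 120
    fwd = seq_a[f0 : f0 + 22]
    r0 = f0 + 189 - 18
    rev = revcomp(seq_a[r0 : r0 + 18])
    for primer in (fwd, rev):
        for g in (seq_a, seq_b):
            occ = g.count(primer) + g.count(revcomp(primer))
            if occ != 1:
                raise SimulationError("validation primer is not unique")
    primers = PrimerPair(fwd=fwd, rev=rev)
    ins_len = spec.mite.tsd_len + spec.mite.length
    expected_amplicons = {"wildtype": 189, "mutant": 189 + ins_len}

    return SimResult(
        spec=spec,
        genome_a=genome_a,
        genome_b=genome_b,
        features_a=features_a,
        features_b=features_b,
        genes=genes,
        library=library,
        mite_seq=mite_seq,
        cassette_seq=cassette,
        element_seqs=element_seqs,
        truth_elements=truth_elements,
        truth_diffs=truth_diffs,
        truth_inversion=truth_inversion,
        truth_effects=truth_effects,
        primers=primers,
        expected_amplicons=expected_amplicons,
    )


def simulate_expression(sim: SimResult, expr: ExpressionPlan | None = None,
                        seed: int | None = None) -> pd.DataFrame:
    """Long-format TPM table for both strains.

    Per gene, a lognormal baseline; planted effects multiply the
    carrier strain's mean; replicate noise is multiplicative with the
    given CV; each sample is renormalized to sum to 1e6 (the planted
    effect mass is a small fraction of the transcriptome, so
    renormalization distorts ratios negligibly).
    """
    expr = expr or sim.spec.expr
    ss = np.random.SeedSequence(sim.spec.seed if seed is None else seed)
    rng = np.random.default_rng(ss.spawn(8)[7])
    genes = [g.gene_id for g in sim.genes]
    base = np.exp(rng.normal(expr.meanlog, expr.sdlog, size=len(genes)))
    effects = {
        (strain, g): 1.0 for strain in ("wildtype", "mutant") for g in genes
    }
    for r in sim.truth_effects.itertuples():
        effects[(r.strain, r.gene_id)] = r.factor
    sigma = float(np.sqrt(np.log1p(expr.cv**2)))
    rows = []
    for strain in ("wildtype", "mutant"):
        mult = np.array([effects[(strain, g)] for g in genes])
        for tp in expr.timepoints:
            for rep in range(1, expr.n_replicates + 1):
                noise = np.exp(rng.normal(0.0, sigma, size=len(genes)))
                vals = base * mult * noise
                vals = vals / vals.sum() * 1e6
                rows.extend(
                    {
                        "gene_id": g,
                        "strain": strain,
                        "timepoint": tp,
                        "replicate": rep,
                        "tpm": v,
                    }
                    for g, v in zip(genes, vals)
                )
    return pd.DataFrame(rows)


def make_sl_mimic(sim: SimResult, dup_len: int = 44_534) -> GenomeRecord:
    """A third assembly ("7806SL-mimic") derived from the wildtype by
    duplicating a dup_len segment to a distant locus, emulating a large
    direct intra-genome duplication."""
    seq = sim.genome_a.seq
    x = sim.truth_inversion["interval_a"][1] + 30_000
    y = x + dup_len + 60_000
    if y + dup_len >= len(seq):
        x = 10_000
        y = x + dup_len + 30_000
    # run boundaries must be sharp for an exact-length call
    for _ in range(10):
        if seq[x - 1] != seq[y - 1] and seq[x + dup_len] != seq[y]:
            break
        y += 1
    segment = seq[x : x + dup_len]
    return GenomeRecord(id="sl_mimic", seq=seq[:y] + segment + seq[y:])


def make_split_cds_example(seed: int = 7) -> dict:
    """A synthetic stand-in for the interrupted sulfate-binding-protein
    gene: a 1,044-nt CDS (347-aa product) receiving a 195-nt insertion
    block after codon 286, engineered so the transcript encodes a
    286-aa product before the junction stop and a 64-aa ATG-initiated
    product downstream — the arithmetic of a MITE-split gene.
    """
    from .impact_annotator import split_products

    offset = 858  # codon boundary: 286 codons upstream of the junction
    for attempt in range(100):
        rng = np.random.default_rng(np.random.SeedSequence([seed, attempt]))
        cds = list(_random_cds(rng, 1044))
        # the downstream product's stop sits off-frame in the CDS tail:
        # codons 287/288 read CTA|AAA in the gene frame (both sense) but
        # supply TAA three frames of the interrupted transcript later
        cds[858:861] = "GGT"
        cds[861:864] = "CTA"
        cds[864:867] = "AAA"
        cds_s = "".join(cds)
        insert = (
            "TAA"  # junction stop: product 1 ends at 286 aa
            + _random_dna(rng, 4, 0.42)
            + "ATG"
            + "".join(rng.choice(SENSE_CODONS, size=61))
            + "GC"  # straddle codon GC+G(cds[858]) stays sense
        )
        assert len(insert) == 195
        got = split_products(cds_s, offset, insert).lengths_aa
        if got == [286, 64]:
            return {"cds": cds_s, "offset": offset, "insert": insert}
    raise SimulationError("split-CDS example construction failed")


def make_extension_example(seed: int = 11) -> dict:
    """A synthetic stand-in for a stop-ablating insertion: the element
    lands just before the stop codon and supplies the next in-frame
    stop itself, extending the CDS by +81 nt.

    Both the old and the new coding region are codon multiples, so the
    extension is necessarily a multiple of 3; +81 is the constructed
    value closest to the ~80-nt extensions seen when an IS element
    lands at a gene's 3' end.
    """
    rng = np.random.default_rng(seed)
    cds = _random_cds(rng, 900)
    offset = 897  # codon boundary just before the stop codon
    # 27 sense codons then a stop: first in-frame stop of the mutated
    # transcript ends at 897 + 84 = 981 nt -> delta = 981 - 900 = +81
    ins_seq = "".join(rng.choice(SENSE_CODONS, size=27)) + "TAA" + "".join(
        rng.choice(SENSE_CODONS, size=12)
    )
    return {"cds": cds, "offset": offset, "insert": ins_seq, "expected_delta": 81}
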