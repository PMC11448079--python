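"""TPM-based differential expression and its overlay on insertion calls.

The contrast model follows standard practice for small-n TPM tables:
per gene and timepoint, a Welch (unequal-variance) t-test between the
two strains on TPM values, Benjamini-Hochberg adjustment within each
timepoint, and a fold-change filter on pseudocounted means. A gene is
significant when |fold change| >= fc_threshold AND q <= q_threshold,
both inclusive.

The overlay then joins each insertion difference to the expression
flags of the genes it can plausibly regulate: the interrupted gene for
intragenic insertions, downstream same-sense genes within a window for
intergenic ones, plus the immediate neighbors.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .genome_io import Feature
from .impact_annotator import ImpactReport

logger = logging.getLogger(__name__)

VAR_FLOOR_REL = 1e-8  # variance floor, relative to squared mean
PSEUDOCOUNT_TPM = 1.0

REQUIRED_COLUMNS = ["gene_id", "strain", "timepoint", "replicate", "tpm"]


def read_expression(path) -> pd.DataFrame:
    """Long-format TSV: gene_id, strain, timepoint, replicate, tpm."""
    table = pd.read_csv(path, sep="\t")
    missing = set(REQUIRED_COLUMNS) - set(table.columns)
    if missing:
        raise ValueError(f"expression table missing columns {sorted(missing)}")
    if (table["tpm"] < 0).any():
        raise ValueError("negative TPM values")
    return table


def tpm_from_counts(counts, lengths) -> np.ndarray:
    """TPM_i = (c_i/l_i) / sum_j(c_j/l_j) * 1e6."""
    counts = np.asarray(counts, dtype=float)
    lengths = np.asarray(lengths, dtype=float)
    if (lengths <= 0).any():
        raise ValueError("gene lengths must be positive")
    if (counts < 0).any():
        raise ValueError("counts must be non-negative")
    rates = counts / lengths
    total = rates.sum()
    if total == 0:
        logger.warning("all-zero counts: TPM undefined, returning zeros")
        return np.zeros_like(rates)
    return rates / total * 1e6


def welch_t(values_a: Sequence[float], values_b: Sequence[float]) -> tuple[float, float, float]:
    """Welch statistic, Satterthwaite df, two-sided p.

    Sign convention: t = (mean_a - mean_b) / se, so swapping the groups
    flips the sign and leaves p unchanged. Two zero-variance groups with
    equal means give p = 1; zero-variance with unequal means gets a
    variance floor (n=2 TPM duplicates tie often enough that dropping
    the gene would bias the screen).
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs n >= 2")
    ma, mb = a.mean(), b.mean()
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if va == 0.0 and vb == 0.0:
        if ma == mb:
            return 0.0, float(len(a) + len(b) - 2), 1.0
        floor = VAR_FLOOR_REL * ((ma + mb) / 2) ** 2 or VAR_FLOOR_REL
        va = vb = floor
    sa, sb = va / len(a), vb / len(b)
    se = math.sqrt(sa + sb)
    t = (ma - mb) / se
    df = (sa + sb) ** 2 / (sa**2 / (len(a) - 1) + sb**2 / (len(b) - 1))
    p = 2 * stats.t.sf(abs(t), df)
    return float(t), float(df), float(p)


def bh_fdr(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values; NaNs pass through untested."""
    p = np.asarray(p_values, dtype=float)
    q = np.full_like(p, np.nan)
    mask = ~np.isnan(p)
    if mask.any():
        if ((p[mask] < 0) | (p[mask] > 1)).any():
            raise ValueError("p-values outside [0, 1]")
        _, qvals, _, _ = multipletests(p[mask], method="fdr_bh")
        q[mask] = qvals
    return q


def _is_significant(fold: float, q: float, fc_threshold: float, q_threshold: float) -> bool:
    """Inclusive on both thresholds (>= fold, <= q)."""
    return fold >= fc_threshold and q <= q_threshold


def flag_de(
    table: pd.DataFrame,
    strain_pair: tuple[str, str],
    timepoints: Sequence[str] | None = None,
    fc_threshold: float = 2.0,
    q_threshold: float = 0.05,
) -> pd.DataFrame:
    """Per gene x timepoint DE results for strain B vs strain A.

    log2_fc uses pseudocounted means (+1 TPM). The BH family is all
    genes tested within one timepoint. Genes without >= 2 replicates in
    both strains at a timepoint are skipped with a log entry.
    """
    strain_a, strain_b = strain_pair
    if timepoints is None:
        timepoints = sorted(table["timepoint"].unique())
    rows = []
    for tp in timepoints:
        sub = table[table["timepoint"] == tp]
        for gene_id, g in sub.groupby("gene_id", sort=True):
            va = g.loc[g["strain"] == strain_a, "tpm"].to_numpy()
            vb = g.loc[g["strain"] == strain_b, "tpm"].to_numpy()
            if len(va) < 2 or len(vb) < 2:
                logger.info("gene %s skipped at %s: missing replicates", gene_id, tp)
                continue
            t, df, p = welch_t(va, vb)
            ratio = (vb.mean() + PSEUDOCOUNT_TPM) / (va.mean() + PSEUDOCOUNT_TPM)
            rows.append(
                {
                    "gene_id": gene_id,
                    "timepoint": tp,
                    "mean_a": va.mean(),
                    "mean_b": vb.mean(),
                    "log2_fc": math.log2(ratio),
                    "fold": max(ratio, 1 / ratio),
                    "t": -t,  # report B-vs-A orientation
                    "df": df,
                    "p": p,
                }
            )
    result = pd.DataFrame(
        rows,
        columns=[
            "gene_id", "timepoint", "mean_a", "mean_b",
            "log2_fc", "fold", "t", "df", "p",
        ],
    )
    if result.empty:
        result["q"] = pd.Series(dtype=float)
        result["significant"] = pd.Series(dtype=bool)
        return result
    result["q"] = np.nan
    for tp in timepoints:
        mask = result["timepoint"] == tp
        if mask.any():
            result.loc[mask, "q"] = bh_fdr(result.loc[mask, "p"].to_numpy())
    result["significant"] = [
        _is_significant(f, q, fc_threshold, q_threshold)
        for f, q in zip(result["fold"], result["q"])
    ]
    return result


@dataclass
class OverlayRow:
    diff_index: int
    carrier: str
    site_in_other: int
    gene_id: str
    relation: str  # hit | downstream | neighbor
    distance: int
    timepoint: str
    log2_fc: float
    q: float
    significant: bool


def overlay(
    impacts: Sequence[ImpactReport],
    de_results: pd.DataFrame,
    features: Sequence[Feature],
    window_genes: int = 4,
    window_nt: int = 5_000,
) -> pd.DataFrame:
    """Join insertion differences to DE flags of candidate target genes.

    For each insertion: the hit gene (intragenic, always included), or
    up to window_genes genes within window_nt that read away from the
    site on their own strand (the genes an inserted element can silence
    or drive), plus both immediate neighbors. One row per (diff, gene,
    timepoint).
    """
    cds = sorted((f for f in features if f.ftype == "CDS"), key=lambda f: f.start)
    de_by_gene = dict(tuple(de_results.groupby("gene_id"))) if not de_results.empty else {}
    rows: list[dict] = []

    def add(ix: int, rep: ImpactReport, gene_id: str, relation: str, distance: int) -> None:
        sub = de_by_gene.get(gene_id)
        if sub is None:
            logger.info("overlay: gene %s has no DE result", gene_id)
            return
        for _, r in sub.iterrows():
            rows.append(
                {
                    "diff_index": ix,
                    "carrier": rep.diff.carrier,
                    "site_in_other": rep.diff.site_in_other,
                    "gene_id": gene_id,
                    "relation": relation,
                    "distance": distance,
                    "timepoint": r["timepoint"],
                    "log2_fc": r["log2_fc"],
                    "q": r["q"],
                    "significant": bool(r["significant"]),
                }
            )

    for ix, rep in enumerate(impacts):
        seen: set[str] = set()
        if rep.context == "intragenic":
            for gid in rep.hit_genes:
                add(ix, rep, gid, "hit", 0)
                seen.add(gid)
            continue
        site = rep.diff.site_in_other
        downstream: list[tuple[int, str]] = []
        for f in cds:
            gid = f.gene_id or "?"
            if f.strand == "+" and f.start >= site and f.start - site <= window_nt:
                downstream.append((f.start - site, gid))
            elif f.strand == "-" and f.end <= site and site - f.end <= window_nt:
                downstream.append((site - f.end, gid))
        for dist, gid in sorted(downstream)[:window_genes]:
            if gid not in seen:
                add(ix, rep, gid, "downstream", dist)
                seen.add(gid)
        for nb in (rep.upstream_gene, rep.downstream_gene):
            if nb is not None and nb.gene_id not in seen:
                add(ix, rep, nb.gene_id, "neighbor", nb.distance)
                seen.add(nb.gene_id)
        if not seen:
            logger.info("overlay: no genes in window for diff %d", ix)
    return pd.DataFrame(
        rows,
        columns=[
            "diff_index", "carrier", "site_in_other", "gene_id", "relation",
            "distance", "timepoint", "log2_fc", "q", "significant",
        ],
    )
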