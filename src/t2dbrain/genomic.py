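"""Biotype/chromosome composition and intra-chromosomal distance statistics.

Genes associated with the same disease process tend to lie near one another,
so the pairwise genomic distance of differential genes within and between
regional gene sets is compared with a Wilcoxon rank-sum test. Distances are
anchored at the strand-aware transcription start site (start on +, end on -)
and only same-chromosome pairs contribute.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = [
    "biotype_composition",
    "chromosome_composition",
    "pairwise_intrachromosomal_distances",
    "wilcoxon_ranksum",
    "DistanceComparison",
    "compare_distance_sets",
]


def _tss(ann: pd.DataFrame, anchor: str = "tss") -> pd.Series:
    if anchor == "tss":
        return pd.Series(
            np.where(ann["strand"] == "+", ann["start"], ann["end"]),
            index=ann["gene_id"],
        )
    if anchor == "midpoint":
        return pd.Series(((ann["start"] + ann["end"]) // 2).to_numpy(), index=ann["gene_id"])
    if anchor == "start":
        return pd.Series(ann["start"].to_numpy(), index=ann["gene_id"])
    raise ValueError(f"unknown anchor {anchor!r}")


def _composition(gene_set, annotation: pd.DataFrame, key: str) -> pd.Series:
    genes = sorted(set(gene_set))
    if not genes:
        raise ValueError("empty gene set")
    ann = annotation.set_index("gene_id")
    vals = []
    missing = 0
    for g in genes:
        if g in ann.index:
            vals.append(str(ann.at[g, key]))
        else:
            vals.append("unknown")
            missing += 1
    if missing:
        logger.warning("%d genes missing from annotation; counted as 'unknown'", missing)
    counts = pd.Series(vals).value_counts()
    return counts / counts.sum()


def biotype_composition(gene_set, annotation: pd.DataFrame) -> pd.Series:
    """Proportion of the gene set per biotype (sums to 1)."""
    return _composition(gene_set, annotation, "biotype")


def chromosome_composition(gene_set, annotation: pd.DataFrame) -> pd.Series:
    """Proportion of the gene set per chromosome (sums to 1)."""
    return _composition(gene_set, annotation, "chromosome")


def _within_distances(genes: list[str], ann: pd.DataFrame, anchor: str) -> np.ndarray:
    tss = _tss(ann, anchor)
    sub = ann[ann["gene_id"].isin(genes)]
    out = []
    for _, grp in sub.groupby("chromosome"):
        pos = tss[grp["gene_id"]].to_numpy(float)
        if pos.size >= 2:
            d = np.abs(pos[:, None] - pos[None, :])
            out.append(d[np.triu_indices(pos.size, k=1)])
    return np.concatenate(out) if out else np.array([])


def _between_distances(a: list[str], b: list[str], ann: pd.DataFrame, anchor: str) -> np.ndarray:
    # genes in both sets are excluded to avoid zero-distance artifacts
    shared = set(a) & set(b)
    a = [g for g in a if g not in shared]
    b = [g for g in b if g not in shared]
    tss = _tss(ann, anchor)
    sa = ann[ann["gene_id"].isin(a)]
    sb = ann[ann["gene_id"].isin(b)]
    out = []
    for c in set(sa["chromosome"]) & set(sb["chromosome"]):
        pa = tss[sa.loc[sa["chromosome"] == c, "gene_id"]].to_numpy(float)
        pb = tss[sb.loc[sb["chromosome"] == c, "gene_id"]].to_numpy(float)
        out.append(np.abs(pa[:, None] - pb[None, :]).ravel())
    return np.concatenate(out) if out else np.array([])


def pairwise_intrachromosomal_distances(
    set_a,
    set_b=None,
    annotation: pd.DataFrame = None,
    anchor: str = "tss",
) -> dict[str, np.ndarray]:
    """Same-chromosome pairwise distances within (and optionally between) sets.

    Returns a dict with keys ``within_a`` (and ``within_b``, ``between`` when a
    second set is supplied). Distances are |anchor_i - anchor_j| in bp.
    """
    a = sorted(set(set_a))
    out = {"within_a": _within_distances(a, annotation, anchor)}
    if set_b is not None:
        b = sorted(set(set_b))
        out["within_b"] = _within_distances(b, annotation, anchor)
        out["between"] = _between_distances(a, b, annotation, anchor)
    return out


def wilcoxon_ranksum(x, y) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney U) test.

    Exact enumeration when n_x + n_y <= 20 with no ties, otherwise the normal
    approximation with tie and continuity correction. Returns (U, p).
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    no_ties = np.unique(np.concatenate([x, y])).size == x.size + y.size
    method = "exact" if (x.size + y.size <= 20 and no_ties) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method, use_continuity=True)
    return float(res.statistic), float(res.pvalue)


@dataclass
class DistanceComparison:
    within_a: np.ndarray
    within_b: np.ndarray
    between: np.ndarray
    p_a_vs_b: float
    p_a_vs_between: float
    p_b_vs_between: float
    anchor: str = "tss"


def compare_distance_sets(set_a, set_b, annotation: pd.DataFrame, anchor: str = "tss") -> DistanceComparison:
    """Full distance comparison between two gene sets with Wilcoxon p-values."""
    d = pairwise_intrachromosomal_distances(set_a, set_b, annotation, anchor)
    return DistanceComparison(
        within_a=d["within_a"],
        within_b=d["within_b"],
        between=d["between"],
        p_a_vs_b=wilcoxon_ranksum(d["within_a"], d["within_b"])[1]
        if d["within_a"].size and d["within_b"].size else float("nan"),
        p_a_vs_between=wilcoxon_ranksum(d["within_a"], d["between"])[1]
        if d["within_a"].size and d["between"].size else float("nan"),
        p_b_vs_between=wilcoxon_ranksum(d["within_b"], d["between"])[1]
        if d["within_b"].size and d["between"].size else float("nan"),
        anchor=anchor,
    )
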