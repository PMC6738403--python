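"""GWAS SNP gene-set enrichment via the weighted KS running-sum statistic.

SNPs are assigned to genes within strand-aware windows (20 kb beyond the 5'
end, 10 kb beyond the 3' end, inclusive on 1-based positions); each gene is
scored by the most significant assigned SNP (-log10 p). Genes are ranked by
descending score and a gene set's enrichment score (ES) is the signed maximum
deviation of the GSEA running sum: hits increment by |score|^w / sum of set
|score|^w, misses decrement by 1/(N - set size). The null is generated by
random gene-label subsets of the same size; ES is z-scaled by the null
moments, the empirical p is plus-one smoothed, and BH FDR is taken across
sets. A negative-control GWAS (e.g. height) can be run side by side.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "read_gwas",
    "assign_snps_to_genes",
    "gene_scores",
    "enrichment_score",
    "permutation_null",
    "score_and_test_sets",
    "GwasEnrichmentResult",
]


def read_gwas(path: str | Path) -> pd.DataFrame:
    """Read whitespace/tab-delimited summary stats with SNP, CHR, POS/BP, P
    columns (case-insensitive; extra columns ignored). Duplicate SNP ids keep
    the smallest p."""
    df = pd.read_csv(path, sep=r"\s+")
    cols = {c.upper(): c for c in df.columns}
    ren = {}
    for want, aliases in (("SNP", ("SNP", "RSID", "ID")),
                          ("CHR", ("CHR", "CHROM", "CHROMOSOME")),
                          ("POS", ("POS", "BP", "POSITION")),
                          ("P", ("P", "PVAL", "PVALUE", "P_VALUE"))):
        for a in aliases:
            if a in cols:
                ren[cols[a]] = want
                break
        else:
            raise ValueError(f"GWAS table lacks a {want} column")
    df = df.rename(columns=ren)[["SNP", "CHR", "POS", "P"]]
    df = df.sort_values("P").drop_duplicates("SNP", keep="first").reset_index(drop=True)
    return df


def assign_snps_to_genes(
    gwas: pd.DataFrame,
    annotation: pd.DataFrame,
    upstream: int = 20_000,
    downstream: int = 10_000,
) -> dict[str, np.ndarray]:
    """Map SNPs into strand-aware gene windows.

    + strand: [start - upstream, end + downstream]; - strand:
    [start - downstream, end + upstream]; membership is inclusive on 1-based
    positions, and a SNP may land in several overlapping windows. Returns
    gene_id -> array of row indices into ``gwas``.
    """
    gwas = gwas.reset_index(drop=True)  # assignment indices are positional
    shared = set(gwas["CHR"].astype(str)) & set(annotation["chromosome"].astype(str))
    if not shared:
        logger.warning(
            "no shared chromosome names between GWAS (%s...) and annotation (%s...)",
            sorted(set(gwas["CHR"].astype(str)))[:3],
            sorted(set(annotation["chromosome"].astype(str)))[:3],
        )
    out: dict[str, np.ndarray] = {}
    for c in sorted(shared):
        snp = gwas[gwas["CHR"].astype(str) == c]
        pos = snp["POS"].to_numpy(np.int64)
        order = np.argsort(pos)
        pos_sorted = pos[order]
        rows = snp.index.to_numpy()[order]
        ann = annotation[annotation["chromosome"].astype(str) == c]
        plus = ann["strand"].to_numpy() == "+"
        lo = np.where(plus, ann["start"].to_numpy() - upstream, ann["start"].to_numpy() - downstream)
        hi = np.where(plus, ann["end"].to_numpy() + downstream, ann["end"].to_numpy() + upstream)
        left = np.searchsorted(pos_sorted, lo, side="left")
        right = np.searchsorted(pos_sorted, hi, side="right")
        for g, l, r in zip(ann["gene_id"], left, right):
            if r > l:
                out[g] = rows[l:r]
    return out


def gene_scores(assignment: dict[str, np.ndarray], gwas: pd.DataFrame) -> pd.Series:
    """Best-SNP gene scores: max over assigned SNPs of -log10 p, sorted by
    descending score with gene-id tie-breaking. Genes with no assigned SNP
    are absent (not scored 0)."""
    if not assignment:
        raise ValueError("empty SNP-to-gene assignment")
    p = gwas["P"].to_numpy(float)
    scores = {g: float(-np.log10(np.clip(p[idx], 1e-300, 1.0).min()))
              for g, idx in assignment.items()}
    s = pd.Series(scores, name="score")
    order = sorted(s.index, key=lambda g: (-s[g], g))
    return s.loc[order]


def enrichment_score(ranking: pd.Series, gene_set, weight: float = 1.0) -> float:
    """Signed maximum-deviation KS running-sum enrichment score.

    ``ranking`` is descending-sorted gene scores. Hits step up by
    |score|^weight normalised over the set; misses step down by 1/(N - m).
    With ``weight>0`` and all set scores zero the computation falls back to
    unweighted increments with a warning. A set covering the whole ranking
    has no misses and ES = 1. When the maximal positive and negative
    deviations tie in magnitude the positive one is reported.
    """
    genes = ranking.index.to_numpy()
    scores = ranking.to_numpy(float)
    hit = np.isin(genes, list(gene_set))
    m = int(hit.sum())
    N = genes.size
    if m == 0:
        raise ValueError("gene set does not intersect the ranking")
    w = np.abs(scores) ** weight
    denom = w[hit].sum()
    if weight > 0 and denom == 0:
        logger.warning("all set scores are zero; falling back to unweighted increments")
        w = np.ones(N)
        denom = float(m)
    elif weight == 0:
        denom = float(m)
    steps = np.where(hit, w / denom, 0.0)
    if N > m:
        steps = steps - np.where(hit, 0.0, 1.0 / (N - m))
    running = np.cumsum(steps)
    i_max = int(np.argmax(running))
    i_min = int(np.argmin(running))
    es_pos = running[i_max]
    es_neg = min(running[i_min], 0.0)
    return float(es_pos if es_pos >= -es_neg else es_neg)


def _batch_es(scores: np.ndarray, hit_pos: np.ndarray, weight: float) -> np.ndarray:
    """ES for many gene subsets at once.

    ``scores`` is the descending ranking (length N); ``hit_pos`` is
    (n_perm, m) of sorted 0-based hit rank positions. The running sum's
    extrema occur immediately after (maximum) or immediately before
    (minimum) a hit, so only hit positions need evaluation.
    """
    N = scores.size
    n_perm, m = hit_pos.shape
    w = np.abs(scores) ** weight if weight != 0 else np.ones(N)
    hw = w[hit_pos]
    denom = hw.sum(axis=1, keepdims=True)
    fallback = denom[:, 0] == 0
    if fallback.any():
        hw[fallback] = 1.0
        denom[fallback] = m
    cum = np.cumsum(hw, axis=1) / denom
    j = np.arange(m)[None, :]
    miss_rate = 1.0 / (N - m) if N > m else 0.0
    misses_before = (hit_pos - j) * miss_rate
    after = cum - misses_before
    before = np.concatenate([np.zeros((n_perm, 1)), cum[:, :-1]], axis=1) - misses_before
    es_pos = after.max(axis=1)
    es_neg = np.minimum(before.min(axis=1), 0.0)
    return np.where(es_pos >= -es_neg, es_pos, es_neg)


def permutation_null(
    ranking: pd.Series,
    set_size: int,
    n_perm: int = 20_000,
    seed: int = 0,
    weight: float = 1.0,
    chunk: int = 2_000,
) -> tuple[float, float, np.ndarray]:
    """Null ES distribution from random same-size gene subsets.

    Returns (mean, sd, null sample). Raises if the null is degenerate
    (sd = 0).
    """
    N = len(ranking)
    if not 0 < set_size < N:
        raise ValueError("set_size must lie strictly between 0 and the ranking size")
    rng = np.random.default_rng(seed)
    scores = ranking.to_numpy(float)
    out = np.empty(n_perm)
    done = 0
    while done < n_perm:
        b = min(chunk, n_perm - done)
        keys = rng.random((b, N))
        hit_pos = np.sort(np.argpartition(keys, set_size - 1, axis=1)[:, :set_size], axis=1)
        out[done:done + b] = _batch_es(scores, hit_pos, weight)
        done += b
    mean, sd = float(out.mean()), float(out.std(ddof=1))
    if sd == 0:
        raise ValueError("degenerate ranking: permutation null has zero spread")
    return mean, sd, out


@dataclass
class GwasEnrichmentResult:
    table: pd.DataFrame  # set, n_mapped, es, z, p_emp, fdr, significant [+ control columns]
    n_perm: int
    weight: float


def score_and_test_sets(
    ranking: pd.Series,
    sets: dict[str, set[str]],
    n_perm: int = 20_000,
    seed: int = 0,
    weight: float = 1.0,
    min_set_size: int = 10,
    control_ranking: pd.Series | None = None,
) -> GwasEnrichmentResult:
    """ES, z, one-sided empirical p and BH FDR for each gene set.

    z = (ES_obs - mean_null) / sd_null; p_emp = (1 + #{null >= obs}) /
    (n_perm + 1); FDR is BH across all tested sets; significance is flagged
    at FDR < 0.05. When ``control_ranking`` is given (the negative-control
    GWAS), the same sets are tested against it and reported side by side.
    """
    from .de import bh_adjust

    rows = []
    nulls_cache: dict[int, tuple[float, float, np.ndarray]] = {}
    for i, (name, genes) in enumerate(sorted(sets.items())):
        mapped = set(genes) & set(ranking.index)
        if len(mapped) < min_set_size:
            logger.warning("set %s has %d mapped genes (< %d); skipped", name, len(mapped), min_set_size)
            continue
        es = enrichment_score(ranking, mapped, weight)
        m = len(mapped)
        if m not in nulls_cache:
            nulls_cache[m] = permutation_null(ranking, m, n_perm, seed=seed + 17 * m, weight=weight)
        mean, sd, null = nulls_cache[m]
        z = (es - mean) / sd
        p_emp = (1.0 + float((null >= es).sum())) / (n_perm + 1.0)
        rows.append({"set": name, "n_mapped": m, "es": es, "z": z, "p_emp": p_emp})
    table = pd.DataFrame(rows)
    if table.empty:
        return GwasEnrichmentResult(table=table, n_perm=n_perm, weight=weight)
    table["fdr"] = bh_adjust(table["p_emp"].to_numpy())
    table["significant"] = table["fdr"] < 0.05

    if control_ranking is not None:
        ctrl = score_and_test_sets(
            control_ranking, sets, n_perm=n_perm, seed=seed + 1_000_003,
            weight=weight, min_set_size=min_set_size,
        ).table
        if not ctrl.empty:
            ctrl = ctrl.rename(columns={
                "es": "control_es", "z": "control_z",
                "p_emp": "control_p_emp", "fdr": "control_fdr",
                "significant": "control_significant",
            })[["set", "control_es", "control_z", "control_p_emp", "control_fdr",
                "control_significant"]]
            table = table.merge(ctrl, on="set", how="left")
    return GwasEnrichmentResult(table=table, n_perm=n_perm, weight=weight)
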