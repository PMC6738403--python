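"""Cell-type/region specificity index and module-marker Fisher enrichment.

The specificity index (SI) of gene g in type t is the mean, over all pairwise
comparisons of t against the other types, of the rank of g when genes are
ordered by descending fold change of t over the comparison type. A
permutation p-value (gene values shuffled across types) converts the SI into
a per-gene, per-type pSI; thresholding the pSI at 0.01 / 0.001 / 0.0001
yields nested marker sets. Module-marker enrichment is a one-sided Fisher
exact test on the 2x2 in-module x in-set table over a shared gene universe,
Bonferroni-corrected across the (module x set) grid within each threshold.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = [
    "specificity_index",
    "marker_sets_from_psi",
    "fisher_enrichment",
    "PSI_THRESHOLDS",
]

PSI_THRESHOLDS = (0.01, 0.001, 0.0001)


def _si_ranks(log_expr: np.ndarray) -> np.ndarray:
    """Mean cross-comparison rank per (type, gene); log_expr is types x genes.

    For each ordered pair (t, t'), genes are ranked by descending
    log_expr[t] - log_expr[t'] (rank 1 = most t-specific); SI_{t,g} is the
    mean rank over the T-1 comparisons of type t.
    """
    T, G = log_expr.shape
    si = np.zeros((T, G))
    for t in range(T):
        acc = np.zeros(G)
        for u in range(T):
            if u == t:
                continue
            fc = log_expr[t] - log_expr[u]
            order = np.argsort(-fc, kind="stable")
            ranks = np.empty(G)
            ranks[order] = np.arange(1, G + 1)
            acc += ranks
        si[t] = acc / (T - 1)
    return si


def specificity_index(
    mean_expr: pd.DataFrame, n_perm: int = 2000, seed: int = 0
) -> pd.DataFrame:
    """Permutation pSI p-values, types x genes.

    ``mean_expr`` holds per-type mean expression (types in rows). Non-positive
    values are shifted above zero with a warning before taking logs. Null
    datasets shuffle each gene's values independently across types; within
    each type the null SI values are pooled across genes and the p-value for
    (t, g) is the plus-one-smoothed fraction of pooled null SIs at most the
    observed SI. Pooling makes the floor 1/(1 + n_perm * n_genes), so a gene
    expressed in only one type can reach a genuinely small p, and keeps the
    p-values uniform under exchangeability.
    """
    if mean_expr.shape[0] < 3:
        raise ValueError("need at least 3 types")
    E = mean_expr.to_numpy(float)
    if (E <= 0).any():
        shift = -E.min() + 1e-6 * max(E.max() - E.min(), 1.0)
        logger.warning("non-positive expression values; shifting by %.3g before log", shift)
        E = E + shift
    L = np.log(E)
    T, G = L.shape
    obs = _si_ranks(L)
    rng = np.random.default_rng(seed)
    count = np.zeros((T, G), dtype=np.int64)
    for _ in range(n_perm):
        perm = np.argsort(rng.random((T, G)), axis=0)
        si_p = _si_ranks(np.take_along_axis(L, perm, axis=0))
        for t in range(T):
            null_sorted = np.sort(si_p[t])
            count[t] += np.searchsorted(null_sorted, obs[t], side="right")
    p = (1.0 + count) / (1.0 + n_perm * G)
    return pd.DataFrame(p, index=mean_expr.index, columns=mean_expr.columns)


def marker_sets_from_psi(
    psi: pd.DataFrame, thresholds: tuple[float, ...] = PSI_THRESHOLDS
) -> dict[float, dict[str, set[str]]]:
    """Threshold the pSI matrix into nested marker sets per type.

    Returns {threshold: {type: gene set}}; stricter thresholds give subsets
    of looser ones by construction.
    """
    out: dict[float, dict[str, set[str]]] = {}
    for tau in thresholds:
        out[tau] = {
            t: set(psi.columns[psi.loc[t] < tau]) for t in psi.index
        }
    return out


def fisher_enrichment(
    modules: dict[str, set[str] | frozenset],
    marker_sets: dict[str, set[str]],
    universe: set[str],
    threshold_label=None,
) -> pd.DataFrame:
    """One-sided (greater) Fisher exact enrichment of modules in marker sets.

    Each (module, set) cell tests the 2x2 table of membership over
    ``universe``; Bonferroni adjustment multiplies by the number of cells in
    the grid. Returns a DataFrame with overlap, odds_ratio, p, p_bonferroni
    and a significance-star column.
    """
    if not universe:
        raise ValueError("empty universe")
    uni = set(universe)
    n_tests = len(modules) * len(marker_sets)
    rows = []
    for mod_name, mod_genes in modules.items():
        mg = set(mod_genes) & uni
        if not set(mod_genes) <= uni:
            logger.warning("module %s has genes outside the universe; intersecting", mod_name)
        for set_name, set_genes in marker_sets.items():
            sg = set(set_genes) & uni
            a = len(mg & sg)
            b = len(mg) - a
            c = len(sg) - a
            d = len(uni) - a - b - c
            odds, p = stats.fisher_exact([[a, b], [c, d]], alternative="greater")
            rows.append((mod_name, set_name, a, len(mg), len(sg), odds, p,
                         min(1.0, p * n_tests)))
    out = pd.DataFrame(
        rows,
        columns=["module", "marker_set", "overlap", "module_size", "set_size",
                 "odds_ratio", "p", "p_bonferroni"],
    )
    out["stars"] = out["p_bonferroni"].map(_stars)
    if threshold_label is not None:
        out.insert(0, "psi_threshold", threshold_label)
    return out


def _stars(p: float) -> str:
    if not np.isfinite(p):
        return ""
    for cut, s in ((1e-4, "****"), (1e-3, "***"), (1e-2, "**"), (5e-2, "*")):
        if p < cut:
            return s
    return ""
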