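"""Signed weighted co-expression network analysis.

Pipeline: per-gene residualisation of the expression matrix on known
covariates and surrogate variables; soft-threshold selection by the
scale-free topology criterion; signed adjacency
a_ij = ((1 + cor_ij)/2)^beta; topological overlap (TOM) similarity; module
detection by average-linkage clustering of 1 - TOM with a deterministic
height-scan cut (the height maximising the number of clusters of at least
``min_module_size`` genes); eigengene-based module merging; kME retention
filtering; module-trait statistics; gene significance / module membership;
and hub calling on the strongest intramodular edges.

The height-scan cut is a deterministic, oracle-testable replacement for
dynamic hybrid tree cutting; minimum module size semantics are preserved.
Pearson correlation is used throughout.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

logger = logging.getLogger(__name__)

__all__ = [
    "NetworkConfig",
    "CoexpressionResult",
    "residualize",
    "pick_soft_threshold",
    "signed_adjacency",
    "tom_similarity",
    "detect_modules",
    "module_eigengene",
    "merge_modules",
    "kme_filter",
    "module_trait_stats",
    "gs_mm",
    "hub_genes",
    "run_network",
]


@dataclass
class NetworkConfig:
    powers: tuple[int, ...] = tuple(range(1, 21))
    rsq_cut: float = 0.85
    merge_cut_height: float = 0.15
    min_module_size: int = 40
    min_kme: float = 0.7
    network_type: str = "signed"

    def validate(self) -> None:
        if not 0.0 < self.merge_cut_height < 1.0:
            raise ValueError("merge_cut_height must lie in (0,1)")
        if not 0.0 < self.min_kme < 1.0:
            raise ValueError("min_kme must lie in (0,1)")
        if self.min_module_size < 2:
            raise ValueError("min_module_size must be >= 2")


def residualize(rlog_matrix, covariates_design: np.ndarray) -> pd.DataFrame | np.ndarray:
    """Per-gene OLS residuals of expression (genes x samples) on the design.

    Residuals are orthogonal to every design column. Raises on rank-deficient
    designs, naming the collinear columns.
    """
    X = np.asarray(covariates_design, float)
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # identify columns whose removal restores full rank
        bad = [j for j in range(X.shape[1])
               if np.linalg.matrix_rank(np.delete(X, j, axis=1)) == rank]
        raise ValueError(f"design is rank deficient; collinear columns: {bad}")
    Y = np.asarray(rlog_matrix, float)
    Q, _ = np.linalg.qr(X)
    R = Y - (Y @ Q) @ Q.T
    if isinstance(rlog_matrix, pd.DataFrame):
        return pd.DataFrame(R, index=rlog_matrix.index, columns=rlog_matrix.columns)
    return R


def signed_adjacency(X, beta: float) -> np.ndarray:
    """Signed adjacency a_ij = ((1 + cor(x_i, x_j))/2)^beta, zero diagonal.

    ``X`` is genes x samples.
    """
    if beta < 1:
        raise ValueError("beta must be >= 1")
    C = np.corrcoef(np.asarray(X, float))
    A = ((1.0 + np.clip(C, -1.0, 1.0)) / 2.0) ** beta
    np.fill_diagonal(A, 0.0)
    return A


def pick_soft_threshold(
    X, powers=tuple(range(1, 21)), rsq_cut: float = 0.85, n_bins: int = 10
) -> tuple[int, pd.DataFrame]:
    """Scale-free topology criterion for the soft-threshold power.

    For each power: build the signed adjacency, compute connectivity
    k_i = sum_j a_ij, bin k into ``n_bins`` equal-width bins, and regress
    log10 of the bin frequency on log10 of the bin's mean k (empty bins
    dropped); the signed fit index is -sign(slope) * R^2. The chosen beta is
    the smallest power reaching ``rsq_cut``. If none does, the fit index is
    uninformative (raising the power always sparsifies the network toward an
    apparently better fit), so the conventional signed-network default for
    the sample size is used instead, with a warning: 18 below 20 samples, 16
    below 30, 14 below 40, 12 otherwise.
    """
    Xa = np.asarray(X, float)
    keep = Xa.std(axis=1) > 0
    if not keep.all():
        logger.warning("removing %d constant genes before soft-threshold scan", int((~keep).sum()))
        Xa = Xa[keep]
    if Xa.shape[0] < 3:
        raise ValueError("need at least 3 non-constant genes")
    C = np.corrcoef(Xa)
    base = (1.0 + np.clip(C, -1.0, 1.0)) / 2.0
    np.fill_diagonal(base, 0.0)
    rows = []
    for b in powers:
        k = (base ** b).sum(axis=1)
        k = k[k > 0]
        edges = np.linspace(k.min(), k.max() + 1e-12, n_bins + 1)
        which = np.clip(np.digitize(k, edges) - 1, 0, n_bins - 1)
        freq, meank = [], []
        for i in range(n_bins):
            m = which == i
            if m.any():
                freq.append(m.sum())
                meank.append(k[m].mean())
        if len(freq) < 3:
            rows.append((b, np.nan, np.nan, float(k.mean())))
            continue
        lx, ly = np.log10(meank), np.log10(freq)
        slope, _, r, _, _ = stats.linregress(lx, ly)
        rows.append((b, -np.sign(slope) * r**2, slope, float(k.mean())))
    table = pd.DataFrame(rows, columns=["power", "sft_rsq", "slope", "mean_k"])
    ok = table[table["sft_rsq"] >= rsq_cut]
    if len(ok):
        beta = int(ok["power"].iloc[0])
    else:
        n = Xa.shape[1]
        default = 18 if n < 20 else 16 if n < 30 else 14 if n < 40 else 12
        beta = int(min(default, max(powers)))
        logger.warning("no power reached signed R^2 >= %.2f; falling back to the "
                       "signed-network default beta=%d for %d samples", rsq_cut, beta, n)
    return beta, table


def tom_similarity(A: np.ndarray) -> np.ndarray:
    """Topological overlap matrix.

    TOM_ij = (sum_{u != i,j} a_iu a_uj + a_ij) / (min(k_i, k_j) + 1 - a_ij),
    TOM_ii = 1. The numerator's shared-neighbour sum is (A @ A)_ij since the
    diagonal of A is zero.
    """
    A = np.asarray(A, float)
    if not np.allclose(A, A.T):
        raise ValueError("adjacency must be symmetric")
    if np.any(np.diag(A) != 0):
        raise ValueError("adjacency diagonal must be zero")
    k = A.sum(axis=1)
    shared = A @ A
    denom = np.minimum(k[:, None], k[None, :]) + 1.0 - A
    tom = (shared + A) / denom
    np.fill_diagonal(tom, 1.0)
    return tom


def detect_modules(diss_tom: np.ndarray, min_module_size: int = 40,
                   cohesion: float = 0.9) -> np.ndarray:
    """Height-scan module detection on a TOM dissimilarity matrix.

    Average-linkage clustering; the cut height is scanned over the
    {0.05, 0.06, ..., 0.99, 0.995} quantiles of the dendrogram merge heights
    and the height maximising the number of clusters with at least
    ``min_module_size`` members is chosen (ties broken toward the smaller
    height). The grid reaches low quantiles because with many unstructured
    genes most dendrogram merges happen near the top, far above the heights
    at which real modules are still separate. Genes in clusters below the
    minimum size get label 0; modules are numbered 1, 2, ... by decreasing
    size.

    A size-eligible cluster only counts as a module if it is cohesive: its
    mean within-cluster dissimilarity must fall below ``cohesion`` times the
    overall mean off-diagonal dissimilarity. Without this check, cutting a
    dendrogram of unstructured genes inside its narrow top band of merge
    heights yields arbitrary large chunks that are no tighter than the
    background.
    """
    D = np.asarray(diss_tom, float)
    n = D.shape[0]
    Z = hierarchy.linkage(squareform(D, checks=False), method="average")
    heights = Z[:, 2]
    d_bar = float(D[~np.eye(n, dtype=bool)].mean())

    def _module_ids(lab: np.ndarray) -> list[int]:
        sizes = np.bincount(lab)
        out = []
        for c in np.flatnonzero(sizes >= min_module_size):
            if c == 0:
                continue
            m = lab == c
            intra = D[np.ix_(m, m)]
            if intra[~np.eye(m.sum(), dtype=bool)].mean() <= cohesion * d_bar:
                out.append(int(c))
        return out

    qs = np.append(np.arange(0.05, 0.9999, 0.01), 0.995)
    best_labels, best_mods, best_key = None, [], (-1, -1)
    for q in sorted(qs):
        h = float(np.quantile(heights, q))
        lab = hierarchy.fcluster(Z, t=h, criterion="distance")
        mods = _module_ids(lab)
        covered = int(np.isin(lab, mods).sum())
        # maximise module count, then gene coverage; remaining ties keep the
        # smallest height (the first scan hit)
        if (len(mods), covered) > best_key:
            best_key, best_labels, best_mods = (len(mods), covered), lab, mods
    best_count = best_key[0]
    if best_count == 0:
        logger.warning("no cohesive cluster reaches min_module_size=%d; all genes unassigned",
                       min_module_size)
        return np.zeros(n, dtype=int)
    lab = best_labels
    sizes = np.bincount(lab)
    # number modules by decreasing size (ties by original cluster id)
    order = sorted(best_mods, key=lambda c: (-sizes[c], c))
    mapping = {c: i + 1 for i, c in enumerate(order)}
    return np.array([mapping.get(c, 0) for c in lab], dtype=int)


def module_eigengene(X, labels: np.ndarray) -> pd.DataFrame:
    """First principal component of each module's standardised submatrix.

    ``X`` is genes x samples. Each eigengene is scaled to unit variance and
    sign-anchored so that its mean correlation with member genes is positive.
    Returns samples x modules (columns ``ME<k>``).
    """
    Xa = np.asarray(X, float)
    labels = np.asarray(labels, int)
    n = Xa.shape[1]
    mes = {}
    for m in sorted(set(labels) - {0}):
        sub = Xa[labels == m]
        sd = sub.std(axis=1, ddof=0)
        sd[sd == 0] = 1.0
        Zs = (sub - sub.mean(axis=1, keepdims=True)) / sd[:, None]
        # first right singular vector in sample space
        _, _, Vt = np.linalg.svd(Zs, full_matrices=False)
        me = Vt[0]
        cors = np.array([np.corrcoef(me, g)[0, 1] for g in Zs])
        if np.nanmean(cors) < 0:
            me = -me
        me = (me - me.mean()) / me.std(ddof=1)
        mes[f"ME{m}"] = me
    cols = sorted(mes, key=lambda s: int(s[2:]))
    idx = X.columns if isinstance(X, pd.DataFrame) else pd.RangeIndex(n)
    return pd.DataFrame({c: mes[c] for c in cols}, index=idx)


def merge_modules(X, labels: np.ndarray, merge_cut_height: float = 0.15) -> np.ndarray:
    """Merge modules whose eigengenes are closer than ``merge_cut_height``
    in 1 - cor dissimilarity (average linkage), iterated to a fixed point."""
    labels = np.asarray(labels, int).copy()
    while True:
        mods = sorted(set(labels) - {0})
        if len(mods) < 2:
            return labels
        ME = module_eigengene(X, labels)
        C = np.corrcoef(ME.to_numpy().T)
        D = np.clip(1.0 - C, 0.0, 2.0)
        np.fill_diagonal(D, 0.0)
        Z = hierarchy.linkage(squareform(D, checks=False), method="average")
        groups = hierarchy.fcluster(Z, t=merge_cut_height, criterion="distance")
        if len(set(groups)) == len(mods):
            return _renumber(labels)
        mapping = {}
        for g in sorted(set(groups)):
            members = [mods[i] for i in np.flatnonzero(groups == g)]
            for m in members:
                mapping[m] = members[0]
        labels = np.array([mapping.get(l, 0) for l in labels], dtype=int)


def _renumber(labels: np.ndarray) -> np.ndarray:
    sizes = pd.Series(labels[labels != 0]).value_counts()
    order = sorted(sizes.index, key=lambda c: (-sizes[c], c))
    mapping = {c: i + 1 for i, c in enumerate(order)}
    return np.array([mapping.get(l, 0) for l in labels], dtype=int)


def kme_filter(X, labels: np.ndarray, min_kme: float = 0.7, min_module_size: int = 40) -> np.ndarray:
    """Reassign genes with cor(gene, own-module eigengene) below ``min_kme``
    to the background (label 0); dissolve modules that drop below the
    minimum size."""
    labels = np.asarray(labels, int).copy()
    if not (set(labels) - {0}):
        return labels
    ME = module_eigengene(X, labels)
    Xa = np.asarray(X, float)
    for m in sorted(set(labels) - {0}):
        me = ME[f"ME{m}"].to_numpy()
        idx = np.flatnonzero(labels == m)
        for i in idx:
            g = Xa[i]
            if g.std() == 0 or np.corrcoef(g, me)[0, 1] < min_kme:
                labels[i] = 0
    sizes = pd.Series(labels[labels != 0]).value_counts()
    for m, sz in sizes.items():
        if sz < min_module_size:
            labels[labels == m] = 0
    return _renumber(labels)


def module_trait_stats(ME: pd.DataFrame, status) -> pd.DataFrame:
    """Pearson r of each eigengene with binary status, with a Student-t
    p-value on n - 2 degrees of freedom."""
    st = np.asarray(status, float)
    n = st.size
    if n < 3:
        raise ValueError("need at least 3 samples")
    rows = []
    for c in ME.columns:
        me = ME[c].to_numpy(float)
        if me.std() == 0:
            rows.append((c, np.nan, np.nan))
            continue
        r = float(np.corrcoef(me, st)[0, 1])
        r_ = np.clip(r, -0.9999999999, 0.9999999999)
        t = r_ * np.sqrt((n - 2) / (1.0 - r_**2))
        p = 2.0 * stats.t.sf(abs(t), n - 2)
        rows.append((c, r, float(p)))
    return pd.DataFrame(rows, columns=["module", "r", "p"]).set_index("module")


def gs_mm(X, labels: np.ndarray, ME: pd.DataFrame, status) -> tuple[pd.Series, pd.DataFrame, pd.DataFrame]:
    """Gene significance, module membership, and per-module cor(|GS|, MM).

    GS = cor(gene, status); MM_gm = cor(gene, ME_m). The third return value
    reports, per module, the Pearson correlation between |GS| and the
    own-module MM over member genes with its t-test p-value.
    """
    Xa = np.asarray(X, float)
    st = np.asarray(status, float)
    idx = X.index if isinstance(X, pd.DataFrame) else pd.RangeIndex(Xa.shape[0])

    def _safe_cor(a, b):
        if a.std() == 0 or b.std() == 0:
            return 0.0
        return float(np.corrcoef(a, b)[0, 1])

    gs = pd.Series([_safe_cor(g, st) for g in Xa], index=idx, name="GS")
    mm = pd.DataFrame(
        {c: [_safe_cor(g, ME[c].to_numpy(float)) for g in Xa] for c in ME.columns}, index=idx
    )
    rows = []
    n_min = 3
    for m in sorted(set(np.asarray(labels, int)) - {0}):
        mask = np.asarray(labels, int) == m
        col = f"ME{m}"
        if mask.sum() < n_min or col not in mm.columns:
            continue
        a = np.abs(gs.to_numpy()[mask])
        b = mm[col].to_numpy()[mask]
        r = _safe_cor(a, b)
        k = mask.sum()
        r_ = np.clip(r, -0.9999999999, 0.9999999999)
        t = r_ * np.sqrt((k - 2) / (1.0 - r_**2))
        p = 2.0 * stats.t.sf(abs(t), k - 2)
        rows.append((m, r, float(p), int(k)))
    corr = pd.DataFrame(rows, columns=["module", "cor_gs_mm", "p", "n_genes"]).set_index("module")
    return gs, mm, corr


def hub_genes(
    A: np.ndarray,
    labels: np.ndarray,
    module: int,
    gene_ids=None,
    top_edges: int = 500,
    top_fraction: float = 0.05,
) -> pd.DataFrame:
    """Hubs of one module: degree on the ``top_edges`` strongest intramodular
    edges; the top ``ceil(top_fraction * module_size)`` genes by degree.

    Edge-weight ties break by lexicographic gene-id pair; degree ties break
    by total incident kept-edge weight, then gene id.
    """
    labels = np.asarray(labels, int)
    idx = np.flatnonzero(labels == module)
    if idx.size < 2:
        raise ValueError(f"module {module} has fewer than 2 genes")
    ids = (np.asarray(gene_ids)[idx] if gene_ids is not None
           else np.array([f"g{i}" for i in idx]))
    sub = np.asarray(A, float)[np.ix_(idx, idx)]
    iu, ju = np.triu_indices(idx.size, k=1)
    edges = sorted(
        zip(sub[iu, ju], ids[iu], ids[ju]),
        key=lambda e: (-e[0], min(e[1], e[2]), max(e[1], e[2])),
    )[: int(top_edges)]
    degree = {g: 0 for g in ids}
    wsum = {g: 0.0 for g in ids}
    for w, a, b in edges:
        degree[a] += 1
        degree[b] += 1
        wsum[a] += w
        wsum[b] += w
    n_hubs = int(np.ceil(top_fraction * idx.size))
    ranked = sorted(ids, key=lambda g: (-degree[g], -wsum[g], g))
    out = pd.DataFrame(
        {
            "gene_id": ranked,
            "degree": [degree[g] for g in ranked],
            "incident_weight": [wsum[g] for g in ranked],
        }
    )
    out["is_hub"] = False
    out.loc[: n_hubs - 1, "is_hub"] = True
    return out


@dataclass
class CoexpressionResult:
    beta: int
    sft_table: pd.DataFrame
    module_labels: pd.Series  # gene -> module id (0 = unassigned)
    eigengenes: pd.DataFrame  # samples x modules
    module_trait: pd.DataFrame
    gs: pd.Series
    mm: pd.DataFrame
    gs_mm_cor: pd.DataFrame
    connectivity: pd.Series  # within-module adjacency sum per gene
    adjacency: np.ndarray = field(repr=False, default=None)
    metadata: dict = field(default_factory=dict)


def run_network(
    expr: pd.DataFrame,
    status,
    config: NetworkConfig | None = None,
) -> CoexpressionResult:
    """Full network stage on a residualised genes x samples matrix."""
    cfg = config or NetworkConfig()
    cfg.validate()
    beta, table = pick_soft_threshold(expr, cfg.powers, cfg.rsq_cut)
    A = signed_adjacency(expr, beta)
    tom = tom_similarity(A)
    labels = detect_modules(1.0 - tom, cfg.min_module_size)
    labels = merge_modules(expr, labels, cfg.merge_cut_height)
    labels = kme_filter(expr, labels, cfg.min_kme, cfg.min_module_size)
    if (set(labels) - {0}):
        ME = module_eigengene(expr, labels)
        trait = module_trait_stats(ME, status)
        gs, mm, gm = gs_mm(expr, labels, ME, status)
    else:
        ME = pd.DataFrame(index=expr.columns)
        trait = pd.DataFrame(columns=["r", "p"])
        gs, mm, gm = pd.Series(dtype=float), pd.DataFrame(index=expr.index), pd.DataFrame()
    kin = np.zeros(len(expr))
    for m in set(labels) - {0}:
        mask = labels == m
        kin[mask] = A[np.ix_(mask, mask)].sum(axis=1)
    return CoexpressionResult(
        beta=beta,
        sft_table=table,
        module_labels=pd.Series(labels, index=expr.index, name="module"),
        eigengenes=ME,
        module_trait=trait,
        gs=gs,
        mm=mm,
        gs_mm_cor=gm,
        connectivity=pd.Series(kin, index=expr.index, name="kWithin"),
        adjacency=A,
        metadata={
            "correlation": "pearson",
            "network_type": cfg.network_type,
            "cut": "height-scan (deterministic)",
            "merge_cut_height": cfg.merge_cut_height,
            "min_module_size": cfg.min_module_size,
            "min_kme": cfg.min_kme,
        },
    )


def export_top_edges(A, labels, module, gene_ids, tsv_path, graphml_path=None,
                     top_edges: int = 500) -> None:
    """Write the module's strongest edges as a (gene_a, gene_b, weight) TSV
    and optionally as GraphML with hub annotations."""
    import networkx as nx

    hubs = hub_genes(A, labels, module, gene_ids=gene_ids, top_edges=top_edges)
    idx = np.flatnonzero(np.asarray(labels, int) == module)
    ids = np.asarray(gene_ids)[idx]
    sub = np.asarray(A, float)[np.ix_(idx, idx)]
    iu, ju = np.triu_indices(idx.size, k=1)
    edges = sorted(
        zip(sub[iu, ju], ids[iu], ids[ju]),
        key=lambda e: (-e[0], min(e[1], e[2]), max(e[1], e[2])),
    )[: int(top_edges)]
    pd.DataFrame([(a, b, w) for w, a, b in edges],
                 columns=["gene_a", "gene_b", "weight"]
                 ).to_csv(tsv_path, sep="\t", index=False)
    if graphml_path is None:
        return
    g = nx.Graph()
    hubset = set(hubs.loc[hubs["is_hub"], "gene_id"])
    for _, row in hubs.iterrows():
        g.add_node(row["gene_id"], degree=int(row["degree"]), is_hub=row["gene_id"] in hubset)
    for w, a, b in edges:
        g.add_edge(a, b, weight=float(w))
    nx.write_graphml(g, graphml_path)
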