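"""Truth-known synthetic cohorts for the case-control brain transcriptomics pipeline.

Real cohorts of this kind (post-mortem brain RNA-seq with a binary disease
status) are access-restricted, so every downstream stage is exercised on
generated data whose structure is known exactly: negative-binomial counts with
gene-wise dispersions, a planted case/control effect on a known gene subset, a
hidden batch factor, latent-factor-driven co-expression modules, optionally
chromosomally clustered differential genes, marker sets concentrated in one
module, and GWAS summary statistics with low p-values planted near one
module's genes.

The count model is

    K_gj ~ NB(mu_gj, alpha_g),   Var = mu + alpha * mu^2
    log mu_gj = baseline_g + status_j * lfc_g + batch_j * b_g
                + sum_m lambda_gm * f_mj + log L_j

with module factors f_mj ~ N(0, 1) i.i.d. across samples and loadings
lambda_gm nonzero only for genes of module m.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "CohortConfig",
    "SyntheticTruth",
    "generate_cohort",
    "generate_annotation",
    "generate_gwas",
    "generate_markers",
    "write_counts_tsv",
    "write_counts_mtx",
    "write_covariates_tsv",
    "write_annotation_bed",
    "write_gwas_tsv",
    "write_gmt",
    "read_gmt",
]


@dataclass
class CohortConfig:
    """Parameters of a synthetic case-control expression cohort.

    Defaults describe a desk-scale cohort with the structural features the
    pipeline's stages assume: five strong co-expression modules of 100 genes,
    a planted disease effect of |log2FC| = 1 on 10% of genes (concentrated in
    the first module so the module is trait-associated), a two-level hidden
    batch, and mild case/control covariate imbalance for the matching stage
    to correct.
    """

    n_genes: int = 2000
    n_cases: int = 30
    n_controls: int = 60
    n_modules: int = 5
    module_size: int = 100
    de_fraction: float = 0.10
    lfc: float = 1.0
    dispersion: float = 0.2
    batch_effect: float = 0.0
    batch_gene_fraction: float = 0.3
    module_factor_sd: float = 1.0
    covariate_imbalance: float = 1.0  # case shift in units of the covariate SD
    de_in_target_module: bool = True
    seed: int = 0

    def validate(self) -> None:
        if min(self.n_genes, self.n_cases, self.n_controls) <= 0:
            raise ValueError("n_genes, n_cases, n_controls must be positive")
        if self.n_modules < 0 or self.module_size < 0:
            raise ValueError("n_modules and module_size must be non-negative")
        if self.n_modules * self.module_size > self.n_genes:
            raise ValueError(
                f"module genes ({self.n_modules}x{self.module_size}) exceed n_genes={self.n_genes}"
            )
        if not 0.0 <= self.de_fraction <= 1.0:
            raise ValueError("de_fraction must lie in [0, 1]")
        if self.dispersion <= 0:
            raise ValueError("dispersion must be > 0")


@dataclass
class SyntheticTruth:
    """Ground truth planted by :func:`generate_cohort`."""

    de_genes: set[str]
    module_assignment: dict[str, int]  # 0 = background
    batch: np.ndarray  # per-sample hidden factor level (int)
    signal_genes: set[str]  # genes with planted GWAS signal
    marker_sets: dict[str, set[str]] = field(default_factory=dict)
    effect_sizes: dict[str, float] = field(default_factory=dict)  # true log2FC

    def module_genes(self, module: int) -> set[str]:
        return {g for g, m in self.module_assignment.items() if m == module}

    def to_json(self, path: str | Path) -> None:
        payload = {
            "de_genes": sorted(self.de_genes),
            "module_assignment": self.module_assignment,
            "batch": np.asarray(self.batch).tolist(),
            "signal_genes": sorted(self.signal_genes),
            "marker_sets": {k: sorted(v) for k, v in self.marker_sets.items()},
            "effect_sizes": self.effect_sizes,
        }
        Path(path).write_text(json.dumps(payload, indent=1))


def _nb_sample(rng: np.random.Generator, mu: np.ndarray, alpha: np.ndarray) -> np.ndarray:
    """Gamma-Poisson draw of NB counts with Var = mu + alpha mu^2; alpha ~ 0 -> Poisson."""
    alpha = np.broadcast_to(np.asarray(alpha, float)[:, None], mu.shape)
    out = np.empty(mu.shape, dtype=np.int64)
    poi = alpha < 1e-10
    if poi.any():
        out[poi] = rng.poisson(mu[poi])
    nb = ~poi
    if nb.any():
        shape = 1.0 / alpha[nb]
        lam = rng.gamma(shape, mu[nb] / shape)
        out[nb] = rng.poisson(lam)
    return out


def generate_cohort(config: CohortConfig) -> tuple[pd.DataFrame, pd.DataFrame, SyntheticTruth]:
    """Generate (counts, samples, truth) for one synthetic cohort.

    Returns
    -------
    counts : DataFrame, genes x samples, non-negative integers
    samples : DataFrame indexed by sample_id with columns
        age, sex, race, bmi, rin, status (0/1), region
    truth : SyntheticTruth
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    G, n = config.n_genes, config.n_cases + config.n_controls

    genes = np.array([f"G{i:05d}" for i in range(G)])
    sample_ids = np.array([f"S{j:04d}" for j in range(n)])
    status = np.concatenate([np.ones(config.n_cases), np.zeros(config.n_controls)])

    # module memberships: contiguous blocks at the front of the gene list
    module = np.zeros(G, dtype=int)
    for m in range(config.n_modules):
        module[m * config.module_size:(m + 1) * config.module_size] = m + 1

    # planted DE genes and true log2 fold changes
    n_de = int(round(config.de_fraction * G))
    lfc_true = np.zeros(G)
    if n_de > 0 and config.lfc != 0.0:
        if config.de_in_target_module and config.n_modules >= 1:
            target = np.flatnonzero(module == 1)
            head = target[: min(n_de, target.size)]
            rest_pool = np.flatnonzero(module != 1)
            rest = rng.choice(rest_pool, size=n_de - head.size, replace=False)
            de_idx = np.concatenate([head, rest])
            # coherent sign inside the target module keeps it trait-associated
            lfc_true[head] = config.lfc
            lfc_true[rest] = rng.choice([-1.0, 1.0], size=rest.size) * config.lfc
        else:
            de_idx = rng.choice(G, size=n_de, replace=False)
            lfc_true[de_idx] = rng.choice([-1.0, 1.0], size=n_de) * config.lfc
    else:
        de_idx = np.array([], dtype=int)

    # hidden two-level batch on a gene subset
    batch = rng.integers(0, 2, size=n)
    b_g = np.zeros(G)
    if config.batch_effect != 0.0:
        n_batch_genes = int(round(config.batch_gene_fraction * G))
        idx = rng.choice(G, size=n_batch_genes, replace=False)
        b_g[idx] = rng.choice([-1.0, 1.0], size=n_batch_genes) * config.batch_effect

    # latent module factors
    factors = rng.normal(size=(config.n_modules, n))
    loadings = np.zeros((G, config.n_modules))
    for m in range(config.n_modules):
        members = module == m + 1
        loadings[members, m] = config.module_factor_sd * rng.uniform(0.8, 1.2, members.sum())

    baseline = rng.normal(np.log(200.0), 1.0, size=G)
    log_lib = rng.normal(0.0, 0.15, size=n)

    ln2 = np.log(2.0)
    log_mu = (
        baseline[:, None]
        + lfc_true[:, None] * ln2 * status[None, :]
        + b_g[:, None] * batch[None, :]
        + loadings @ factors
        + log_lib[None, :]
    )
    alpha = np.exp(rng.normal(np.log(config.dispersion), 0.3, size=G))
    counts = _nb_sample(rng, np.exp(log_mu), alpha)
    counts_df = pd.DataFrame(counts, index=genes, columns=sample_ids)

    # covariates with configurable case/control imbalance (pre-matching)
    shift = config.covariate_imbalance
    age = rng.normal(55.0, 10.0, size=n) + shift * 10.0 * status
    bmi = rng.normal(27.0, 4.0, size=n) + shift * 2.0 * status
    rin = np.clip(rng.normal(7.5, 0.7, size=n) - 0.2 * shift * status, 6.05, 10.0)
    p_male = np.where(status == 1, 0.5 + 0.1 * min(shift, 1.0), 0.5)
    sex = np.where(rng.random(n) < p_male, "male", "female")
    p_white = np.where(status == 1, 0.8 - 0.1 * min(shift, 1.0), 0.8)
    race = np.where(rng.random(n) < p_white, "white", "black")
    samples = pd.DataFrame(
        {
            "sample_id": sample_ids,
            "age": age,
            "sex": sex,
            "race": race,
            "bmi": bmi,
            "rin": rin,
            "status": status.astype(int),
            "region": "caudate",
        }
    ).set_index("sample_id", drop=False)

    truth = SyntheticTruth(
        de_genes=set(genes[de_idx]),
        module_assignment={g: int(m) for g, m in zip(genes, module)},
        batch=batch,
        signal_genes=set(genes[module == 1]) if config.n_modules >= 1 else set(),
        effect_sizes={g: float(l) for g, l in zip(genes, lfc_true) if l != 0.0},
    )
    return counts_df, samples, truth


# ---------------------------------------------------------------------------
# gene annotation


def generate_annotation(
    n_genes: int,
    n_chromosomes: int = 10,
    cluster_de: bool = False,
    truth: SyntheticTruth | None = None,
    seed: int = 0,
    mean_gene_length: int = 20_000,
    mean_spacing: int = 200_000,
) -> pd.DataFrame:
    """Non-overlapping gene intervals with strand and biotype.

    With ``cluster_de`` the truth's DE genes are packed into tight chromosomal
    clusters (spacing ~1% of the background spacing) so that intra-set genomic
    distances are small; otherwise placement is uniform per chromosome.

    Returns a DataFrame with columns
    gene_id, chromosome, start, end, strand, biotype (0-based half-open).
    """
    if n_chromosomes < 1:
        raise ValueError("n_chromosomes must be >= 1")
    rng = np.random.default_rng(seed)
    genes = [f"G{i:05d}" for i in range(n_genes)]
    de = sorted(truth.de_genes) if (cluster_de and truth is not None) else []
    de_set = set(de)
    background = [g for g in genes if g not in de_set]

    chroms = [f"chr{c + 1}" for c in range(n_chromosomes)]
    rows: list[tuple[str, str, int, int, str, str]] = []
    biotypes = np.array(["protein_coding", "lincRNA", "antisense", "pseudogene"])
    bio_p = np.array([0.80, 0.08, 0.07, 0.05])

    # distribute background genes round-robin, uniform spacing with jitter
    per_chrom: dict[str, list[str]] = {c: [] for c in chroms}
    for i, g in enumerate(background):
        per_chrom[chroms[i % n_chromosomes]].append(g)
    cursor = {c: 1_000 for c in chroms}
    for c in chroms:
        for g in per_chrom[c]:
            gap = int(rng.exponential(mean_spacing)) + 1_000
            length = int(rng.exponential(mean_gene_length)) + 1_000
            start = cursor[c] + gap
            rows.append((g, c, start, start + length, "+" if rng.random() < 0.5 else "-",
                         str(rng.choice(biotypes, p=bio_p))))
            cursor[c] = start + length

    # DE genes: tight clusters appended past the background genes
    if de:
        cluster_chroms = rng.permutation(chroms)
        n_clusters = min(len(de), n_chromosomes)
        splits = np.array_split(np.array(de), n_clusters)
        for c, members in zip(cluster_chroms, splits):
            for g in members:
                gap = int(rng.exponential(mean_spacing * 0.01)) + 100
                length = int(rng.exponential(mean_gene_length)) + 1_000
                start = cursor[c] + gap
                rows.append((g, c, start, start + length,
                             "+" if rng.random() < 0.5 else "-",
                             str(rng.choice(biotypes, p=bio_p))))
                cursor[c] = start + length

    ann = pd.DataFrame(rows, columns=["gene_id", "chromosome", "start", "end", "strand", "biotype"])
    return ann.set_index("gene_id", drop=False).loc[genes].reset_index(drop=True)


# ---------------------------------------------------------------------------
# GWAS summary statistics


def generate_gwas(
    annotation: pd.DataFrame,
    truth: SyntheticTruth | None,
    n_snps: int = 20_000,
    signal_strength: float = 0.0,
    seed: int = 0,
    upstream: int = 20_000,
    downstream: int = 10_000,
) -> pd.DataFrame:
    """SNP table (SNP, CHR, POS, P) with optional planted signal.

    Positions are uniform over each chromosome's annotated span. P-values are
    Uniform(0,1) except for SNPs falling inside the signal genes' assignment
    windows (the same 20kb 5' / 10kb 3' strand-aware windows used downstream),
    which draw from Beta(a, 1) with a = 1/(1 + signal_strength); a
    signal-free null is obtained with ``signal_strength=0``.
    """
    if n_snps < 1:
        raise ValueError("n_snps must be >= 1")
    rng = np.random.default_rng(seed)
    spans = annotation.groupby("chromosome")["end"].max()
    chroms = spans.index.to_numpy()
    weights = spans.to_numpy(float)
    weights = weights / weights.sum()
    snp_chrom = rng.choice(chroms, size=n_snps, p=weights)
    snp_pos = np.empty(n_snps, dtype=np.int64)
    for c in chroms:
        m = snp_chrom == c
        snp_pos[m] = rng.integers(1, int(spans[c]) + 1, size=m.sum())
    p = rng.uniform(size=n_snps)

    if truth is not None and signal_strength > 0 and truth.signal_genes:
        sig = annotation[annotation["gene_id"].isin(truth.signal_genes)]
        plus = sig["strand"].to_numpy() == "+"
        lo = np.where(plus, sig["start"].to_numpy() - upstream, sig["start"].to_numpy() - downstream)
        hi = np.where(plus, sig["end"].to_numpy() + downstream, sig["end"].to_numpy() + upstream)
        in_window = np.zeros(n_snps, dtype=bool)
        for c in np.unique(sig["chromosome"]):
            gm = sig["chromosome"].to_numpy() == c
            sm = snp_chrom == c
            if not sm.any():
                continue
            pos = snp_pos[sm]
            hit = ((pos[:, None] >= lo[gm][None, :]) & (pos[:, None] <= hi[gm][None, :])).any(axis=1)
            idx = np.flatnonzero(sm)
            in_window[idx[hit]] = True
        a = 1.0 / (1.0 + signal_strength)
        p[in_window] = rng.beta(a, 1.0, size=in_window.sum())

    return pd.DataFrame(
        {
            "SNP": [f"rs{i}" for i in range(n_snps)],
            "CHR": snp_chrom,
            "POS": snp_pos,
            "P": np.clip(p, 1e-300, 1.0),
        }
    )


# ---------------------------------------------------------------------------
# marker sets


def generate_markers(
    truth: SyntheticTruth,
    target_module: int = 1,
    n_sets: int = 5,
    overlap_fraction: float = 0.5,
    set_size: int = 40,
    seed: int = 0,
) -> dict[str, set[str]]:
    """Marker gene sets, one of which overlaps the target module.

    The planted set shares exactly ``round(overlap_fraction * set_size)``
    genes with the target module; the remaining sets are uniform draws from
    the background (non-target) genes.
    """
    if not 0.0 <= overlap_fraction <= 1.0:
        raise ValueError("overlap_fraction must lie in [0, 1]")
    target_genes = sorted(truth.module_genes(target_module))
    if not target_genes:
        raise ValueError(f"target module {target_module} not present in truth")
    rng = np.random.default_rng(seed)
    universe = sorted(truth.module_assignment)
    background = [g for g in universe if truth.module_assignment[g] != target_module]

    n_overlap = int(round(overlap_fraction * set_size))
    n_overlap = min(n_overlap, len(target_genes))
    planted = set(rng.choice(target_genes, size=n_overlap, replace=False)) | set(
        rng.choice(background, size=set_size - n_overlap, replace=False)
    )
    sets = {"planted_markers": planted}
    for k in range(1, n_sets):
        sets[f"random_markers_{k}"] = set(rng.choice(background, size=set_size, replace=False))
    truth.marker_sets = sets
    return sets


# ---------------------------------------------------------------------------
# writers / readers for the standard text formats


def write_counts_tsv(counts: pd.DataFrame, path: str | Path) -> None:
    counts.to_csv(path, sep="\t", index_label="gene_id")


def write_counts_mtx(counts: pd.DataFrame, prefix: str | Path) -> None:
    """MatrixMarket .mtx plus .rows / .cols index files."""
    from scipy import io as spio
    from scipy import sparse

    prefix = Path(prefix)
    spio.mmwrite(str(prefix.with_suffix(".mtx")), sparse.csr_matrix(counts.to_numpy()))
    prefix.with_suffix(".rows").write_text("\n".join(counts.index) + "\n")
    prefix.with_suffix(".cols").write_text("\n".join(counts.columns) + "\n")


def write_covariates_tsv(samples: pd.DataFrame, path: str | Path) -> None:
    samples.to_csv(path, sep="\t", index=False)


def write_annotation_bed(annotation: pd.DataFrame, path: str | Path) -> None:
    """BED6+1: chrom, start, end, gene_id, score, strand, biotype (0-based half-open)."""
    bed = annotation[["chromosome", "start", "end", "gene_id"]].copy()
    bed["score"] = 0
    bed["strand"] = annotation["strand"]
    bed["biotype"] = annotation["biotype"]
    bed.to_csv(path, sep="\t", header=False, index=False)


def read_annotation_bed(path: str | Path) -> pd.DataFrame:
    ann = pd.read_csv(
        path, sep="\t", header=None,
        names=["chromosome", "start", "end", "gene_id", "score", "strand", "biotype"],
    )
    return ann[["gene_id", "chromosome", "start", "end", "strand", "biotype"]]


def read_annotation_gff3(path: str | Path) -> pd.DataFrame:
    """Minimal GFF3 reader: gene lines only; gene_id and biotype from the
    attribute column (ID=/gene_id= and biotype=/gene_biotype=, else 'unknown').
    Coordinates convert from 1-based closed to 0-based half-open."""
    rows = []
    for line in Path(path).read_text().splitlines():
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) < 9 or parts[2] != "gene":
            continue
        attrs = dict(kv.split("=", 1) for kv in parts[8].rstrip(";").split(";") if "=" in kv)
        gene_id = attrs.get("ID") or attrs.get("gene_id")
        if gene_id is None:
            continue
        rows.append((gene_id, parts[0], int(parts[3]) - 1, int(parts[4]),
                     parts[6] if parts[6] in "+-" else "+",
                     attrs.get("biotype", attrs.get("gene_biotype", "unknown"))))
    return pd.DataFrame(rows, columns=["gene_id", "chromosome", "start", "end",
                                       "strand", "biotype"])


def write_gwas_tsv(gwas: pd.DataFrame, path: str | Path) -> None:
    gwas.to_csv(path, sep="\t", index=False)


def write_gmt(sets: dict[str, set[str]], path: str | Path, description: str = "synthetic") -> None:
    with open(path, "w") as fh:
        for name, members in sets.items():
            fh.write("\t".join([name, description, *sorted(members)]) + "\n")


def read_gmt(path: str | Path) -> dict[str, set[str]]:
    sets: dict[str, set[str]] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        name, _desc, *members = line.rstrip("\n").split("\t")
        sets[name] = set(members)
    return sets
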