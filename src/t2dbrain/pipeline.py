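"""End-to-end orchestration: match -> SVA -> DE -> distances -> network ->
marker enrichment -> GWAS enrichment, with a run manifest and deterministic
per-stage seeds derived from one master seed."""

from __future__ import annotations

import hashlib
import json
import logging
import zlib
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import de as de_mod
from . import genomic, gwas as gwas_mod, markers as markers_mod, matching, network, sva, synthetic

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_pipeline", "demo", "compare_regions", "stage_seed"]


@dataclass
class RunConfig:
    """Paths and stage parameters; defaults follow the study protocol
    (2:1 matching, 3 surrogate variables, FDR 0.05, signed network with
    minModSize 40 / mergeCutHeight 0.15 / minKME 0.7, pSI thresholds
    0.01/0.001/0.0001, 20kb/10kb SNP windows, 20,000 permutations, hubs =
    top 5% of connections among the top 500 edges)."""

    counts: str = ""
    covariates: str = ""
    annotation: str = ""
    gwas: str = ""
    control_gwas: str = ""
    markers_gmt: str = ""
    out_dir: str = "run"
    region: str = "caudate"

    min_rin: float = 6.0
    ratio: int = 2
    n_sv: int = 3
    fdr: float = 0.05
    min_module_size: int = 40
    merge_cut_height: float = 0.15
    min_kme: float = 0.7
    rsq_cut: float = 0.85
    upstream: int = 20_000
    downstream: int = 10_000
    n_perm: int = 20_000
    hub_top_fraction: float = 0.05
    hub_top_edges: int = 500
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        import yaml

        data = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)


def stage_seed(master: int, stage: str) -> int:
    """Deterministic per-stage seed below 2^31."""
    return (int(master) * 1_000_003 + zlib.crc32(stage.encode())) % (2**31 - 1)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages in order; returns the manifest dict.

    Stage artifacts are written under ``config.out_dir``; any stage failure
    raises with the stage name attached.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for key in ("counts", "covariates", "annotation", "gwas"):
        p = getattr(config, key)
        if not p or not Path(p).exists():
            raise FileNotFoundError(f"input '{key}' not found: {p!r}")

    manifest: dict = {
        "config": asdict(config),
        "inputs": {k: _sha256(Path(getattr(config, k)))
                   for k in ("counts", "covariates", "annotation", "gwas",
                             "control_gwas", "markers_gmt")
                   if getattr(config, k) and Path(getattr(config, k)).exists()},
        "stage_seeds": {},
        "stages": {},
    }

    stage = "load"
    try:
        counts = pd.read_csv(config.counts, sep="\t", index_col=0)
        samples = pd.read_csv(config.covariates, sep="\t").set_index("sample_id", drop=False)
        annotation = synthetic.read_annotation_bed(config.annotation)
        gw = gwas_mod.read_gwas(config.gwas)
        control_gw = gwas_mod.read_gwas(config.control_gwas) if config.control_gwas else None
        marker_sets = synthetic.read_gmt(config.markers_gmt) if config.markers_gmt else {}

        stage = "match"
        cohort = matching.match_cohort(samples, ratio=config.ratio, min_rin=config.min_rin)
        filtered = matching.filter_samples(samples, min_rin=config.min_rin)
        bal = matching.balance_table(cohort, filtered)
        (out / "cohort.json").write_text(json.dumps(cohort.to_dict(), indent=1))
        bal.to_csv(out / "balance.tsv", sep="\t", index=False)
        manifest["stages"]["match"] = {
            "n_cases": len(cohort.case_ids), "n_controls": len(cohort.control_ids),
            "metric": cohort.distance_metric, "total_distance": cohort.total_distance,
        }

        ids = cohort.all_ids()
        counts_m = counts[ids]
        samples_m = samples.loc[ids]
        status = samples_m["status"].to_numpy(int)
        covariates = samples_m[["age", "bmi", "rin", "sex", "race"]]

        stage = "sva"
        s = de_mod.size_factors(counts_m)
        svs = sva.fit_surrogate_variables(counts_m, s, covariates, status, n_sv=config.n_sv)
        pd.DataFrame(svs, index=ids,
                     columns=[f"SV{i+1}" for i in range(svs.shape[1])]
                     ).to_csv(out / "surrogate_variables.tsv", sep="\t")
        manifest["stages"]["sva"] = {"n_sv": int(svs.shape[1])}

        stage = "de"
        design = np.column_stack([sva.build_design(covariates), svs, status.astype(float)])
        disp = de_mod.estimate_dispersions(counts_m, s, design)
        res = de_mod.nb_wald_test(counts_m, s, disp, design)
        res = de_mod.independent_filter(res, alpha=config.fdr)
        res.to_csv(out / "de.tsv", sep="\t", index_label="gene_id")
        dags = res.index[(res["padj"] < config.fdr)].tolist()
        detectable = res.index[res["padj"].notna()].tolist()
        rlog = de_mod.rlog_transform(counts_m, s)
        cluster_p = float("nan")
        if len(dags) >= 2:
            _, cluster_p = de_mod.cluster_status_test(rlog.loc[dags], status)
        manifest["stages"]["de"] = {
            "n_dags_fdr05": len(dags),
            "n_dags_fdr10": int((res["padj"] < 0.10).sum()),
            "n_dags_fdr01": int((res["padj"] < 0.01).sum()),
            "n_detectable": len(detectable),
            "filter_theta": res.attrs.get("filter_theta"),
            "cluster_fisher_p": cluster_p,
        }

        stage = "distances"
        if dags:
            comp = genomic.biotype_composition(dags, annotation)
            comp.to_csv(out / "dag_biotypes.tsv", sep="\t", header=["proportion"])
            chrom = genomic.chromosome_composition(dags, annotation)
            chrom.to_csv(out / "dag_chromosomes.tsv", sep="\t", header=["proportion"])
            manifest["stages"]["distances"] = {"n_dags_annotated": len(dags)}

        stage = "network"
        expr = rlog.loc[detectable] if detectable else rlog
        resid = network.residualize(expr, np.column_stack([sva.build_design(covariates), svs]))
        cfg = network.NetworkConfig(
            rsq_cut=config.rsq_cut, merge_cut_height=config.merge_cut_height,
            min_module_size=config.min_module_size, min_kme=config.min_kme,
        )
        net = network.run_network(resid, status, cfg)
        net.module_labels.to_csv(out / "modules.tsv", sep="\t", header=["module"])
        net.eigengenes.to_csv(out / "eigengenes.tsv", sep="\t")
        net.module_trait.to_csv(out / "module_trait.tsv", sep="\t")
        manifest["stages"]["network"] = {
            "beta": net.beta,
            "n_modules": int(net.module_labels.max()),
            "module_sizes": net.module_labels[net.module_labels > 0]
                              .value_counts().sort_index().tolist(),
        }

        stage = "hub_genes"
        modules_present = sorted(set(net.module_labels) - {0})
        hub_tables = {}
        gene_ids = net.module_labels.index.to_numpy()
        for m in modules_present:
            hubs = network.hub_genes(
                net.adjacency, net.module_labels.to_numpy(), m, gene_ids=gene_ids,
                top_edges=config.hub_top_edges, top_fraction=config.hub_top_fraction,
            )
            hub_tables[m] = hubs
            hubs.to_csv(out / f"hubs_module{m}.tsv", sep="\t", index=False)
            network.export_top_edges(
                net.adjacency, net.module_labels.to_numpy(), m, gene_ids,
                out / f"edges_module{m}.tsv", out / f"edges_module{m}.graphml",
                top_edges=config.hub_top_edges)
        manifest["stages"]["hub_genes"] = {
            str(m): hub_tables[m].loc[hub_tables[m]["is_hub"], "gene_id"].tolist()
            for m in modules_present
        }

        stage = "marker_enrichment"
        marker_result = None
        if marker_sets and modules_present:
            module_sets = {
                f"module_{m}": set(gene_ids[net.module_labels.to_numpy() == m])
                for m in modules_present
            }
            universe = set(gene_ids)
            marker_result = markers_mod.fisher_enrichment(module_sets, marker_sets, universe)
            marker_result.to_csv(out / "marker_enrichment.tsv", sep="\t", index=False)
            best = marker_result.loc[marker_result["p_bonferroni"].idxmin()]
            manifest["stages"]["marker_enrichment"] = {
                "n_cells": len(marker_result),
                "best_cell": [best["module"], best["marker_set"],
                              float(best["p_bonferroni"])],
            }
        else:
            pd.DataFrame().to_csv(out / "marker_enrichment.tsv", sep="\t", index=False)
            manifest["stages"]["marker_enrichment"] = {"n_cells": 0}

        stage = "gwas_enrichment"
        seed_g = stage_seed(config.seed, "gwas_enrichment")
        manifest["stage_seeds"]["gwas_enrichment"] = seed_g
        assignment = gwas_mod.assign_snps_to_genes(
            gw, annotation, upstream=config.upstream, downstream=config.downstream)
        ranking = gwas_mod.gene_scores(assignment, gw)
        ctrl_ranking = None
        if control_gw is not None:
            ctrl_assignment = gwas_mod.assign_snps_to_genes(
                control_gw, annotation, upstream=config.upstream, downstream=config.downstream)
            ctrl_ranking = gwas_mod.gene_scores(ctrl_assignment, control_gw)
        module_sets = {
            f"module_{m}": set(gene_ids[net.module_labels.to_numpy() == m])
            for m in modules_present
        }
        # marker-restricted sub-modules of the trait-associated modules
        if marker_sets:
            trait_mods = [m for m in modules_present
                          if net.module_trait.loc[f"ME{m}", "p"] < 0.05]
            for m in trait_mods:
                mod_genes = set(gene_ids[net.module_labels.to_numpy() == m])
                for sname, sgenes in marker_sets.items():
                    sub = mod_genes & set(sgenes)
                    if len(sub) >= 10:
                        module_sets[f"module_{m}|{sname}"] = sub
        enr = gwas_mod.score_and_test_sets(
            ranking, module_sets, n_perm=config.n_perm, seed=seed_g,
            control_ranking=ctrl_ranking,
        )
        enr.table.to_csv(out / "gwas_enrichment.tsv", sep="\t", index=False)
        manifest["stages"]["gwas_enrichment"] = {
            "n_sets": len(enr.table),
            "significant": enr.table.loc[enr.table["significant"], "set"].tolist()
            if not enr.table.empty else [],
        }
    except Exception as exc:
        raise RuntimeError(f"pipeline failed at stage '{stage}': {exc}") from exc

    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, default=str))
    return manifest


def demo(seed: int = 7, out_dir: str | Path = "demo", n_perm: int = 5_000) -> dict:
    """Generate a synthetic cohort with every planted structure and run the
    full pipeline on it. Returns the manifest augmented with the truth."""
    out = Path(out_dir)
    data = out / "data"
    data.mkdir(parents=True, exist_ok=True)
    cfg = synthetic.CohortConfig(
        n_cases=30, n_controls=90, batch_effect=0.5, seed=stage_seed(seed, "cohort"))
    counts, samples, truth = synthetic.generate_cohort(cfg)
    ann = synthetic.generate_annotation(
        cfg.n_genes, n_chromosomes=10, cluster_de=True, truth=truth,
        seed=stage_seed(seed, "annotation"))
    gw = synthetic.generate_gwas(ann, truth, n_snps=20_000, signal_strength=9.0,
                                 seed=stage_seed(seed, "gwas"))
    ctrl = synthetic.generate_gwas(ann, truth, n_snps=20_000, signal_strength=0.0,
                                   seed=stage_seed(seed, "control_gwas"))
    marker_sets = synthetic.generate_markers(truth, target_module=1, n_sets=5,
                                             overlap_fraction=0.5, set_size=60,
                                             seed=stage_seed(seed, "markers"))
    synthetic.write_counts_tsv(counts, data / "counts.tsv")
    synthetic.write_covariates_tsv(samples, data / "covariates.tsv")
    synthetic.write_annotation_bed(ann, data / "annotation.bed")
    synthetic.write_gwas_tsv(gw, data / "gwas_t2d.tsv")
    synthetic.write_gwas_tsv(ctrl, data / "gwas_control.tsv")
    synthetic.write_gmt(marker_sets, data / "markers.gmt")
    truth.to_json(data / "truth.json")

    run_cfg = RunConfig(
        counts=str(data / "counts.tsv"),
        covariates=str(data / "covariates.tsv"),
        annotation=str(data / "annotation.bed"),
        gwas=str(data / "gwas_t2d.tsv"),
        control_gwas=str(data / "gwas_control.tsv"),
        markers_gmt=str(data / "markers.gmt"),
        out_dir=str(out / "results"),
        n_perm=n_perm,
        seed=seed,
    )
    manifest = run_pipeline(run_cfg)
    manifest["truth_path"] = str(data / "truth.json")
    (out / "results" / "manifest.json").write_text(json.dumps(manifest, indent=1, default=str))
    return manifest


def compare_regions(de_tables: dict[str, pd.DataFrame], fdr: float = 0.05) -> pd.DataFrame:
    """Post-hoc join of per-region DE tables: per-gene hit count, region list
    and direction concordance across regions ('multi-hit' genes)."""
    rows = {}
    for region, tab in de_tables.items():
        hits = tab[tab["padj"] < fdr]
        for g, r in hits.iterrows():
            rows.setdefault(g, []).append((region, r["direction"]))
    out = []
    for g, hits in rows.items():
        regions = [h[0] for h in hits]
        dirs = {h[1] for h in hits}
        out.append((g, len(regions), ",".join(sorted(regions)), len(dirs) == 1))
    return pd.DataFrame(out, columns=["gene_id", "n_regions", "regions", "direction_concordant"]
                        ).sort_values(["n_regions", "gene_id"], ascending=[False, True]
                        ).reset_index(drop=True)
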