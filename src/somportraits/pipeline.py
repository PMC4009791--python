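"""End-to-end orchestration: preprocess → SOM → spots → enrichment →
similarity → subtyping → characterization, with outlier correction.

A single :class:`PipelineConfig` (one global seed fanning out to stage
seeds) drives every stage; :func:`run_pipeline` writes all module outputs
plus a machine-readable run manifest into one output directory. The outlier
loop mirrors interactive practice: spots whose top-enriched gene set falls
into a user-flagged contamination category are removed gene-wise and the SOM
is retrained on the cleaned matrix.
"""

from __future__ import annotations

import json
import logging
import platform
import time
import zlib
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import __version__
from .datatypes import ExpressionMatrix, GeneSetCollection, SurvivalTable
from .enrichment import EnrichmentConfig, gsz_profile, spot_enrichment
from .io import (
    read_expression_tsv,
    read_gmt,
    read_survival_tsv,
    write_edge_list,
    write_expression_tsv,
    write_newick,
)
from .preprocess import preprocess
from .similarity import (
    correlation_network,
    ica_embed,
    nj_tree,
    pairwise_correlation,
    sample_distance_matrix,
)
from .som import SOMConfig, SOMModel, train_som
from .spots import (
    OVER,
    UNDER,
    SpotSet,
    detect_spots,
    spot_correlation,
    spot_profiles,
    write_spots_json,
)
from .subtyping import (
    bootstrap_stability,
    consensus_cluster,
    kmeans_assign,
    prototype_from_spot,
)
from .survival import characteristic_table, logrank_test, survival_by_group
from .synthetic import SyntheticConfig, generate_cohort, generate_gene_sets, \
    generate_survival

log = logging.getLogger("somportraits")

STAGES = ("preprocess", "train", "spots", "enrichment", "correction",
          "similarity", "subtyping", "characterization")


def stage_seed(global_seed: int, stage: str) -> int:
    """Derive a stable per-stage seed from the global seed (< 2^31)."""
    return (int(global_seed) * 1000003 + zlib.crc32(stage.encode())) % (2 ** 31)


@dataclass
class PipelineConfig:
    """Everything one run needs; all stage settings in one place."""

    expression_path: str | None = None       # raw genes × samples TSV
    gene_sets_path: str | None = None        # GMT
    phenotype_path: str | None = None        # sample_id + categorical columns
    survival_path: str | None = None         # sample_id, time, event[, group]
    synthetic: SyntheticConfig | None = None  # used when expression_path is None

    som: SOMConfig = field(default_factory=SOMConfig)
    spot_percentile: float = 98.0
    alpha: float = 0.05
    flagged_categories: tuple[str, ...] = ("contamination",)
    r_threshold: float = 0.5
    n_subtypes: int = 4
    bootstrap_fraction: float = 0.8
    bootstrap_reps: int = 500
    consensus_k_range: tuple[int, ...] = (2, 3, 4, 5, 6)
    consensus_reps: int = 500
    render_portraits: bool = False
    outdir: str = "somportraits_run"
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        import yaml

        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        som = SOMConfig(**raw.pop("som", {}))
        synth = raw.pop("synthetic", None)
        synthetic = SyntheticConfig(**synth) if synth is not None else None
        for key in ("flagged_categories", "consensus_k_range"):
            if key in raw and raw[key] is not None:
                raw[key] = tuple(raw[key])
        return cls(som=som, synthetic=synthetic, **raw)


# ---------------------------------------------------------------------------
# outlier detection / correction
# ---------------------------------------------------------------------------

def detect_outlier_spots(spotset: SpotSet,
                         enrichment: Mapping[str, pd.DataFrame],
                         flagged_categories: Sequence[str],
                         p_threshold: float) -> list[str]:
    """Spots whose top-enriched gene set is significant and flagged.

    ``enrichment`` maps spot label → overrepresentation table (sorted by p).
    A spot is an outlier candidate when its single most-enriched set passes
    the significance threshold *and* belongs to one of the flagged categories
    (tissue signatures, drug metabolism, …).
    """
    flagged = set(flagged_categories)
    if not flagged:
        return []
    out = []
    for label, table in enrichment.items():
        if table.empty:
            continue
        top = table.iloc[0]
        if top["p"] < p_threshold and top["category"] in flagged:
            out.append(label)
    return out


def correct_and_retrain(raw_matrix: ExpressionMatrix, model: SOMModel,
                        outlier_spots: Sequence, som_config: SOMConfig,
                        ) -> tuple[ExpressionMatrix, SOMModel | None, list[str]]:
    """Drop the outlier spots' genes and retrain the SOM on the cleaned data.

    Returns the reduced raw matrix, the freshly trained model (None when no
    genes were removed — retraining is skipped), and the removed gene ids.
    Raises when the removal would leave fewer genes than metagenes.
    """
    removed: list[str] = []
    seen = set()
    for spot in outlier_spots:
        for g in spot.genes:
            if g not in seen:
                seen.add(g)
                removed.append(g)
    if not removed:
        return raw_matrix, None, []
    remaining = raw_matrix.n_genes - len(removed)
    K = som_config.rows * som_config.cols
    if remaining < K:
        raise ValueError(
            f"removing {len(removed)} genes leaves {remaining} < {K} metagenes"
        )
    reduced = raw_matrix.drop_genes(removed)
    new_model = train_som(preprocess(reduced), som_config)
    return reduced, new_model, removed


# ---------------------------------------------------------------------------
# the pipeline
# ---------------------------------------------------------------------------

def _rank_spots_by_size(spotset: SpotSet) -> list[str]:
    return [s.label for s in sorted(spotset, key=lambda s: (-len(s.genes), s.label))]


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all stages and write the report bundle; returns the manifest."""
    t_start = time.time()
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "package": "somportraits",
        "version": __version__,
        "python": platform.python_version(),
        "seed": config.seed,
        "stages": [],
        "parameters": {
            "som": asdict(config.som),
            "spot_percentile": config.spot_percentile,
            "alpha": config.alpha,
            "r_threshold": config.r_threshold,
            "n_subtypes": config.n_subtypes,
        },
    }

    def stage_done(name: str, **info):
        log.info("[%s] done (%.1fs elapsed) %s", name, time.time() - t_start, info)
        manifest["stages"].append({"name": name, **info})

    try:
        # ---- input / simulation ------------------------------------------
        truth = None
        survival = None
        if config.expression_path is not None:
            raw = read_expression_tsv(config.expression_path)
        else:
            synth = config.synthetic or SyntheticConfig(seed=stage_seed(config.seed, "simulate"))
            raw, truth = generate_cohort(synth)
            write_expression_tsv(raw, out / "expression_raw.tsv")
            truth.sample_labels.to_csv(out / "truth_labels.tsv", sep="\t")
            truth.gene_modules.to_csv(out / "truth_modules.tsv", sep="\t")
            survival = generate_survival(truth, synth)
            survival.data.to_csv(out / "survival.tsv", sep="\t", index=False)
        if config.survival_path is not None:
            survival = read_survival_tsv(config.survival_path)
        gene_sets: GeneSetCollection | None = None
        if config.gene_sets_path is not None:
            gene_sets = read_gmt(config.gene_sets_path)
        elif truth is not None:
            gene_sets = generate_gene_sets(
                truth, n_random=20, seed=stage_seed(config.seed, "gene_sets"))

        # ---- preprocess ---------------------------------------------------
        logfc = preprocess(raw)
        write_expression_tsv(logfc, out / "expression_logfc.tsv")
        stage_done("preprocess", n_genes=logfc.n_genes, n_samples=logfc.n_samples)

        # ---- SOM ----------------------------------------------------------
        som_cfg = config.som
        model = train_som(logfc, som_cfg)
        model.save(out / "som_model.zip")
        stage_done("train", quantization_error=model.quantization_errors[-1])

        # ---- spots --------------------------------------------------------
        over = detect_spots(model, config.spot_percentile, OVER)
        under = detect_spots(model, config.spot_percentile, UNDER)
        write_spots_json(over, out / "spots_over.json")
        write_spots_json(under, out / "spots_under.json")
        _write_spot_report(over, under, out / "spot_report.tsv")
        profiles = spot_profiles(model, over) if len(over) else None
        if profiles is not None:
            profiles.to_csv(out / "spot_profiles.tsv", sep="\t")
            if len(over) >= 2 and model.metadata.shape[1] >= 3:
                spot_correlation(profiles).to_csv(
                    out / "spot_correlation.tsv", sep="\t", index=False)
        stage_done("spots", n_over=len(over), n_under=len(under))

        # ---- enrichment ---------------------------------------------------
        enrichment_tables: dict[str, pd.DataFrame] = {}
        p_threshold = None
        if gene_sets is not None and len(over):
            enr_cfg = EnrichmentConfig(alpha=config.alpha, n_tests=len(gene_sets))
            p_threshold = enr_cfg.p_threshold
            universe = logfc.gene_ids
            enr_dir = out / "enrichment"
            enr_dir.mkdir(exist_ok=True)
            for spot in over:
                table = spot_enrichment(spot.genes, gene_sets, universe)
                enrichment_tables[spot.label] = table
                table.to_csv(enr_dir / f"spot_{spot.label}.tsv", sep="\t", index=False)
            stage_done("enrichment", n_sets=len(gene_sets), p_threshold=p_threshold)
        else:
            stage_done("enrichment", skipped=True)

        # ---- outlier correction ------------------------------------------
        removed_genes: list[str] = []
        if enrichment_tables and config.flagged_categories and p_threshold:
            outliers = detect_outlier_spots(
                over, enrichment_tables, config.flagged_categories, p_threshold)
            if outliers:
                spots = [over.spots[l] for l in outliers]
                raw, new_model, removed_genes = correct_and_retrain(
                    raw, model, spots, som_cfg)
                if new_model is not None:
                    logfc = preprocess(raw)
                    model = new_model
                    model.save(out / "som_model_corrected.zip")
                    over = detect_spots(model, config.spot_percentile, OVER)
                    write_spots_json(over, out / "spots_over_corrected.json")
                    profiles = spot_profiles(model, over) if len(over) else None
                (out / "correction_log.tsv").write_text(
                    "removed_gene\n" + "".join(g + "\n" for g in removed_genes))
            stage_done("correction", outlier_spots=outliers,
                       n_removed_genes=len(removed_genes))
        else:
            stage_done("correction", skipped=True)

        # ---- similarity ---------------------------------------------------
        r = pairwise_correlation(model.metadata, model.sample_ids)
        r.to_csv(out / "correlation_matrix.tsv", sep="\t")
        net = correlation_network(r, config.r_threshold,
                                  seed=stage_seed(config.seed, "similarity"))
        write_edge_list(net.graph, out / "network_edges.tsv")
        dist = sample_distance_matrix(model.metadata, model.sample_ids)
        tree = nj_tree(dist)
        (out / "nj_tree.nwk").write_text(write_newick(tree.tree) + "\n")
        if model.metadata.shape[1] >= 2:
            ica = ica_embed(model.metadata, 2,
                            seed=stage_seed(config.seed, "ica"),
                            sample_ids=model.sample_ids)
            ica.to_csv(out / "ica_embedding.tsv", sep="\t")
        stage_done("similarity", n_edges=net.graph.number_of_edges())

        # ---- subtyping ----------------------------------------------------
        labels = None
        if len(over) >= config.n_subtypes:
            proto_labels = _rank_spots_by_size(over)[: config.n_subtypes]
            prototypes = {l: prototype_from_spot(over.spots[l], model)
                          for l in sorted(proto_labels)}
            result = kmeans_assign(model.metadata, prototypes,
                                   sample_ids=model.sample_ids)
            stability = bootstrap_stability(
                model.metadata, result.labels,
                subsample_fraction=config.bootstrap_fraction,
                n_reps=config.bootstrap_reps,
                seed=stage_seed(config.seed, "bootstrap"))
            labels = result.labels
            pd.DataFrame({"class": labels, "stability": stability}).to_csv(
                out / "subtype_labels.tsv", sep="\t", index_label="sample_id")
            consensus = consensus_cluster(
                model.metadata, model.sample_ids,
                k_range=config.consensus_k_range,
                n_reps=config.consensus_reps,
                subsample_fraction=config.bootstrap_fraction,
                seed=stage_seed(config.seed, "consensus"))
            cdf_rows = []
            for k, (grid, cdf) in consensus.cdf.items():
                for x, v in zip(grid, cdf):
                    cdf_rows.append({"k": k, "consensus": x, "cdf": v})
            pd.DataFrame(cdf_rows).to_csv(out / "consensus_cdf.tsv",
                                          sep="\t", index=False)
            stage_done("subtyping", prototype_spots=sorted(proto_labels),
                       cdf_areas=consensus.cdf_areas())
        else:
            stage_done("subtyping", skipped=True,
                       reason=f"fewer than {config.n_subtypes} spots")

        # ---- characterization --------------------------------------------
        if labels is not None and (survival is not None or config.phenotype_path
                                   or truth is not None):
            rows = []
            if truth is not None:
                pheno = pd.DataFrame({"true_class": truth.sample_labels})
            elif config.phenotype_path:
                pheno = pd.read_csv(config.phenotype_path, sep="\t",
                                    index_col="sample_id")
            else:
                pheno = None
            if pheno is not None:
                for res in characteristic_table(
                        labels, pheno, seed=stage_seed(config.seed, "fisher")):
                    rows.append({"characteristic": res.characteristic,
                                 "p": res.fisher.p, "method": res.fisher.method,
                                 "n_missing": res.n_missing})
            logrank = None
            if survival is not None:
                merged = survival.data.drop(columns="group", errors="ignore") \
                    .set_index("sample_id").join(labels.rename("subtype"),
                                                 how="inner")
                if merged["event"].sum() > 0:
                    stat, p = logrank_test(merged["time"], merged["event"],
                                           merged["subtype"])
                    logrank = {"statistic": stat, "p": p}
                    curves = survival_by_group(SurvivalTable(
                        merged.reset_index().rename(
                            columns={"subtype": "group"})
                        [["sample_id", "time", "event", "group"]]))
                    _write_km_tsv(curves, out / "km_curves.tsv")
            pd.DataFrame(rows).to_csv(out / "characteristics.tsv", sep="\t",
                                      index=False)
            stage_done("characterization",
                       n_characteristics=len(rows), logrank=logrank)
        else:
            stage_done("characterization", skipped=True)

    except Exception as exc:
        failed_after = [s["name"] for s in manifest["stages"]]
        raise RuntimeError(
            f"pipeline aborted after stages {failed_after}: {exc}"
        ) from exc

    manifest["runtime_seconds"] = round(time.time() - t_start, 2)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return manifest


def _write_spot_report(over: SpotSet, under: SpotSet, path) -> None:
    rows = []
    for spotset in (over, under):
        for s in spotset:
            rows.append({
                "label": s.label, "polarity": spotset.polarity,
                "n_metagenes": len(s.metagenes), "n_genes": len(s.genes),
                "centroid_row": s.centroid[0], "centroid_col": s.centroid[1],
            })
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def _write_km_tsv(curves: dict, path) -> None:
    rows = []
    for group, curve in curves.items():
        for t, s, n in zip(curve.times, curve.survival, curve.at_risk):
            rows.append({"group": group, "time": t, "survival": s, "at_risk": n})
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
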