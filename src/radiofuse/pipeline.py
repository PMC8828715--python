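"""End-to-end orchestration: simulate/load -> views -> features ->
signatures -> stage association -> gene filtering -> RRs -> enrichment.

Every stage draws its own seed deterministically from the global seed and
the stage name, so stages can be re-run independently and a rerun with
the same configuration reproduces the run report byte for byte (modulo
timestamps, which the report does not contain).  All artifacts are plain
text: CSV/TSV/JSON/GMT/NIfTI.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import clinical as clin
from . import gsea
from . import rr as rrmod
from .core import derive_seed
from .deepfeat import DEFAULT_WIDTH, extract_deep, filterbank_standin
from .genes import filter_genes
from .hcfeat import HCConfig, extract_hc, hc_feature_names
from .imaging import extract_views
from .selection import SelectionConfig, build_signatures, fuse
from .synthcohort import PlantedLink, SyntheticCohort, generate_cohort

DEFAULT_LINK_FEATURES = (
    "firstorder.mean",
    "shape.volume_mm3",
    "glcm.contrast",
    "wavelet.LLL.firstorder.std",
)


@dataclass
class RunConfig:
    """Parameters of one pipeline run (simulation-backed by default)."""

    n_patients: int = 40
    n_genes: int = 200
    n_links: int = 4
    link_strength: float = 0.6
    n_gene_sets: int = 10
    # drawn over all genes pre-filter, so sized such that the effective
    # (post-filter) sizes stay above the 15-gene enrichment floor
    gene_set_size_range: tuple[int, int] = (40, 60)
    grid_shape: tuple[int, int, int] = (44, 44, 44)
    deep_width: int = DEFAULT_WIDTH
    mad_drop_quantile: float = 0.25
    mrmr_k: int = 100
    lasso_folds: int = 10
    kmeans_k: int = 3
    kmeans_restarts: int = 10
    gene_filter_q: float = 0.25
    rr_alpha: float = 0.001
    gsea_size_bounds: tuple[int, int] = (15, 500)
    gsea_n_perm: int = 1000
    gsea_alpha: float = 0.05
    seed: int = 0
    out_dir: str | None = None


class StageError(RuntimeError):
    """Raised when a pipeline stage fails; carries the stage name so the
    run can be resumed from the persisted intermediates."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(
            f"stage {stage!r} failed: {cause}. Intermediates written so far "
            "remain in the output directory; rerun from this stage after "
            "fixing the input."
        )
        self.stage = stage


def _default_links(cfg: RunConfig) -> list[PlantedLink]:
    feats = list(DEFAULT_LINK_FEATURES)
    catalogue = hc_feature_names()
    while len(feats) < cfg.n_links:
        feats.append(catalogue[len(feats) * 37 % len(catalogue)])
    return [
        PlantedLink(gene_id=f"LINK{i:02d}", feature_id=feats[i],
                    strength=cfg.link_strength)
        for i in range(cfg.n_links)
    ]


def run_pipeline(cfg: RunConfig,
                 cohort: SyntheticCohort | None = None) -> dict:
    """Execute the full workflow and return the machine-readable report.

    A pre-built cohort can be supplied (e.g. loaded from disk); otherwise
    one is simulated from the config.  When ``cfg.out_dir`` is set, every
    intermediate artifact and the report are persisted there.
    """
    out = Path(cfg.out_dir) if cfg.out_dir else None
    if out:
        out.mkdir(parents=True, exist_ok=True)
    report: dict = {"config": asdict(cfg), "stages": {}}

    def _save_df(df: pd.DataFrame, name: str, **kw) -> None:
        if out:
            df.to_csv(out / name, **kw)

    # -- simulate -----------------------------------------------------------
    stage = "simulate"
    try:
        if cohort is None:
            links = _default_links(cfg)
            cohort = generate_cohort(
                cfg.n_patients, cfg.n_genes, links,
                seed=derive_seed(cfg.seed, stage),
                grid_shape=cfg.grid_shape,
                n_gene_sets=cfg.n_gene_sets,
                gene_set_size_range=cfg.gene_set_size_range,
            )
        report["stages"][stage] = {
            "n_patients": len(cohort.patient_ids),
            "n_genes": cohort.expression.shape[0],
            "n_links": len(cohort.truth.get("links", [])),
            "n_gene_sets": len(cohort.gene_sets),
            "seed": derive_seed(cfg.seed, stage),
        }
        _save_df(cohort.clinical, "clinical.csv", index=False)
        if out:
            cohort.expression.to_csv(out / "expression.tsv", sep="\t",
                                     index_label="gene")
            if cohort.gene_sets:
                gsea.write_gmt(cohort.gene_sets, out / "gene_sets.gmt")
    except Exception as e:  # noqa: BLE001
        raise StageError(stage, e) from e

    # -- views + feature blocks --------------------------------------------
    stage = "features"
    try:
        hc = cohort.hc_features
        tl_extractor = filterbank_standin(derive_seed(cfg.seed, "tl"),
                                          cfg.deep_width)
        ft_extractor = filterbank_standin(derive_seed(cfg.seed, "ft"),
                                          cfg.deep_width)
        tl_rows, ft_rows = [], []
        for vm in cohort.volumes_masks:
            views = extract_views(vm)
            tl_rows.append(extract_deep(views, tl_extractor, block="TL"))
            ft_rows.append(extract_deep(views, ft_extractor, block="FT"))
        tl = pd.DataFrame([fv.values for fv in tl_rows],
                          index=cohort.patient_ids,
                          columns=[f"TL.{n}" for n in tl_rows[0].names])
        ft = pd.DataFrame([fv.values for fv in ft_rows],
                          index=cohort.patient_ids,
                          columns=[f"FT.{n}" for n in ft_rows[0].names])
        report["stages"][stage] = {
            "hc_dim": hc.shape[1], "tl_dim": tl.shape[1],
            "ft_dim": ft.shape[1],
            "fused_dim": hc.shape[1] + tl.shape[1] + ft.shape[1],
        }
        _save_df(hc, "features_hc.csv", index_label="patient_id")
        _save_df(tl, "features_tl.csv", index_label="patient_id")
        _save_df(ft, "features_ft.csv", index_label="patient_id")
    except Exception as e:  # noqa: BLE001
        raise StageError(stage, e) from e

    # -- signatures ---------------------------------------------------------
    stage = "signatures"
    try:
        sel_cfg = SelectionConfig(mad_drop_quantile=cfg.mad_drop_quantile,
                                  mrmr_k=cfg.mrmr_k,
                                  lasso_folds=cfg.lasso_folds)
        sigs = build_signatures(hc, tl, ft,
                                cohort.clinical["histology"],
                                config=sel_cfg,
                                seed=derive_seed(cfg.seed, stage))
        fused = fuse([hc, tl, ft], ["HC", "TL", "FT"])
        report["stages"][stage] = {
            name: {"n_features": len(sig), "trace": sig.trace,
                   "features": sig.feature_ids}
            for name, sig in sigs.items()
        }
        if out:
            (out / "signatures.json").write_text(json.dumps(
                {name: {"feature_ids": sig.feature_ids,
                        "source": sig.source, "trace": sig.trace,
                        "lambda_min": sig.lambda_min}
                 for name, sig in sigs.items()}, indent=2, default=float))
    except Exception as e:  # noqa: BLE001
        raise StageError(stage, e) from e

    # -- T-stage association ------------------------------------------------
    stage = "stage_association"
    assoc: dict = {}
    for name, sig in sigs.items():
        if sig.empty:
            assoc[name] = {"generated": False}
            continue
        sig_matrix = fused.matrix[sig.feature_ids]
        try:
            labels = clin.cluster_patients(
                sig_matrix, k=cfg.kmeans_k, restarts=cfg.kmeans_restarts,
                seed=derive_seed(cfg.seed, stage))
            chi2, df, p = clin.chi2_stage_association(labels, cohort.clinical)
            assoc[name] = {"generated": True, "chi2": chi2, "df": df, "p": p}
            if out and name == "FF":
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    z = clin.zscore_table(sig_matrix)
                z.assign(cluster=labels).sort_values("cluster").to_csv(
                    out / "ff_sig_zscores.csv", index_label="patient_id")
        except ValueError as e:
            assoc[name] = {"generated": True, "error": str(e)}
    report["stages"][stage] = assoc

    # -- gene filtering ------------------------------------------------------
    stage = "gene_filtering"
    try:
        kept, counts = filter_genes(cohort.expression, q=cfg.gene_filter_q)
        report["stages"][stage] = counts
        if out:
            kept.to_csv(out / "expression_filtered.tsv", sep="\t",
                        index_label="gene")
    except Exception as e:  # noqa: BLE001
        raise StageError(stage, e) from e

    # -- radiogenomics relationships ----------------------------------------
    stage = "rr"
    try:
        rr_tables: dict[str, rrmod.RRTable] = {}
        for name, sig in sigs.items():
            if sig.empty:
                continue
            feats = fused.matrix[sig.feature_ids]
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                rr_tables[name] = rrmod.spearman_rr(
                    feats, kept, alpha=cfg.rr_alpha, source=name)
            _save_df(rr_tables[name].rows, f"rr_{name.lower()}.csv",
                     index=False)
        summary = rrmod.rr_summary(rr_tables) if rr_tables else {}
        strength = {}
        if "FF" in rr_tables:
            for other in ("HC", "TL", "FT"):
                if other in rr_tables:
                    strength[f"FF_vs_{other}"] = rrmod.compare_strengths(
                        rr_tables["FF"], rr_tables[other])
        report["stages"][stage] = {"summary": summary,
                                   "strength_tests": strength}
    except Exception as e:  # noqa: BLE001
        raise StageError(stage, e) from e

    # -- enrichment ----------------------------------------------------------
    stage = "enrichment"
    try:
        enrich: dict = {}
        if cohort.gene_sets:
            for name, sig in sigs.items():
                if sig.empty:
                    enrich[name] = {"generated": False,
                                    "reason": "signature not generated"}
                    continue
                feats = fused.matrix[sig.feature_ids]
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    rho, pmat = rrmod.spearman_matrix(feats, kept)
                rho_df = pd.DataFrame(rho, index=sig.feature_ids,
                                      columns=kept.index)
                p_df = pd.DataFrame(pmat, index=sig.feature_ids,
                                    columns=kept.index)
                res = gsea.signature_enrichment(
                    rho_df, p_df, cohort.gene_sets,
                    size_bounds=cfg.gsea_size_bounds,
                    alpha_rr=cfg.rr_alpha, alpha_go=cfg.gsea_alpha,
                    n_perm=cfg.gsea_n_perm,
                    seed=derive_seed(cfg.seed, f"gsea_{name}"))
                enrich[name] = {
                    "generated": res["generated"],
                    "n_significant": res.get("n_significant", 0),
                    "terms": res.get("terms", {}),
                }
                if out and res["generated"]:
                    pd.DataFrame([
                        {"set_id": r.set_id, "feature_id": r.source_feature,
                         "es": r.es, "nes": r.nes, "p": r.p, "size": r.size}
                        for r in res["results"]
                    ]).to_csv(out / f"enrichment_{name.lower()}.csv",
                              index=False)
        report["stages"][stage] = {
            name: {k: v for k, v in entry.items() if k != "terms"}
            for name, entry in enrich.items()
        }
    except Exception as e:  # noqa: BLE001
        raise StageError(stage, e) from e

    # -- truth recovery (synthetic runs) ------------------------------------
    links = cohort.truth.get("links", [])
    if links:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            rho, pmat = rrmod.spearman_matrix(cohort.hc_features,
                                              cohort.expression)
        feat_idx = {f: i for i, f in enumerate(cohort.hc_features.columns)}
        gene_idx = {g: i for i, g in enumerate(cohort.expression.index)}
        recov = []
        for lk in links:
            fi, gi = feat_idx[lk["feature_id"]], gene_idx[lk["gene_id"]]
            recov.append({
                "gene_id": lk["gene_id"], "feature_id": lk["feature_id"],
                "target_strength": lk["strength"],
                "realised_rho": float(rho[fi, gi]),
                "p": float(pmat[fi, gi]),
                "called": bool(pmat[fi, gi] < cfg.rr_alpha),
            })
        report["truth_recovery"] = {
            "links": recov,
            "sensitivity": float(np.mean([r["called"] for r in recov])),
            "planted_set_ids": cohort.truth.get("planted_set_ids", []),
        }

    if out:
        (out / "report.json").write_text(
            json.dumps(report, indent=2, default=str))
    return report
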