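"""End-to-end orchestration: masks → features → indices → phenotypes → clinic.

A run compiles each case's one-vs-all masks, extracts the seven
morphometry indicators, applies the biopsy adequacy criteria, fits the
z-scaler / index PCA / K-means phenotypes on the training cohort, freezes
them, projects the test cohorts, and computes the clinical associations.
All randomness flows from the single seed in :class:`PipelineConfig`
(K-means uses it directly; nothing else in the run is stochastic).
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as nio
from .clinical import (
    compute_rsc_slope,
    index_vs_ordinal,
    renal_function_pca,
    tertile_rejection_analysis,
)
from .maskops import ClassConfig, compile_masks
from .morphometry import (
    FEATURES_7,
    SamplingCriteria,
    apply_sampling,
    extract_features,
    records_to_frame,
)
from .multivariate import (
    apply_scaler,
    fit_clusters,
    fit_pca,
    predict_clusters,
    project,
)
from .synthetic import SyntheticCase, SyntheticParams, generate_cohort


class PipelineError(RuntimeError):
    """A stage failed; carries the stage name and the offending case."""

    def __init__(self, stage: str, case_id: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed for case {case_id!r}: {cause}")
        self.stage = stage
        self.case_id = case_id
        self.cause = cause


@dataclass
class PipelineConfig:
    """Fully serializable run configuration, archived alongside outputs."""

    pixel_size_um: float = 0.5
    class_config: ClassConfig = field(default_factory=ClassConfig)
    sampling: str = "internal"  # "internal" | "external" | "none"
    min_cta_mm2: float | None = None  # override for reduced-field runs
    pca_retention: str | int = "kaiser"
    k: int | None = 4  # None = silhouette selection over 2..8
    seed: int = 0
    outdir: str | None = None

    def criteria(self, cohort: str) -> SamplingCriteria | None:
        if self.sampling == "none":
            return None
        crit = SamplingCriteria.external() if (
            self.sampling == "external" or cohort == "external_test"
        ) else SamplingCriteria()
        if self.min_cta_mm2 is not None:
            crit = SamplingCriteria(min_glomeruli=crit.min_glomeruli, min_cta_mm2=self.min_cta_mm2)
        return crit

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["class_config"]["priority"] = list(d["class_config"]["priority"])
        return d


def run_pipeline(
    cases: list[SyntheticCase], config: PipelineConfig | None = None
) -> dict:
    """Execute the full analysis over in-memory cases.

    Returns a report dict with the feature table, fitted models, per-case
    scores and cluster labels, and the clinical association results. If
    ``config.outdir`` is set, tables and models are also written there
    together with the archived config.
    """
    config = config or PipelineConfig()

    records, meta_rows = [], []
    for case in cases:
        cid = case.metadata.case_id
        try:
            seg = compile_masks(case.mask_set, config.class_config)
        except Exception as e:  # noqa: BLE001 - rewrap with stage context
            raise PipelineError("compile", cid, e) from e
        try:
            rec = extract_features(seg, truth_labels=case.truth_labels, case_id=cid)
        except Exception as e:  # noqa: BLE001
            raise PipelineError("extract", cid, e) from e
        records.append(rec)
        meta_rows.append(
            {
                "case_id": cid,
                "cohort": case.metadata.cohort,
                "banff_ci": case.metadata.banff_ci,
                "acute_rejection": case.metadata.acute_rejection,
                "archetype": case.archetype,
                "chronicity": case.params.chronicity,
                "acuity": case.params.acuity,
            }
        )
    meta = pd.DataFrame(meta_rows).set_index("case_id")

    # adequacy criteria per cohort
    kept, excluded = [], []
    for rec in records:
        crit = config.criteria(meta.loc[rec.case_id, "cohort"])
        if crit is None:
            kept.append(rec)
            continue
        k_, e_ = apply_sampling([rec], crit)
        kept.extend(k_)
        excluded.extend(e_)

    features = records_to_frame(kept).set_index("case_id")
    if features[FEATURES_7].isna().any().any():
        bad = features[features[FEATURES_7].isna().any(axis=1)].index.tolist()
        raise PipelineError("features", bad[0], ValueError("undefined tubular features"))
    cohorts = meta.loc[features.index, "cohort"]
    training = features.loc[cohorts == "training", FEATURES_7]
    if len(training) == 0:  # single-cohort runs: treat everything as training
        training = features[FEATURES_7]

    model = fit_pca(training, retention=config.pca_retention)
    scores = project(model, features[FEATURES_7])
    z_train = apply_scaler(model.scaler, training)
    cluster_model = fit_clusters(z_train, k=config.k, seed=config.seed)
    z_all = apply_scaler(model.scaler, features[FEATURES_7])
    cluster_labels = predict_clusters(cluster_model, z_all)

    # clinical associations on scored cases
    sub_meta = meta.loc[features.index]
    ci_assoc = index_vs_ordinal(
        scores["ChronicityIndex"].to_numpy(), sub_meta["banff_ci"].to_numpy()
    )
    tertiles = tertile_rejection_analysis(
        scores["InvertedAcuteIndex"].to_numpy(),
        sub_meta["acute_rejection"].to_numpy(dtype=bool),
    )
    rf_rows = []
    for case in cases:
        cid = case.metadata.case_id
        if cid not in features.index:
            continue
        rf = compute_rsc_slope(case.metadata.creatinine_series)
        rf_rows.append(
            {
                "case_id": cid,
                "InvertedAcuteIndex": scores.loc[cid, "InvertedAcuteIndex"],
                "ChronicityIndex": scores.loc[cid, "ChronicityIndex"],
                "rSC": rf.rsc,
                "rSCs": rf.rscs if rf.sufficient_followup else np.nan,
            }
        )
    rf_table = pd.DataFrame(rf_rows).set_index("case_id")
    try:
        rf_pca = renal_function_pca(rf_table)
    except ValueError:
        rf_pca = None

    report = {
        "config": config.to_dict(),
        "n_cases": len(cases),
        "n_kept": len(kept),
        "n_excluded": len(excluded),
        "exclusions": [(r.case_id, reason) for r, reason in excluded],
        "features": features,
        "meta": sub_meta,
        "index_model": model,
        "scores": scores,
        "cluster_model": cluster_model,
        "cluster_labels": pd.Series(cluster_labels, index=features.index, name="cluster"),
        "ci_association": ci_assoc,
        "tertile_analysis": tertiles,
        "renal_function_table": rf_table,
        "renal_function_pca": rf_pca,
    }
    if config.outdir:
        _write_outputs(Path(config.outdir), report, config)
    return report


def _write_outputs(outdir: Path, report: dict, config: PipelineConfig) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    feats = report["features"].reset_index()
    nio.write_feature_table(outdir / "features.csv", feats)
    scored = report["scores"].copy()
    scored["cluster"] = report["cluster_labels"]
    scored["phenotype"] = [
        report["cluster_model"].semantic_labels[i] for i in report["cluster_labels"]
    ]
    scored.to_csv(outdir / "scores.csv")
    nio.write_index_model(outdir / "index_model.json", report["index_model"])
    nio.write_cluster_model(outdir / "cluster_model.json", report["cluster_model"])
    summary = {
        "config": config.to_dict(),
        "n_cases": report["n_cases"],
        "n_kept": report["n_kept"],
        "n_excluded": report["n_excluded"],
        "exclusions": report["exclusions"],
        "kruskal_ci": report["ci_association"].get("kruskal"),
        "tertile_freq_pct": report["tertile_analysis"]["rejection_freq_pct"],
    }
    (outdir / "report.json").write_text(json.dumps(summary, indent=2, sort_keys=True, default=str))
    nio.write_yaml(outdir / "config.yaml", config.to_dict())


# --------------------------------------------------------------------------
# Case persistence (simulate → disk → run)


def save_case(dirpath: str | Path, case: SyntheticCase) -> dict:
    """Write one case (masks, truth raster, metadata) and return its manifest entry."""
    dirpath = Path(dirpath)
    dirpath.mkdir(parents=True, exist_ok=True)
    nio.write_mask_set(dirpath, case.mask_set)
    nio.write_labels(dirpath / "truth_labels.tif", case.truth_labels.astype(np.int16))
    if case.rgb_render is not None:
        nio.write_png(dirpath / "render.png", case.rgb_render)
    return {
        "case_id": case.metadata.case_id,
        "dir": dirpath.name,
        "cohort": case.metadata.cohort,
        "banff_ci": int(case.metadata.banff_ci),
        "acute_rejection": bool(case.metadata.acute_rejection),
        "creatinine_series": [[float(t), float(v)] for t, v in case.metadata.creatinine_series],
        "archetype": case.archetype,
        "latent": {"chronicity": case.params.chronicity, "acuity": case.params.acuity},
        "truth": {
            "areas_um2": {k: float(v) for k, v in case.truth_areas.items()},
            "tubule_count": case.truth_tubule_count,
            "nucleus_count": case.truth_nucleus_count,
        },
    }


def simulate_to_dir(
    outdir: str | Path,
    n: int,
    design: str = "continuous",
    seed: int = 0,
    base_params: SyntheticParams | None = None,
    splits: dict[str, float] | None = None,
) -> Path:
    """Generate a cohort and persist it with a YAML manifest and truth CSV."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cases = generate_cohort(n, design=design, seed=seed, base_params=base_params, splits=splits)
    entries = [save_case(outdir / c.metadata.case_id, c) for c in cases]
    px = (base_params or SyntheticParams()).pixel_size_um
    nio.write_yaml(
        outdir / "manifest.yaml",
        {"pixel_size_um": px, "design": design, "seed": seed, "cases": entries},
    )
    truth = pd.DataFrame(
        [
            {
                "case_id": e["case_id"],
                "cohort": e["cohort"],
                "chronicity": e["latent"]["chronicity"],
                "acuity": e["latent"]["acuity"],
                "archetype": e["archetype"],
                **{f"truth_{k}_um2": v for k, v in e["truth"]["areas_um2"].items()},
                "truth_tubule_count": e["truth"]["tubule_count"],
                "truth_nucleus_count": e["truth"]["nucleus_count"],
            }
            for e in entries
        ]
    )
    truth.to_csv(outdir / "truth.csv", index=False)
    return outdir / "manifest.yaml"


def load_cases(manifest_path: str | Path) -> list[SyntheticCase]:
    """Reload persisted cases from a manifest for a file-driven run."""
    from .maskops import ClassMaskSet  # noqa: F401 (shape check happens in read)
    from .synthetic import CaseMetadata

    manifest_path = Path(manifest_path)
    manifest = nio.read_yaml(manifest_path)
    root = manifest_path.parent
    cases = []
    for e in manifest["cases"]:
        d = root / e["dir"]
        mask_set = nio.read_mask_set(d)
        if "cortex" not in mask_set.masks:
            raise PipelineError(
                "load", e["case_id"], ValueError("case lacks a cortex mask")
            )
        truth_labels = nio.read_labels(d / "truth_labels.tif").astype(np.uint8)
        meta = CaseMetadata(
            case_id=e["case_id"],
            banff_ci=e["banff_ci"],
            acute_rejection=e["acute_rejection"],
            creatinine_series=[(t, v) for t, v in e["creatinine_series"]],
            cohort=e["cohort"],
        )
        params = SyntheticParams(
            chronicity=e["latent"]["chronicity"],
            acuity=e["latent"]["acuity"],
            pixel_size_um=mask_set.pixel_size_um,
        )
        cases.append(
            SyntheticCase(
                mask_set=mask_set,
                truth_labels=truth_labels,
                truth_areas={
                    k.replace("truth_", "").replace("_um2", ""): v
                    for k, v in e["truth"]["areas_um2"].items()
                },
                truth_tubule_count=e["truth"]["tubule_count"],
                truth_nucleus_count=e["truth"]["nucleus_count"],
                params=params,
                metadata=meta,
                archetype=e.get("archetype"),
            )
        )
    return cases
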