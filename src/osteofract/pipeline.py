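"""End-to-end orchestration: images -> per-image features -> statistics.

``run_extract`` walks a cohort table, computes the nine features (four
fractal, five GLCM) for every image, and writes one CSV row per image.
``run_evaluate`` aggregates per-image rows to patient x section values
(three planes plus their average), and for every feature x section cell
reports the univariable logistic P on optimal-cutpoint-categorized values,
the continuous-value AUC with a bootstrap bias-corrected 95% CI, and the
classification accuracy at the optimal threshold; it then runs the
stepwise multivariable model on the averaged, categorized features and a
Spearman correlation of features against the tumor size covariates.

Outputs carry a header comment line with a hash of the configuration, so a
result file can always be traced to the exact settings that produced it.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from .errors import OsteofractError, ValidationError
from .fractal import FractalConfig, fractal_features
from .glcm import GLCMConfig, glcm_features
from .imaging import load_grayscale
from .stats import (
    aggregate_features,
    auc_continuous,
    bootstrap_bias_corrected,
    classification_accuracy,
    fit_logistic,
    optimal_threshold,
    spearman_correlation,
    stepwise_selection,
)
from .synthetic import FEATURE_COLUMNS

logger = logging.getLogger("osteofract")

__all__ = ["RunConfig", "run_extract", "run_evaluate", "extract_image_features"]

SECTIONS = ("coronal", "sagittal", "transversal", "average")


@dataclass
class RunConfig:
    """Serializable settings of a full pipeline run."""

    cohort_csv: Optional[str] = None
    data_dir: Optional[str] = None
    output_dir: str = "osteofract_out"
    binarize_method: str = "otsu"
    fixed_threshold: Optional[int] = None
    box_sizes: Optional[list[int]] = None
    glcm_levels: int = 256
    glcm_symmetric: bool = True
    glcm_log_base: float = 2.0
    glcm_use_mask: bool = True
    n_boot: int = 1000
    alpha: float = 0.05
    p_enter: float = 0.10
    p_stay: float = 0.05
    seed: int = 0

    def fractal_config(self) -> FractalConfig:
        return FractalConfig(
            box_sizes=self.box_sizes,
            binarize_method=self.binarize_method,
            fixed_threshold=self.fixed_threshold,
        )

    def glcm_config(self) -> GLCMConfig:
        return GLCMConfig(
            levels=self.glcm_levels,
            symmetric=self.glcm_symmetric,
            log_base=self.glcm_log_base,
            use_mask=self.glcm_use_mask,
        )

    def config_hash(self) -> str:
        # identifies the analysis settings; where the output lands is not
        # part of the scientific configuration
        payload = dataclasses.asdict(self)
        payload.pop("output_dir")
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True, default=str).encode()
        ).hexdigest()[:16]

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self)))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text())
        return cls(**data)


def _write_csv(df: pd.DataFrame, path: Path, cfg: RunConfig) -> None:
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write(f"# config_hash={cfg.config_hash()}\n")
        df.to_csv(fh, index=False)


def read_output_csv(path: str | Path) -> pd.DataFrame:
    """Read a pipeline CSV, skipping the config-hash header line."""
    return pd.read_csv(path, comment="#")


def extract_image_features(gray, cfg: RunConfig | None = None) -> dict:
    """The nine features of one loaded ROI as a flat dict."""
    cfg = cfg or RunConfig()
    ff = fractal_features(gray, cfg.fractal_config())
    gf = glcm_features(gray, cfg.glcm_config())
    return {
        "d_bin": ff.d_bin,
        "d_out": ff.d_out,
        "sfr": ff.sfr,
        "lambda": ff.lacunarity,
        "s_asm": gf.s_asm,
        "s_idm": gf.s_idm,
        "s_cn": gf.s_cn,
        "s_cr": gf.s_cr,
        "s_e": gf.s_e,
        "threshold": ff.notes.get("threshold"),
        "n_sizes": ff.notes.get("n_sizes"),
    }


def run_extract(cfg: RunConfig) -> pd.DataFrame:
    """Compute per-image features for every row of the cohort table.

    Unreadable or degenerate images are logged and skipped; the run fails
    only if no image could be processed.  The feature table is written to
    ``<output_dir>/features.csv``.
    """
    if cfg.cohort_csv is None:
        raise ValidationError("cohort_csv must be set")
    cohort = pd.read_csv(cfg.cohort_csv, comment="#")
    base = Path(cfg.data_dir) if cfg.data_dir else Path(cfg.cohort_csv).parent
    rows = []
    n_failed = 0
    for _, rec in cohort.iterrows():
        image_id = f"{rec['patient_id']}_{rec['plane']}_{rec['replicate']}"
        try:
            gray = load_grayscale(
                base / rec["image"],
                base / rec["mask"] if isinstance(rec.get("mask"), str) else None,
                plane=rec["plane"],
                image_id=image_id,
            )
            feats = extract_image_features(gray, cfg)
        except OsteofractError as exc:
            n_failed += 1
            logger.warning("skipping %s: %s", image_id, exc)
            continue
        rows.append(
            {
                "patient_id": rec["patient_id"],
                "plane": rec["plane"],
                "replicate": rec["replicate"],
                "image_id": image_id,
                **feats,
            }
        )
    if not rows:
        raise OsteofractError("no image in the cohort could be processed")
    if n_failed:
        logger.warning("%d of %d images failed and were skipped", n_failed, len(cohort))
    features = pd.DataFrame(rows)
    _write_csv(features, Path(cfg.output_dir) / "features.csv", cfg)
    return features


def run_evaluate(
    features: pd.DataFrame | str | Path,
    cohort: pd.DataFrame | str | Path,
    cfg: RunConfig | None = None,
    feature_cols: Sequence[str] = FEATURE_COLUMNS,
) -> dict:
    """The full statistical evaluation on a per-image feature table.

    Returns a dict with keys ``results`` (feature x section grid),
    ``model`` (stepwise multivariable LogisticModel), ``spearman``
    (features vs tumor size covariates), and ``aggregated`` (patient x
    section values).  Tables are also written under ``cfg.output_dir``.
    """
    cfg = cfg or RunConfig()
    if not isinstance(features, pd.DataFrame):
        features = read_output_csv(features)
    if not isinstance(cohort, pd.DataFrame):
        cohort = pd.read_csv(cohort, comment="#")
    labels_by_patient = (
        cohort.drop_duplicates("patient_id").set_index("patient_id")["response"]
    )
    if labels_by_patient.nunique() < 2:
        raise ValidationError("cohort contains a single responder class")
    unknown = set(features["patient_id"]) - set(labels_by_patient.index)
    if unknown:
        raise ValidationError(f"feature rows without cohort entry: {sorted(unknown)}")

    feature_cols = [c for c in feature_cols if c in features.columns]
    agg = aggregate_features(features, feature_cols)
    agg["response"] = agg["patient_id"].map(labels_by_patient)

    results_rows = []
    rules: dict[tuple[str, str], object] = {}
    for feat in feature_cols:
        for section in SECTIONS:
            sub = agg[agg["section"] == section][["patient_id", feat, "response"]]
            sub = sub.dropna(subset=[feat])
            row = {"feature": feat, "section": section, "n": len(sub)}
            if len(sub) >= 4 and sub["response"].nunique() == 2:
                values = sub[feat].to_numpy()
                labels = sub["response"].to_numpy()
                try:
                    rule = optimal_threshold(values, labels, feature=feat)
                    rules[(feat, section)] = rule
                    cat = rule.apply(values).astype(float)
                    row["p"] = np.nan
                    row["p_method"] = "logistic_wald"
                    if np.unique(cat).size > 1:
                        with warnings.catch_warnings():
                            warnings.simplefilter("ignore")
                            model = fit_logistic(
                                pd.DataFrame({feat: cat}), labels
                            )
                        row["p"] = float(model.p_values.get(feat, np.nan))
                        if model.separation or not np.isfinite(row["p"]):
                            # Wald p is undefined under (quasi-)separation;
                            # fall back to the cutpoint's chi-square p
                            row["p"] = rule.p_value
                            row["p_method"] = "chi2_fallback"
                    roc = bootstrap_bias_corrected(
                        values, labels, cfg.n_boot, cfg.alpha, cfg.seed
                    )
                    row.update(
                        auc=roc.auc,
                        ci_lo=roc.ci_corrected[0],
                        ci_hi=roc.ci_corrected[1],
                        accuracy=classification_accuracy(rule, values, labels),
                        cutpoint=rule.cutpoint,
                        direction=rule.direction,
                    )
                except (ValidationError, OsteofractError) as exc:
                    logger.warning("%s/%s: %s", feat, section, exc)
            results_rows.append(row)
    results = pd.DataFrame(results_rows)

    # multivariable model on averaged, categorized features
    avg = agg[agg["section"] == "average"].set_index("patient_id")
    labels_avg = avg["response"]
    cand = {}
    for feat in feature_cols:
        rule = rules.get((feat, "average"))
        col = avg[feat]
        if rule is not None and col.notna().all():
            cand[feat] = rule.apply(col.to_numpy()).astype(float)
    model = None
    if cand and labels_avg.nunique() == 2:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = stepwise_selection(
                pd.DataFrame(cand, index=avg.index),
                labels_avg,
                p_enter=cfg.p_enter,
                p_stay=cfg.p_stay,
            )

    # Spearman correlation of averaged features vs tumor size covariates
    spearman_rows = []
    size_cols = [c for c in ("tumor_volume", "tumor_surface") if c in cohort.columns]
    if size_cols:
        sizes = cohort.drop_duplicates("patient_id").set_index("patient_id")
        for feat in feature_cols:
            for section in SECTIONS:
                sub = agg[agg["section"] == section].set_index("patient_id")[feat]
                for sc in size_cols:
                    pair = pd.concat([sub, sizes[sc]], axis=1).dropna()
                    if len(pair) >= 3:
                        with warnings.catch_warnings():
                            warnings.simplefilter("ignore")
                            rho = spearman_correlation(
                                pair[feat].to_numpy(), pair[sc].to_numpy()
                            )
                    else:
                        rho = math.nan
                    spearman_rows.append(
                        {"feature": feat, "section": section, "covariate": sc, "rho": rho}
                    )
    spearman = pd.DataFrame(spearman_rows)

    out = Path(cfg.output_dir)
    _write_csv(results, out / "results.csv", cfg)
    _write_csv(spearman, out / "spearman.csv", cfg)
    _write_csv(agg, out / "aggregated.csv", cfg)
    _write_report(out / "report.txt", cfg, results, model, spearman)
    return {"results": results, "model": model, "spearman": spearman, "aggregated": agg}


def _write_report(path: Path, cfg: RunConfig, results, model, spearman) -> None:
    lines = [
        f"osteofract evaluation report (config_hash={cfg.config_hash()})",
        "",
        "Univariable results (P from logistic fit on optimal-cutpoint-",
        "categorized values; AUC on continuous values, poor responder",
        "positive; 95% CI bootstrap bias-corrected; accuracy at threshold):",
        "",
        results.to_string(index=False),
        "",
    ]
    if model is not None:
        if model.included:
            table = pd.DataFrame(
                {
                    "coefficient": model.coefficients,
                    "std_error": model.std_errors,
                    "p": model.p_values,
                }
            )
            lines += ["Stepwise multivariable logistic model:", table.to_string(), ""]
        else:
            lines += [f"Stepwise multivariable model: {model.note}", ""]
    if spearman is not None and not spearman.empty:
        lines += [
            "Spearman correlation vs tumor size covariates:",
            spearman.to_string(index=False),
            "",
        ]
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text("\n".join(lines))
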