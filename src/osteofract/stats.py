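"""Predictive evaluation: optimal cutpoints, stepwise logistic regression,
bootstrap bias-corrected ROC/AUC, accuracy, and Spearman correlation.

The response label throughout is binary with **poor responder as the
positive class** (necrosis <= 90% after induction chemotherapy).  The AUC
is the Mann-Whitney probability that a poor responder's feature value
exceeds a good responder's (ties count 1/2), and its orientation is never
flipped: an AUC below 0.5 means the feature runs higher in good
responders, which is itself informative and is reported as-is.

Continuous features are dichotomized at the cutpoint maximizing the
Pearson chi-square of the induced 2x2 table against the response (the
"minimum-p" optimal-cutpoint method implemented by X-tile-style tools).
Cutpoint optimization inflates apparent significance; the bootstrap layer
and the null-calibration tests quantify this rather than hide it.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Literal, Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps
from statsmodels.tools.sm_exceptions import (
    ConvergenceWarning,
    PerfectSeparationError,
    PerfectSeparationWarning,
)

from .errors import ValidationError

__all__ = [
    "ThresholdRule",
    "RocSummary",
    "LogisticModel",
    "aggregate_features",
    "auc_continuous",
    "bootstrap_bias_corrected",
    "optimal_threshold",
    "classification_accuracy",
    "fit_logistic",
    "stepwise_selection",
    "spearman_correlation",
]


def _as_labels(labels) -> np.ndarray:
    """Coerce labels to a boolean array, True = poor responder."""
    arr = np.asarray(labels)
    if arr.dtype.kind in "USO":
        known = {"poor": True, "good": False}
        try:
            arr = np.array([known[str(v).lower()] for v in arr])
        except KeyError as exc:
            raise ValidationError(f"unknown response label {exc}") from exc
    return arr.astype(bool)


@dataclass
class ThresholdRule:
    """A dichotomization rule for one feature."""

    feature: str
    cutpoint: float
    direction: Literal["greater_is_positive", "lesser_is_positive"]
    chi_square: float
    p_value: float

    def apply(self, values) -> np.ndarray:
        """Categorize values: True = predicted poor responder."""
        values = np.asarray(values, dtype=float)
        above = values > self.cutpoint
        return above if self.direction == "greater_is_positive" else ~above


@dataclass
class RocSummary:
    auc: float
    ci_raw: tuple[float, float]
    bias: float
    ci_corrected: tuple[float, float]
    n_boot: int
    seed: int


@dataclass
class LogisticModel:
    """A fitted (or failed) binary logistic regression."""

    included: list[str]
    coefficients: "pd.Series"
    std_errors: "pd.Series"
    p_values: "pd.Series"
    log_likelihood: float
    converged: bool
    separation: bool = False
    note: str = ""


def aggregate_features(
    df: pd.DataFrame,
    feature_cols: Sequence[str],
    *,
    planes: Sequence[str] = ("coronal", "sagittal", "transversal"),
) -> pd.DataFrame:
    """Collapse per-image rows into per-patient, per-section feature means.

    Input is tidy: one row per image with ``patient_id``, ``plane`` and the
    feature columns.  Output has one row per patient per section, where the
    sections are the three planes plus ``average`` = mean of the plane
    means.  A patient missing a plane gets NaN in that plane's rows and in
    ``average`` (with a warning), so missingness propagates instead of
    silently reweighting.
    """
    if df.empty:
        raise ValidationError("no image rows to aggregate")
    missing = set(("patient_id", "plane")) - set(df.columns)
    if missing:
        raise ValidationError(f"missing required columns: {sorted(missing)}")
    plane_means = (
        df.groupby(["patient_id", "plane"], sort=True)[list(feature_cols)]
        .mean()
        .reset_index()
    )
    wide = plane_means.pivot(index="patient_id", columns="plane", values=list(feature_cols))
    rows = []
    for pid in wide.index:
        present = {p for p in planes if (feature_cols[0], p) in wide.columns
                   and not pd.isna(wide.loc[pid, (feature_cols[0], p)])}
        if len(present) < len(planes):
            warnings.warn(
                f"patient {pid} has planes {sorted(present)} only; "
                "three-plane average recorded as missing",
                stacklevel=2,
            )
        for section in list(planes) + ["average"]:
            row = {"patient_id": pid, "section": section}
            for feat in feature_cols:
                if section == "average":
                    vals = [
                        wide.loc[pid, (feat, p)] if (feat, p) in wide.columns else np.nan
                        for p in planes
                    ]
                    row[feat] = float(np.mean(vals))  # NaN propagates
                else:
                    row[feat] = (
                        float(wide.loc[pid, (feat, section)])
                        if (feat, section) in wide.columns
                        else np.nan
                    )
            rows.append(row)
    return pd.DataFrame(rows)


def auc_continuous(values, labels) -> float:
    """Mann-Whitney AUC of poor (positive) vs good responders, ties 1/2."""
    values = np.asarray(values, dtype=float)
    pos = _as_labels(labels)
    if values.shape != pos.shape:
        raise ValidationError("values and labels must have equal length")
    n_pos, n_neg = int(pos.sum()), int((~pos).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValidationError("both responder classes must be non-empty")
    ranks = sps.rankdata(values)
    u = ranks[pos].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def bootstrap_bias_corrected(
    values,
    labels,
    n_boot: int = 1000,
    alpha: float = 0.05,
    seed: int = 0,
) -> RocSummary:
    """Stratified bootstrap of the AUC with a bias-shifted percentile CI.

    Resampling is with replacement within each responder class, so every
    replicate keeps both classes.  The raw CI is the (alpha/2, 1-alpha/2)
    percentile interval of the bootstrap AUCs; the bias estimate is
    ``mean(bootstrap AUC) - observed AUC`` and the corrected CI is the raw
    interval shifted by ``-bias`` and clipped to [0, 1].
    """
    values = np.asarray(values, dtype=float)
    pos = _as_labels(labels)
    if n_boot < 200:
        raise ValidationError("n_boot must be at least 200")
    if pos.sum() < 2 or (~pos).sum() < 2:
        raise ValidationError("each responder class needs at least 2 members")
    observed = auc_continuous(values, pos)
    rng = np.random.default_rng(seed)
    pos_vals = values[pos]
    neg_vals = values[~pos]
    n_p, n_g = pos_vals.size, neg_vals.size
    boot = np.empty(n_boot, dtype=float)
    lab = np.concatenate([np.ones(n_p, dtype=bool), np.zeros(n_g, dtype=bool)])
    for b in range(n_boot):
        sample = np.concatenate(
            [
                pos_vals[rng.integers(0, n_p, n_p)],
                neg_vals[rng.integers(0, n_g, n_g)],
            ]
        )
        boot[b] = auc_continuous(sample, lab)
    lo, hi = np.quantile(boot, [alpha / 2.0, 1.0 - alpha / 2.0])
    bias = float(boot.mean() - observed)
    corrected = (
        float(np.clip(lo - bias, 0.0, 1.0)),
        float(np.clip(hi - bias, 0.0, 1.0)),
    )
    return RocSummary(
        auc=observed,
        ci_raw=(float(lo), float(hi)),
        bias=bias,
        ci_corrected=corrected,
        n_boot=n_boot,
        seed=seed,
    )


def _chi_square_2x2(pred: np.ndarray, pos: np.ndarray) -> float:
    """Pearson chi-square (no continuity correction) of predicted vs actual."""
    a = float(np.sum(pred & pos))
    b = float(np.sum(pred & ~pos))
    c = float(np.sum(~pred & pos))
    d = float(np.sum(~pred & ~pos))
    n = a + b + c + d
    denom = (a + b) * (c + d) * (a + c) * (b + d)
    if denom == 0:
        return 0.0
    return n * (a * d - b * c) ** 2 / denom


def optimal_threshold(values, labels, feature: str = "feature") -> ThresholdRule:
    """Exhaustive chi-square-maximizing cutpoint over midpoints of the
    sorted distinct values.

    Ties are broken toward the more balanced split, then the smaller
    cutpoint.  The rule's direction points toward the side with the higher
    poor-responder fraction.
    """
    values = np.asarray(values, dtype=float)
    pos = _as_labels(labels)
    if pos.all() or not pos.any():
        raise ValidationError("both responder classes must be present")
    distinct = np.unique(values)
    if distinct.size < 2:
        raise ValidationError("need at least 2 distinct values to place a cutpoint")
    n = values.size
    best = None  # (chi2, -balance_gap, -cut) maximized
    for cut in (distinct[:-1] + distinct[1:]) / 2.0:
        above = values > cut
        chi2 = _chi_square_2x2(above, pos)
        balance_gap = abs(int(above.sum()) - n / 2.0)
        key = (chi2, -balance_gap, -cut)
        if best is None or key > best[0]:
            best = (key, cut, above)
    _, cut, above = best
    rate_above = pos[above].mean() if above.any() else 0.0
    rate_below = pos[~above].mean() if (~above).any() else 0.0
    direction = (
        "greater_is_positive" if rate_above >= rate_below else "lesser_is_positive"
    )
    chi2 = best[0][0]
    return ThresholdRule(
        feature=feature,
        cutpoint=float(cut),
        direction=direction,
        chi_square=float(chi2),
        p_value=float(sps.chi2.sf(chi2, df=1)),
    )


def classification_accuracy(rule: ThresholdRule, values, labels) -> float:
    """Percentage of patients whose categorized prediction matches the label."""
    pos = _as_labels(labels)
    pred = rule.apply(values)
    return float(100.0 * np.mean(pred == pos))


def fit_logistic(
    design: pd.DataFrame | np.ndarray,
    labels,
    *,
    add_intercept: bool = True,
    maxiter: int = 100,
) -> LogisticModel:
    """Maximum-likelihood binary logistic fit with Wald p-values.

    Complete separation is detected (via statsmodels' check and divergent
    coefficient norms) and flagged on the returned model together with an
    explicit warning; a non-converged fit is flagged, never silent.
    """
    X = pd.DataFrame(design).copy()
    X.columns = [str(c) for c in X.columns]
    y = _as_labels(labels).astype(float)
    if len(X) != y.size:
        raise ValidationError("design and labels must have equal length")
    if len(X) <= X.shape[1] + int(add_intercept):
        raise ValidationError("need more observations than parameters")
    nunique = X.nunique()
    if (nunique <= 1).any():
        raise ValidationError(
            f"constant columns in design: {list(nunique[nunique <= 1].index)}"
        )
    if add_intercept:
        X = sm.add_constant(X, has_constant="add")
    separation = False
    converged = False
    note = ""
    failure: Exception | None = None
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        try:
            res = sm.Logit(y, X.astype(float)).fit(disp=0, maxiter=maxiter)
        except (PerfectSeparationError, np.linalg.LinAlgError) as exc:
            failure = exc
    if failure is not None:
        # a singular Hessian on binary data is the separation signature
        warnings.warn(f"logistic fit shows separation: {failure}", stacklevel=2)
        nan = pd.Series(np.nan, index=X.columns)
        return LogisticModel(
            included=[c for c in X.columns if c != "const"],
            coefficients=nan,
            std_errors=nan,
            p_values=nan,
            log_likelihood=math.nan,
            converged=False,
            separation=True,
            note=str(failure),
        )
    for w in caught:
        if issubclass(w.category, PerfectSeparationWarning):
            separation = True
            note = str(w.message)
        elif issubclass(w.category, ConvergenceWarning):
            note = str(w.message)
    converged = bool(res.mle_retvals.get("converged", False))
    # huge coefficients with exploding SEs are the practical separation signature
    if not separation and np.abs(res.params.values).max() > 1e3:
        separation = True
        note = note or "divergent coefficients suggest (quasi-)separation"
    if separation:
        warnings.warn(
            f"logistic fit shows separation: {note}", stacklevel=2
        )
    return LogisticModel(
        included=[c for c in X.columns if c != "const"],
        coefficients=res.params,
        std_errors=res.bse,
        p_values=res.pvalues,
        log_likelihood=float(res.llf),
        converged=converged,
        separation=separation,
        note=note,
    )


def _wald_p(candidates: pd.DataFrame, labels, cols: list[str], target: str) -> float:
    """Wald p-value of ``target`` in a logistic model containing ``cols``."""
    try:
        model = fit_logistic(candidates[cols], labels)
    except ValidationError:
        return 1.0
    p = model.p_values.get(target, np.nan)
    return 1.0 if not np.isfinite(p) else float(p)


def stepwise_selection(
    candidates: pd.DataFrame,
    labels,
    p_enter: float = 0.10,
    p_stay: float = 0.05,
) -> LogisticModel:
    """Forward-selection / backward-elimination logistic regression.

    Candidates (already categorized by their threshold rules, or continuous
    covariates) are first screened univariably; those with Wald P below
    ``p_enter`` are eligible.  The best-p eligible candidate is added
    iteratively, and after every addition any included term with P at or
    above ``p_stay`` is removed.  Candidates collinear with the current
    model (|r| = 1 with an included column) are skipped.  An empty final
    model is a valid outcome, returned with a note.
    """
    if candidates.shape[1] == 0:
        raise ValidationError("need at least one candidate")
    candidates = pd.DataFrame(candidates).astype(float)
    candidates.columns = [str(c) for c in candidates.columns]
    y = _as_labels(labels)

    screened = [
        c
        for c in candidates.columns
        if candidates[c].nunique() > 1 and _wald_p(candidates, y, [c], c) < p_enter
    ]
    included: list[str] = []
    seen_states: set[frozenset] = {frozenset()}
    changed = True
    while changed:
        changed = False
        best_c, best_p = None, p_enter
        for c in screened:
            if c in included:
                continue
            if included:
                corr = candidates[included].corrwith(candidates[c]).abs()
                if (corr > 1 - 1e-12).any():
                    continue  # collinearity guard
            p = _wald_p(candidates, y, included + [c], c)
            if p < best_p:
                best_c, best_p = c, p
        if best_c is not None:
            included.append(best_c)
            changed = True
        # backward elimination
        while included:
            ps = {c: _wald_p(candidates, y, included, c) for c in included}
            worst = max(ps, key=ps.get)
            if ps[worst] >= p_stay:
                included.remove(worst)
                changed = True
            else:
                break
        state = frozenset(included)
        if changed and state in seen_states:
            break  # add/remove cycle: the model state has recurred
        seen_states.add(state)
    if not included:
        empty = pd.Series(dtype=float)
        return LogisticModel(
            included=[],
            coefficients=empty,
            std_errors=empty,
            p_values=empty,
            log_likelihood=math.nan,
            converged=True,
            note="no candidate met the stay criterion; empty model",
        )
    return fit_logistic(candidates[included], y)


def spearman_correlation(x, y) -> float:
    """Spearman rank correlation (mid-ranks for ties); NaN when a rank
    variance is zero."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValidationError("need two equal-length samples of size >= 3")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValidationError("inputs must be finite")
    if np.unique(x).size < 2 or np.unique(y).size < 2:
        warnings.warn("zero rank variance; Spearman rho undefined", stacklevel=2)
        return math.nan
    rho, _ = sps.spearmanr(x, y)
    return float(rho)
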