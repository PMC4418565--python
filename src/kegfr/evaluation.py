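"""Statistical evaluation of DGF predictors.

Implements the discrimination and model-enhancement statistics used to
judge each biomarker or GFR estimate as a predictor of delayed graft
function (DGF): empirical ROC/AUC with DeLong covariance inference,
Youden-index operating points and diagnostic cutoff tables, logistic
augmentation of a clinical base risk score with integrated
discrimination improvement (IDI), risk assessment curves, Bland-Altman
agreement, Spearman correlation, and dialysis censoring of the analysis
set.

Directionality is always explicit: GFR-type predictors use
``lower_predicts_event`` (a failing graft filters less), raw marker
concentrations use ``higher_predicts_event``.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = [
    "RocResult",
    "IdiResult",
    "BlandAltmanResult",
    "censor_after_dialysis",
    "empirical_auc",
    "delong_variance_and_test",
    "youden_optimal_cutoff",
    "cutoff_table",
    "fit_augmented_model",
    "idi",
    "risk_assessment_curves",
    "bland_altman",
    "spearman_correlation",
]

logger = logging.getLogger(__name__)

Direction = Literal["higher_predicts_event", "lower_predicts_event"]

#: Ridge strength applied to non-intercept coefficients when a logistic
#: fit is separated or fails to converge.
SEPARATION_RIDGE = 1e-3


@dataclass(frozen=True)
class RocResult:
    """AUC with 95% CI (DeLong), direction, and the ROC curve itself."""

    auc: float
    ci_low: float
    ci_high: float
    direction: Direction
    curve: tuple[tuple[float, float], ...]  # (1-specificity, sensitivity)

    def __post_init__(self) -> None:
        if not (self.ci_low <= self.auc <= self.ci_high):
            raise ValueError("CI must bracket the AUC")


@dataclass(frozen=True)
class IdiResult:
    """Integrated discrimination improvement of an augmented risk model.

    ``idi_events`` is the mean predicted-risk increase among DGF cases,
    ``idi_nonevents`` the mean decrease among non-cases; their sum is
    the difference in discrimination slopes between new and base model.
    """

    idi_events: float
    idi_nonevents: float
    idi_events_ci: tuple[float, float]
    idi_nonevents_ci: tuple[float, float]
    auc_base: float
    auc_augmented: float
    p_auc_difference: float


@dataclass(frozen=True)
class BlandAltmanResult:
    bias: float
    loa_low: float
    loa_high: float
    pairs_used: int

    def __post_init__(self) -> None:
        if not (self.loa_low <= self.bias <= self.loa_high):
            raise ValueError("limits of agreement must bracket the bias")


# ---------------------------------------------------------------------------
# censoring

def censor_after_dialysis(data: pd.DataFrame, timepoint: float) -> pd.DataFrame:
    """Drop rows at/after ``timepoint`` for subjects already on dialysis.

    Dialysis resets marker concentrations, so a subject whose dialysis
    started at or before an analysis timepoint is excluded from that
    timepoint onward; earlier rows (and the subject's outcome label in
    them) are untouched. Idempotent.

    ``data`` needs columns ``timepoint_h`` and ``dialysis_time_h``
    (NaN = never dialysed).
    """
    dial = data["dialysis_time_h"]
    drop = dial.notna() & (dial <= timepoint) & (data["timepoint_h"] >= timepoint)
    out = data.loc[~drop].copy()
    if out.empty:
        logger.warning("censoring at %g h left an empty analysis set", timepoint)
    return out


# ---------------------------------------------------------------------------
# ROC / AUC

def _oriented(scores: np.ndarray, direction: Direction) -> np.ndarray:
    if direction == "higher_predicts_event":
        return scores
    if direction == "lower_predicts_event":
        return -scores
    raise ValueError(f"unknown direction {direction!r}")


def _validate_labels(labels: np.ndarray) -> None:
    if labels.all() or (~labels).all():
        raise ValueError("both event and non-event labels are required")


def _mann_whitney_auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """AUC as the midrank Mann-Whitney statistic (ties count 1/2)."""
    ranks = stats.rankdata(scores)
    n1 = int(labels.sum())
    n0 = labels.size - n1
    u = ranks[labels].sum() - n1 * (n1 + 1) / 2.0
    return float(u / (n1 * n0))


def _roc_points(scores: np.ndarray, labels: np.ndarray):
    """Monotone ROC curve from (0,0) to (1,1), higher score = event."""
    order = np.argsort(-scores, kind="mergesort")
    s, y = scores[order], labels[order]
    # collapse ties on score
    distinct = np.r_[np.diff(s) != 0, True]
    tps = np.cumsum(y)[distinct]
    fps = np.cumsum(~y)[distinct]
    sens = np.r_[0.0, tps / tps[-1]]
    fpr = np.r_[0.0, fps / fps[-1]]
    return tuple(zip(fpr.tolist(), sens.tolist()))


def empirical_auc(
    scores: Sequence[float],
    labels: Sequence[bool],
    direction: Direction = "higher_predicts_event",
) -> RocResult:
    """Empirical ROC AUC with a DeLong 95% confidence interval.

    The AUC is the probability a random event outranks a random
    non-event (midrank convention for ties). ``lower_predicts_event``
    negates the scores first.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    if not np.isfinite(scores).all():
        raise ValueError("scores must be finite")
    _validate_labels(labels)
    s = _oriented(scores, direction)
    auc = _mann_whitney_auc(s, labels)
    var = _delong_variance(s, labels)
    half = 1.959963984540054 * np.sqrt(max(var, 0.0))
    return RocResult(
        auc=auc,
        ci_low=max(auc - half, 0.0),
        ci_high=min(auc + half, 1.0),
        direction=direction,
        curve=_roc_points(s, labels),
    )


def _placements(scores: np.ndarray, labels: np.ndarray):
    """DeLong placement values V10 (per event) and V01 (per non-event)."""
    x = scores[labels]
    y = scores[~labels]
    # pairwise comparison matrix: 1 if event > non-event, 0.5 ties
    cmp = (x[:, None] > y[None, :]).astype(float)
    cmp += 0.5 * (x[:, None] == y[None, :])
    return cmp.mean(axis=1), cmp.mean(axis=0)


def _delong_variance(scores: np.ndarray, labels: np.ndarray) -> float:
    v10, v01 = _placements(scores, labels)
    m, n = v10.size, v01.size
    s10 = v10.var(ddof=1) if m > 1 else 0.0
    s01 = v01.var(ddof=1) if n > 1 else 0.0
    return s10 / m + s01 / n


def delong_variance_and_test(
    scores_a: Sequence[float],
    scores_b: Sequence[float],
    labels: Sequence[bool],
) -> dict:
    """Paired DeLong comparison of two predictors on the same subjects.

    Returns a dict with each AUC and its 95% CI, the AUC difference
    (a − b), its standard error, and the two-sided p-value from the
    normal approximation. Identical score vectors give difference 0,
    p = 1.
    """
    a = np.asarray(scores_a, dtype=float)
    b = np.asarray(scores_b, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    if a.shape != b.shape or a.shape != labels.shape:
        raise ValueError("scores_a, scores_b and labels must be aligned")
    _validate_labels(labels)

    v10a, v01a = _placements(a, labels)
    v10b, v01b = _placements(b, labels)
    auc_a, auc_b = v10a.mean(), v10b.mean()
    m, n = v10a.size, v01a.size

    def cov(u, v, size):
        if size < 2:
            return 0.0
        return np.cov(u, v, ddof=1)[0, 1]

    var_a = _delong_variance(a, labels)
    var_b = _delong_variance(b, labels)
    cov_ab = cov(v10a, v10b, m) / m + cov(v01a, v01b, n) / n
    var_diff = var_a + var_b - 2 * cov_ab

    diff = auc_a - auc_b
    if np.allclose(a, b) or var_diff <= 0:
        se_diff = 0.0
        p = 1.0 if np.isclose(diff, 0.0) else 0.0
    else:
        se_diff = float(np.sqrt(var_diff))
        z = diff / se_diff
        p = float(2 * stats.norm.sf(abs(z)))

    z95 = 1.959963984540054

    def ci(auc, var):
        half = z95 * np.sqrt(max(var, 0.0))
        return (max(auc - half, 0.0), min(auc + half, 1.0))

    return {
        "auc_a": float(auc_a),
        "auc_b": float(auc_b),
        "ci_a": ci(auc_a, var_a),
        "ci_b": ci(auc_b, var_b),
        "auc_difference": float(diff),
        "se_difference": se_diff,
        "p_value": p,
    }


# ---------------------------------------------------------------------------
# cutoffs

def _threshold_grid(s: np.ndarray) -> np.ndarray:
    """Candidate cutpoints: midpoints between distinct sorted scores plus
    sentinels below/above the range (n+1 positions for n distinct)."""
    u = np.unique(s)
    mids = (u[:-1] + u[1:]) / 2.0
    lo = u[0] - 1.0
    hi = u[-1] + 1.0
    return np.r_[lo, mids, hi]


def _sens_spec(s: np.ndarray, labels: np.ndarray, thr: float):
    pos = s >= thr
    sens = (pos & labels).sum() / labels.sum()
    spec = (~pos & ~labels).sum() / (~labels).sum()
    return sens, spec


def youden_optimal_cutoff(
    scores: Sequence[float],
    labels: Sequence[bool],
    direction: Direction = "higher_predicts_event",
) -> tuple[float, float, float]:
    """Cutoff maximizing the Youden index (sensitivity + specificity − 1).

    All n+1 threshold positions over the observed scores are scanned;
    ties are broken toward higher sensitivity. The reported cutoff is
    the midpoint between the adjacent distinct scores it separates,
    expressed on the original score scale.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    _validate_labels(labels)
    s = _oriented(scores, direction)

    best = None
    for thr in _threshold_grid(s):
        sens, spec = _sens_spec(s, labels, thr)
        j = sens + spec - 1.0
        if best is None or j > best[0] + 1e-12 or (
            abs(j - best[0]) <= 1e-12 and sens > best[1]
        ):
            best = (j, sens, spec, thr)
    _, sens, spec, thr = best
    cutoff = thr if direction == "higher_predicts_event" else -thr
    return float(cutoff), float(sens), float(spec)


def cutoff_table(
    scores: Sequence[float],
    labels: Sequence[bool],
    direction: Direction = "higher_predicts_event",
    prevalence: float | None = None,
) -> pd.DataFrame:
    """Diagnostic table at three operating points.

    Rows: threshold nearest 90% sensitivity, the Youden-optimal
    threshold, and the threshold nearest 90% specificity; columns
    cutoff, sensitivity, specificity, PPV and NPV (computed at the
    observed prevalence unless one is supplied).
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    _validate_labels(labels)
    s = _oriented(scores, direction)
    prev = float(labels.mean()) if prevalence is None else float(prevalence)

    grid = _threshold_grid(s)
    rows = [(_sens_spec(s, labels, thr) + (thr,)) for thr in grid]
    sens = np.array([r[0] for r in rows])
    spec = np.array([r[1] for r in rows])
    thrs = np.array([r[2] for r in rows])

    def pick_nearest(target: np.ndarray, aux: np.ndarray) -> int:
        # nearest to 0.9 on `target`; among ties prefer higher `aux`
        d = np.abs(target - 0.9)
        candidates = np.flatnonzero(np.isclose(d, d.min()))
        return candidates[np.argmax(aux[candidates])]

    j = sens + spec - 1.0
    youden_candidates = np.flatnonzero(np.isclose(j, j.max()))
    i_youden = youden_candidates[np.argmax(sens[youden_candidates])]
    picks = {
        "sens90": pick_nearest(sens, spec),
        "youden": i_youden,
        "spec90": pick_nearest(spec, sens),
    }

    records = []
    for name, i in picks.items():
        se, sp = sens[i], spec[i]
        denom_ppv = se * prev + (1 - sp) * (1 - prev)
        denom_npv = (1 - se) * prev + sp * (1 - prev)
        ppv = se * prev / denom_ppv if denom_ppv > 0 else np.nan
        npv = sp * (1 - prev) / denom_npv if denom_npv > 0 else np.nan
        cutoff = thrs[i] if direction == "higher_predicts_event" else -thrs[i]
        records.append(
            {
                "operating_point": name,
                "cutoff": float(cutoff),
                "sensitivity": float(se),
                "specificity": float(sp),
                "ppv": float(ppv),
                "npv": float(npv),
            }
        )
    return pd.DataFrame.from_records(records)


# ---------------------------------------------------------------------------
# logistic augmentation and IDI

def _logit(p: np.ndarray) -> np.ndarray:
    p = np.clip(p, 1e-12, 1 - 1e-12)
    return np.log(p / (1 - p))


def _expit(z: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-np.clip(z, -500, 500)))


def _fit_logistic(X: np.ndarray, y: np.ndarray, ridge: float = 0.0) -> np.ndarray:
    """Maximum-likelihood logistic fit (optional ridge on non-intercept
    coefficients) via L-BFGS on the exact gradient."""

    def nll_grad(beta):
        eta = X @ beta
        p = _expit(eta)
        # log-likelihood via log1p for stability
        ll = np.sum(y * eta - np.logaddexp(0.0, eta))
        grad = X.T @ (y - p)
        if ridge > 0:
            ll -= 0.5 * ridge * np.sum(beta[1:] ** 2)
            grad = grad - ridge * np.r_[0.0, beta[1:]]
        return -ll, -grad

    beta0 = np.zeros(X.shape[1])
    res = optimize.minimize(nll_grad, beta0, jac=True, method="L-BFGS-B")
    if not res.success and ridge == 0.0:
        raise RuntimeError(f"logistic fit failed: {res.message}")
    return res.x


def _separated(X: np.ndarray, beta: np.ndarray, y: np.ndarray) -> bool:
    p = _expit(X @ beta)
    return bool(np.all((p > 0.5) == y) and (np.abs(beta[1:]).max() > 30))


def fit_augmented_model(
    base_risk: Sequence[float],
    biomarker: Sequence[float] | None,
    labels: Sequence[bool],
    base_mode: Literal["recalibrate", "offset"] = "recalibrate",
) -> tuple[np.ndarray, np.ndarray]:
    """Fit the base and biomarker-augmented DGF risk models.

    The clinical score enters as a logit(base_risk) covariate and is
    refit in-sample (``recalibrate``); with ``offset`` it is carried as
    a fixed offset instead. The augmented model adds the biomarker as a
    second covariate. Returns the fitted probability vectors
    ``(p_base, p_new)``; when ``biomarker`` is None only the base model
    is fitted and ``p_new = p_base``.

    Quasi-separated fits are retried with a small ridge penalty
    (``SEPARATION_RIDGE``) on the non-intercept coefficients.
    """
    base_risk = np.asarray(base_risk, dtype=float)
    y = np.asarray(labels, dtype=bool)
    _validate_labels(y)
    if np.any((base_risk <= 0) | (base_risk >= 1)):
        raise ValueError("base_risk must lie strictly inside (0, 1)")
    z = _logit(base_risk)
    yf = y.astype(float)

    def fit_predict(X: np.ndarray) -> np.ndarray:
        try:
            beta = _fit_logistic(X, yf)
            if _separated(X, beta, y):
                raise RuntimeError("separation")
        except RuntimeError:
            logger.warning(
                "logistic fit separated/non-converged; refitting with ridge %g",
                SEPARATION_RIDGE,
            )
            beta = _fit_logistic(X, yf, ridge=SEPARATION_RIDGE)
        return _expit(X @ beta)

    n = base_risk.size
    ones = np.ones(n)

    if base_mode == "recalibrate":
        X_base = np.column_stack([ones, z])
        p_base = fit_predict(X_base)
        if biomarker is None:
            return p_base, p_base
        x = np.asarray(biomarker, dtype=float)
        if np.any(~np.isfinite(x)):
            raise ValueError("biomarker values must be finite")
        X_new = np.column_stack([ones, z, x])
        p_new = fit_predict(X_new)
    elif base_mode == "offset":
        p_base = base_risk.copy()
        if biomarker is None:
            return p_base, p_base
        x = np.asarray(biomarker, dtype=float)
        # model: logit(p) = z + a + b*x  (z fixed offset)
        def fit_offset():
            def nll_grad(beta):
                eta = z + beta[0] + beta[1] * x
                p = _expit(eta)
                ll = np.sum(yf * eta - np.logaddexp(0.0, eta))
                g = np.array([np.sum(yf - p), np.sum((yf - p) * x)])
                return -ll, -g

            res = optimize.minimize(
                nll_grad, np.zeros(2), jac=True, method="L-BFGS-B"
            )
            return res.x

        beta = fit_offset()
        p_new = _expit(z + beta[0] + beta[1] * x)
    else:
        raise ValueError(f"unknown base_mode {base_mode!r}")
    return p_base, p_new


def idi(
    p_base: Sequence[float],
    p_new: Sequence[float],
    labels: Sequence[bool],
    n_bootstrap: int = 2000,
    seed: int | None = None,
    refit_inputs: tuple[Sequence[float], Sequence[float]] | None = None,
    ci_method: Literal["bootstrap", "pencina"] = "bootstrap",
    base_mode: Literal["recalibrate", "offset"] = "recalibrate",
) -> IdiResult:
    """Integrated discrimination improvement of the augmented model.

    ``idi_events`` = mean(p_new − p_base | event); ``idi_nonevents`` =
    mean(p_base − p_new | non-event). Confidence intervals come from a
    seeded subject-level bootstrap (percentile); when ``refit_inputs``
    = (base_risk, biomarker) is given, both models are refit inside
    each resample, otherwise the stored probabilities are resampled
    directly. ``ci_method='pencina'`` uses the analytic paired-t SE
    instead. ``n_bootstrap=0`` skips interval estimation (NaN bounds).
    """
    p_base = np.asarray(p_base, dtype=float)
    p_new = np.asarray(p_new, dtype=float)
    y = np.asarray(labels, dtype=bool)
    _validate_labels(y)

    def components(pb, pn, yy):
        ev = np.mean(pn[yy] - pb[yy])
        ne = np.mean(pb[~yy] - pn[~yy])
        return float(ev), float(ne)

    idi_ev, idi_ne = components(p_base, p_new, y)

    roc = delong_variance_and_test(p_new, p_base, y)
    auc_base, auc_new, p_diff = roc["auc_b"], roc["auc_a"], roc["p_value"]

    nan_ci = (float("nan"), float("nan"))
    ev_ci, ne_ci = nan_ci, nan_ci
    if ci_method == "pencina":
        d = p_new - p_base
        se_ev = stats.sem(d[y]) if y.sum() > 1 else np.nan
        se_ne = stats.sem(-d[~y]) if (~y).sum() > 1 else np.nan
        z95 = 1.959963984540054
        ev_ci = (idi_ev - z95 * se_ev, idi_ev + z95 * se_ev)
        ne_ci = (idi_ne - z95 * se_ne, idi_ne + z95 * se_ne)
    elif n_bootstrap > 0:
        if seed is None:
            raise ValueError("bootstrap CIs require an explicit seed")
        rng = np.random.default_rng(seed)
        n = y.size
        evs, nes = [], []
        for _ in range(n_bootstrap):
            idx = rng.integers(0, n, size=n)
            yy = y[idx]
            if yy.all() or (~yy).all():
                continue
            if refit_inputs is not None:
                br = np.asarray(refit_inputs[0], dtype=float)[idx]
                bm = np.asarray(refit_inputs[1], dtype=float)[idx]
                try:
                    pb, pn = fit_augmented_model(br, bm, yy, base_mode=base_mode)
                except (RuntimeError, ValueError):
                    continue
            else:
                pb, pn = p_base[idx], p_new[idx]
            ev, ne = components(pb, pn, yy)
            evs.append(ev)
            nes.append(ne)
        if evs:
            ev_ci = tuple(np.percentile(evs, [2.5, 97.5]))
            ne_ci = tuple(np.percentile(nes, [2.5, 97.5]))

    return IdiResult(
        idi_events=idi_ev,
        idi_nonevents=idi_ne,
        idi_events_ci=ev_ci,
        idi_nonevents_ci=ne_ci,
        auc_base=auc_base,
        auc_augmented=auc_new,
        p_auc_difference=p_diff,
    )


def risk_assessment_curves(
    p: Sequence[float],
    labels: Sequence[bool],
    n_grid: int = 101,
) -> dict[str, np.ndarray]:
    """Risk assessment plot data for a fitted probability vector.

    For each risk threshold r on a uniform [0, 1] grid: sensitivity
    (share of events with p ≥ r) and 1 − specificity (share of
    non-events with p ≥ r). Both curves are non-increasing in r.
    """
    p = np.asarray(p, dtype=float)
    y = np.asarray(labels, dtype=bool)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("probabilities must lie in [0, 1]")
    r = np.linspace(0.0, 1.0, n_grid)
    ge = p[None, :] >= r[:, None]
    sens = ge[:, y].mean(axis=1) if y.any() else np.full(n_grid, np.nan)
    one_minus_spec = (
        ge[:, ~y].mean(axis=1) if (~y).any() else np.full(n_grid, np.nan)
    )
    return {"risk": r, "sensitivity": sens, "one_minus_specificity": one_minus_spec}


# ---------------------------------------------------------------------------
# agreement and correlation

def bland_altman(x: Sequence[float], y: Sequence[float]) -> BlandAltmanResult:
    """Bland-Altman bias and 95% limits of agreement for paired methods.

    bias = mean(x − y); limits = bias ∓ 1.96 × sample SD of the paired
    differences.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("paired vectors must have equal length")
    if x.size < 2:
        raise ValueError("at least two pairs are required")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("pairs must be finite")
    d = x - y
    bias = float(d.mean())
    sd = float(d.std(ddof=1))
    return BlandAltmanResult(
        bias=bias,
        loa_low=bias - 1.96 * sd,
        loa_high=bias + 1.96 * sd,
        pairs_used=int(x.size),
    )


def spearman_correlation(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Spearman rank correlation with midranks for ties; two-sided p via
    the t approximation."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size < 3:
        raise ValueError("at least three complete pairs are required")
    if np.unique(x).size < 2 or np.unique(y).size < 2:
        raise ValueError("correlation undefined for a constant vector")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        rho, p = stats.spearmanr(x, y)
    return float(rho), float(p)
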