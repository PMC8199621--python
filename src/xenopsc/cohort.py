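"""Cohort statistics for the 2x2 factorial adjuvant-treatment model.

Rare-cell counts are adjusted to counts per low-powered field per 200 uL of
blood and modelled by Poisson regression with heteroscedasticity-consistent
(sandwich, HC0) standard errors; progressive disease by logistic
regression; longitudinal tumour burden (log10 ventral radiant flux) by a
random-intercept linear mixed model with treatment x week interactions.
Tumour doubling time in days follows from the weekly log10 slope as
``7 * log10(2) / slope``.  ROC analysis of rare-cell counts against
recurrence uses the midrank (Mann-Whitney) AUC with a DeLong confidence
interval.
"""

from __future__ import annotations

import warnings
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.stats
import statsmodels.api as sm
import statsmodels.formula.api as smf

from .io_formats import AnimalRecord, FluxSeries, cohort_to_frame, flux_to_frame


def adjust_rare_cell_count(raw: float, n_lpf: float, volume_ul: float) -> float:
    """Adjusted rare-cell count per low-powered field per 200 uL of blood."""
    if volume_ul <= 0:
        raise ValueError("volume must be positive")
    if n_lpf < 1:
        raise ValueError("n_lpf must be >= 1")
    if raw < 0:
        raise ValueError("raw count must be non-negative")
    return raw / n_lpf / (volume_ul / 200.0)


def tumour_volume(length_mm: float, width_mm: float, height_mm: float) -> float:
    """Resected tumour volume in mm^3: half the dimension product."""
    if min(length_mm, width_mm, height_mm) <= 0:
        raise ValueError("tumour dimensions must be positive")
    return 0.5 * length_mm * width_mm * height_mm


def _design(df: pd.DataFrame, covariates: Sequence[str]) -> np.ndarray:
    x = sm.add_constant(df[list(covariates)].to_numpy(dtype=float), has_constant="add")
    rank = np.linalg.matrix_rank(x)
    if rank < x.shape[1]:
        corr = np.corrcoef(x[:, 1:].T)
        aliased = [covariates[i] for i in range(len(covariates))
                   if np.any(np.triu(np.abs(corr) > 0.999, 1)[i])]
        raise ValueError(f"design matrix is rank deficient (aliased: {aliased})")
    return x


def fit_count_model(
    records: Sequence[AnimalRecord],
    outcome: str = "ctc",
    covariates: Sequence[str] = ("G", "HiCi", "last_log10_flux"),
) -> dict:
    """Poisson regression of raw rare-cell counts with robust (HC0) SEs.

    The exposure offset ``log(n_lpf * volume / 200)`` makes the linear
    predictor the log rate per LPF per 200 uL, so exponentiated
    coefficients are rate ratios on the adjusted-count scale.  Wald 95%
    confidence intervals use the sandwich variance.
    """
    if outcome not in ("ctc", "cpsc"):
        raise ValueError("outcome must be 'ctc' or 'cpsc'")
    if len(records) < 10:
        raise ValueError("need at least 10 records")
    df = cohort_to_frame(records)
    y = df[f"raw_{outcome}"].to_numpy(dtype=float)
    x = _design(df, covariates)
    exposure = (df["n_lpf"] * df["blood_volume_ul"] / 200.0).to_numpy()

    model = sm.GLM(y, x, family=sm.families.Poisson(), offset=np.log(exposure))
    try:
        res = model.fit(cov_type="HC0", maxiter=100)
    except Exception as exc:  # noqa: BLE001 - surfaced with diagnostics
        raise RuntimeError(f"Poisson fit failed: {exc}") from exc
    if not res.converged:
        raise RuntimeError("Poisson IRLS did not converge")

    names = ["intercept", *covariates]
    ci = res.conf_int()
    table = pd.DataFrame({
        "term": names,
        "coef": res.params,
        "robust_se": res.bse,
        "rate_ratio": np.exp(res.params),
        "rr_ci_low": np.exp(ci[:, 0]),
        "rr_ci_high": np.exp(ci[:, 1]),
        "p": res.pvalues,
    })
    return {"table": table, "result": res, "outcome": outcome}


def fit_progression_model(
    records: Sequence[AnimalRecord],
    covariates: Sequence[str] = ("G", "HiCi"),
    interaction_p_threshold: float = 0.1,
) -> dict:
    """Logistic regression of progressive disease on the treatment flags.

    The G x HiCi first-order interaction is fitted first and dropped when
    its p-value exceeds ``interaction_p_threshold`` (the pre-specified
    model-building rule for the 2x2 factorial design).  Returns odds ratios
    with Wald CIs.
    """
    df = cohort_to_frame(records)
    y = df["progressive"].to_numpy(dtype=float)
    if len(np.unique(y)) < 2:
        raise ValueError("both outcome classes must be present")

    use_interaction = {"G", "HiCi"} <= set(covariates)
    terms = list(covariates)
    if use_interaction:
        df["G_x_HiCi"] = df["G"] * df["HiCi"]
        x_int = _design(df, [*terms, "G_x_HiCi"])
        try:
            res_int = sm.Logit(y, x_int).fit(disp=0, maxiter=100)
            p_int = res_int.pvalues[-1]
        except Exception:
            p_int = np.nan
        if np.isfinite(p_int) and p_int <= interaction_p_threshold:
            terms = [*terms, "G_x_HiCi"]

    x = _design(df, terms)
    try:
        res = sm.Logit(y, x).fit(disp=0, maxiter=100)
    except Exception as exc:  # noqa: BLE001
        raise RuntimeError(
            "logistic fit failed (possible perfect separation; consider an "
            f"exact or penalised model): {exc}") from exc
    if np.any(np.abs(res.params) > 15):
        raise RuntimeError(
            "logistic fit suggests perfect separation; consider an exact or "
            "penalised model")

    names = ["intercept", *terms]
    ci = res.conf_int()
    table = pd.DataFrame({
        "term": names,
        "coef": res.params,
        "se": res.bse,
        "odds_ratio": np.exp(res.params),
        "or_ci_low": np.exp(ci[:, 0]),
        "or_ci_high": np.exp(ci[:, 1]),
        "p": res.pvalues,
    })
    return {"table": table, "result": res, "interaction_kept": "G_x_HiCi" in terms}


def fit_longitudinal_flux(
    series: Sequence[FluxSeries],
    records: Sequence[AnimalRecord],
    set_level_intercept: bool = False,
) -> dict:
    """Random-intercept mixed model of log10 flux over treatment weeks.

    Fixed effects: week and its interactions with G, HiCi and the centred
    baseline log10 flux (slope modifiers, in log10 fold-change per week);
    random intercept per animal, fitted by maximum likelihood.  A singular
    random-effect variance triggers an OLS refit with a warning.  With
    ``set_level_intercept`` an additional variance component at the animal
    *set* level accounts for set-level clustering.
    """
    rec_df = cohort_to_frame(records).set_index("animal_id")
    df = flux_to_frame(series)
    df = df.join(rec_df[["G", "HiCi", "set_id"]], on="animal_id")
    df["baseline_c"] = df["baseline_log10_flux"] - df["baseline_log10_flux"].mean()
    df["week_G"] = df["week"] * df["G"]
    df["week_HiCi"] = df["week"] * df["HiCi"]
    df["week_baseline"] = df["week"] * df["baseline_c"]

    formula = "log10_flux ~ week + week_G + week_HiCi + week_baseline"
    fallback = False
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            if set_level_intercept:
                model = smf.mixedlm(formula, df, groups=df["set_id"],
                                    re_formula="1",
                                    vc_formula={"animal": "0 + C(animal_id)"})
            else:
                model = smf.mixedlm(formula, df, groups=df["animal_id"])
            res = model.fit(reml=False)
            re_var = (float(np.asarray(res.cov_re).ravel()[0])
                      if res.cov_re.size else 0.0)
        except (np.linalg.LinAlgError, ValueError):
            res = None
            re_var = np.nan

    if res is None or not np.isfinite(re_var) or re_var < 1e-10:
        warnings.warn("singular random-intercept variance; refitting as OLS")
        res = smf.ols(formula, df).fit()
        re_var = 0.0
        fallback = True

    params = res.params
    fixed = {k: float(params[k]) for k in
             ("Intercept", "week", "week_G", "week_HiCi", "week_baseline")}
    return {"fixed_effects": fixed, "random_intercept_var": re_var,
            "result": res, "ols_fallback": fallback}


def doubling_time_from_slope(slope_log10_per_week: float) -> float | None:
    """Tumour-burden doubling time in days from a weekly log10 flux slope.

    Returns ``None`` for non-positive slopes (no doubling: non-progressing).
    """
    if slope_log10_per_week <= 0:
        return None
    return 7.0 * np.log10(2.0) / slope_log10_per_week


def slope_from_doubling_time(days: float) -> float:
    """Inverse of :func:`doubling_time_from_slope`."""
    if days <= 0:
        raise ValueError("doubling time must be positive")
    return 7.0 * np.log10(2.0) / days


def roc_curve(scores: np.ndarray, labels: np.ndarray) -> dict:
    """Empirical ROC with midrank AUC and DeLong 95% confidence interval.

    ``labels`` are binary (1 = positive, e.g. recurrence); ``scores`` are
    the test variable (e.g. adjusted CTC count).  Ties are handled by
    midranks, making the AUC identical to the Mann-Whitney U statistic
    divided by ``n_pos * n_neg``.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    if pos.size == 0 or neg.size == 0:
        raise ValueError("both classes must be present")

    # midrank AUC (Mann-Whitney)
    all_ranks = scipy.stats.rankdata(np.concatenate([pos, neg]))
    r_pos = all_ranks[:pos.size]
    auc = (r_pos.sum() - pos.size * (pos.size + 1) / 2) / (pos.size * neg.size)

    # DeLong structural components
    v_pos = np.array([(np.sum(p > neg) + 0.5 * np.sum(p == neg)) / neg.size
                      for p in pos])
    v_neg = np.array([(np.sum(pos > n) + 0.5 * np.sum(pos == n)) / pos.size
                      for n in neg])
    var = (np.var(v_pos, ddof=1) / pos.size if pos.size > 1 else 0.0) + \
          (np.var(v_neg, ddof=1) / neg.size if neg.size > 1 else 0.0)
    se = np.sqrt(var)
    zcrit = scipy.stats.norm.ppf(0.975)
    ci = (float(np.clip(auc - zcrit * se, 0, 1)),
          float(np.clip(auc + zcrit * se, 0, 1)))

    # empirical curve over all thresholds
    thresholds = np.concatenate([[np.inf], np.unique(scores)[::-1]])
    points = [( float(np.mean(neg >= t)), float(np.mean(pos >= t)))
              for t in thresholds]
    return {"auc": float(auc), "ci95": ci, "se": float(se),
            "points": points, "n_pos": int(pos.size), "n_neg": int(neg.size)}
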