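"""Temporal statistics for lesion and edema volumes.

Per-lesion volume series are normalized to their earliest post-ablation
measurement, the temporal trend of normalized volume is estimated with a
linear mixed model (fixed time effect, random per-animal intercept, REML),
edema-to-lesion ratios are summarised per time interval, ROI T2 time courses
are tabulated, and method agreement is quantified with Bland-Altman and
correlation statistics.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger("rflesion")

# Non-contiguous analysis intervals (min post-ablation-start); observations in
# 25-60 min are deliberately not bridged into either interval.
DEFAULT_INTERVALS: tuple[tuple[float, float], ...] = (
    (0.0, 25.0), (60.0, 80.0), (80.0, 185.0))

__all__ = ["LMMFit", "AgreementResult", "CorrelationResult",
           "IntervalRatioResult", "DEFAULT_INTERVALS", "normalize_to_baseline",
           "fit_lmm", "predict_fixed", "interval_ratio", "roi_t2_timecourse",
           "bland_altman", "correlate", "simulate_lmm_study", "interval_of"]


@dataclass
class LMMFit:
    """Fixed and random effects of the normalized-volume mixed model."""

    intercept: float
    slope: float
    intercept_se: float
    slope_se: float
    intercept_p: float
    slope_p: float
    random_intercept_var: float
    residual_var: float
    n_groups: int
    n_obs: int
    converged: bool
    slope_ci: tuple[float, float]
    method: str = "reml"


@dataclass
class AgreementResult:
    """Bland-Altman summary of paired measurements."""

    bias: float
    sd_diff: float
    loa_low: float
    loa_high: float
    p_paired: float
    n: int


@dataclass
class CorrelationResult:
    r: float
    p: float
    method: str
    slope: float | None = None
    intercept: float | None = None
    defined: bool = True


@dataclass
class IntervalRatioResult:
    per_interval: pd.DataFrame      # interval, n, mean, sd, ci_low, ci_high, p_gt1
    pairs: pd.DataFrame             # lesion_id, interval, t_edema, t_lesion, ratio
    anova_p: float
    excluded_intervals: list = field(default_factory=list)


def interval_of(t_min: float, intervals=DEFAULT_INTERVALS):
    """Half-open interval (lo, hi] containing ``t_min``; None when in a gap."""
    for lo, hi in intervals:
        if lo < t_min <= hi:
            return (lo, hi)
    return None


def normalize_to_baseline(table: pd.DataFrame) -> pd.DataFrame:
    """Divide each (lesion, contrast) volume series by its earliest value.

    The baseline row is the minimum ``t_min`` per (lesion_id, contrast); ties
    are broken deterministically by row order (first occurrence) and logged.
    Baseline volumes must be positive.
    """
    df = table.copy()
    df["normalized_volume"] = np.nan
    for (lesion, contrast), grp in df.groupby(["lesion_id", "contrast"], sort=False):
        tmin = grp["t_min"].min()
        base_rows = grp.index[grp["t_min"] == tmin]
        if len(base_rows) > 1:
            logger.info("baseline tie for lesion %s/%s at t=%.1f; using first row",
                        lesion, contrast, tmin)
        base = df.loc[base_rows[0], "volume_mL"]
        if base <= 0:
            raise ValueError(f"zero/negative baseline volume for lesion "
                             f"{lesion} ({contrast})")
        df.loc[grp.index, "normalized_volume"] = grp["volume_mL"] / base
    return df


def fit_lmm(table: pd.DataFrame, contrast: str | None = None) -> LMMFit:
    """Random-intercept linear mixed model of normalized volume on time.

    y_it = b0 + b1 * t_it + u_i + e_it with u_i a per-animal intercept,
    estimated by REML (statsmodels MixedLM).  Requires at least two animals
    (grouping by a single animal is degenerate and refused) and at least
    three lesions.  Exactly linear noise-free input drives the residual
    variance to zero, where REML is undefined; such input short-circuits to
    the ordinary-least-squares solution with zero variance components.

    Raises
    ------
    ValueError
        On degenerate grouping or insufficient data.
    RuntimeError
        If the optimiser fails to converge (with diagnostics).
    """
    df = table if contrast is None else table[table["contrast"] == contrast]
    df = df.dropna(subset=["normalized_volume", "t_min"])
    n_groups = df["animal_id"].nunique()
    n_lesions = df["lesion_id"].nunique()
    if n_groups < 2:
        raise ValueError("random-intercept model needs >= 2 animals "
                         f"(got {n_groups}); grouping is degenerate")
    if n_lesions < 3:
        raise ValueError(f"need >= 3 lesions (got {n_lesions})")

    y = df["normalized_volume"].to_numpy(dtype=float)
    t = df["t_min"].to_numpy(dtype=float)
    X = np.column_stack([np.ones_like(t), t])

    # Degenerate exactly-linear data: REML blows up as residual variance -> 0.
    beta, res_ss, *_ = np.linalg.lstsq(X, y, rcond=None)
    ss_tot = float(((y - y.mean()) ** 2).sum())
    ss_res = float(res_ss[0]) if len(res_ss) else float(((X @ beta - y) ** 2).sum())
    if ss_res <= max(1e-12 * max(ss_tot, 1.0), 1e-20):
        logger.info("exactly linear input; returning OLS solution with zero "
                    "variance components")
        return LMMFit(intercept=float(beta[0]), slope=float(beta[1]),
                      intercept_se=0.0, slope_se=0.0,
                      intercept_p=0.0, slope_p=0.0,
                      random_intercept_var=0.0, residual_var=0.0,
                      n_groups=int(n_groups), n_obs=len(df), converged=True,
                      slope_ci=(float(beta[1]), float(beta[1])),
                      method="ols-degenerate")

    import statsmodels.api as sm
    model = sm.MixedLM(y, X, groups=df["animal_id"].to_numpy())
    fit = None
    errors = []
    for method in ("bfgs", "powell", "nm"):
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                cand = model.fit(reml=True, method=method)
        except Exception as exc:  # singular working matrices etc.
            errors.append(f"{method}: {exc}")
            continue
        if cand.converged:
            fit = cand
            break
        errors.append(f"{method}: did not converge")
    if fit is None:
        raise RuntimeError("mixed-model fit failed; diagnostics: "
                           + "; ".join(errors))
    ci = fit.conf_int()
    return LMMFit(
        intercept=float(fit.params[0]), slope=float(fit.params[1]),
        intercept_se=float(fit.bse[0]), slope_se=float(fit.bse[1]),
        intercept_p=float(fit.pvalues[0]), slope_p=float(fit.pvalues[1]),
        random_intercept_var=float(np.asarray(fit.cov_re)[0, 0]),
        residual_var=float(fit.scale),
        n_groups=int(n_groups), n_obs=len(df), converged=bool(fit.converged),
        slope_ci=(float(np.asarray(ci)[1, 0]), float(np.asarray(ci)[1, 1])))


def predict_fixed(fit: LMMFit, t_min: float) -> float:
    """Population-level prediction b0 + b1 * t (random effects at zero)."""
    return fit.intercept + fit.slope * t_min


def interval_ratio(edema: pd.DataFrame, lesion: pd.DataFrame,
                   intervals=DEFAULT_INTERVALS) -> IntervalRatioResult:
    """Edema-to-lesion volume ratios at matched time points, per interval.

    A pair forms when both contrasts of a lesion have an observation inside
    the same interval; the nearest-in-time observations are matched.  Per
    interval: mean, SD, 95% CI and a one-sided one-sample t-test of
    ratio > 1; across intervals: Welch ANOVA.  Intervals with fewer than two
    pairs are excluded and reported.
    """
    rows = []
    lesions = sorted(set(edema["lesion_id"]) & set(lesion["lesion_id"]))
    for lid in lesions:
        e = edema[edema["lesion_id"] == lid]
        l = lesion[lesion["lesion_id"] == lid]
        for lo, hi in intervals:
            ei = e[(e["t_min"] > lo) & (e["t_min"] <= hi)]
            li = l[(l["t_min"] > lo) & (l["t_min"] <= hi)]
            if ei.empty or li.empty:
                continue
            best = None
            for _, er in ei.iterrows():
                for _, lr in li.iterrows():
                    d = abs(er["t_min"] - lr["t_min"])
                    if best is None or d < best[0]:
                        best = (d, er, lr)
            _, er, lr = best
            if lr["volume_mL"] <= 0:
                continue
            rows.append({"lesion_id": lid, "interval": f"({lo:g},{hi:g}]",
                         "t_edema": er["t_min"], "t_lesion": lr["t_min"],
                         "ratio": er["volume_mL"] / lr["volume_mL"]})
    pairs = pd.DataFrame(rows, columns=["lesion_id", "interval", "t_edema",
                                        "t_lesion", "ratio"])

    summaries = []
    excluded = []
    for lo, hi in intervals:
        name = f"({lo:g},{hi:g}]"
        r = pairs.loc[pairs["interval"] == name, "ratio"].to_numpy()
        if len(r) < 2:
            excluded.append(name)
            logger.info("interval %s excluded from ratio analysis (%d pairs)",
                        name, len(r))
            continue
        mean, sd = float(r.mean()), float(r.std(ddof=1))
        sem = sd / np.sqrt(len(r))
        tcrit = stats.t.ppf(0.975, len(r) - 1)
        if sd > 0:
            p_gt1 = float(stats.ttest_1samp(r, 1.0, alternative="greater").pvalue)
        else:
            p_gt1 = 0.0 if mean > 1 else 1.0
        summaries.append({"interval": name, "n": len(r), "mean": mean, "sd": sd,
                          "ci_low": mean - tcrit * sem, "ci_high": mean + tcrit * sem,
                          "p_gt1": p_gt1})
    per_interval = pd.DataFrame(
        summaries, columns=["interval", "n", "mean", "sd", "ci_low", "ci_high",
                            "p_gt1"])

    anova_p = float("nan")
    used = per_interval["interval"].tolist()
    if len(used) >= 2:
        sub = pairs[pairs["interval"].isin(used)]
        if sub["ratio"].std(ddof=1) > 0:
            import pingouin as pg
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                aov = pg.welch_anova(data=sub, dv="ratio", between="interval")
            pcol = "p_unc" if "p_unc" in aov.columns else "p-unc"
            anova_p = float(aov[pcol].iloc[0])
    return IntervalRatioResult(per_interval=per_interval, pairs=pairs,
                               anova_p=anova_p, excluded_intervals=excluded)


def roi_t2_timecourse(measurements: pd.DataFrame,
                      intervals=DEFAULT_INTERVALS) -> dict:
    """Summarise ROI-mean T2 per region and interval with paired tests.

    ``measurements`` rows: (lesion_id, t_min, region, mean_t2) where region is
    one of healthy / lesion / edema measured in masks held fixed over time.
    Returns per-interval mean and SD per region, paired t-tests between
    consecutive intervals (paired by lesion), and healthy-vs-region paired
    tests per interval.  Lesions missing a map in an interval drop out of
    that interval for that region.
    """
    df = measurements.copy()
    df["interval"] = df["t_min"].map(lambda t: interval_of(t, intervals))
    df = df.dropna(subset=["interval"])
    df["interval"] = df["interval"].map(lambda iv: f"({iv[0]:g},{iv[1]:g}]")

    # one value per lesion/region/interval (mean over multiple maps)
    cell = (df.groupby(["region", "interval", "lesion_id"])["mean_t2"]
              .mean().reset_index())
    summary = (cell.groupby(["region", "interval"])["mean_t2"]
                   .agg(n="count", mean="mean", sd="std").reset_index())

    names = [f"({lo:g},{hi:g}]" for lo, hi in intervals]
    between = []
    for region, grp in cell.groupby("region"):
        wide = grp.pivot(index="lesion_id", columns="interval", values="mean_t2")
        for a, b in zip(names[:-1], names[1:]):
            if a not in wide or b not in wide:
                continue
            paired = wide[[a, b]].dropna()
            if len(paired) < 2 or np.allclose(paired[a], paired[b]):
                p = float("nan") if len(paired) < 2 else 1.0
            else:
                p = float(stats.ttest_rel(paired[a], paired[b]).pvalue)
            between.append({"region": region, "interval_a": a, "interval_b": b,
                            "n": len(paired), "p": p})

    vs_healthy = []
    wide_all = cell.pivot_table(index=["lesion_id", "interval"], columns="region",
                                values="mean_t2").reset_index()
    for region in sorted(set(cell["region"]) - {"healthy"}):
        if region not in wide_all or "healthy" not in wide_all:
            continue
        paired = wide_all[[region, "healthy"]].dropna()
        if len(paired) < 2 or np.allclose(paired[region], paired["healthy"]):
            p = float("nan") if len(paired) < 2 else 1.0
        else:
            p = float(stats.ttest_rel(paired[region], paired["healthy"]).pvalue)
        vs_healthy.append({"region": region, "n": len(paired), "p": p})

    return {"summary": summary,
            "between_intervals": pd.DataFrame(between),
            "vs_healthy": pd.DataFrame(vs_healthy)}


def bland_altman(a, b) -> AgreementResult:
    """Paired-difference agreement: bias, SD and 95% limits of agreement."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1 or len(a) < 3:
        raise ValueError("need two equal-length 1D arrays with >= 3 pairs")
    d = a - b
    bias = float(d.mean())
    sd = float(d.std(ddof=1))
    if sd > 0:
        p = float(stats.ttest_rel(a, b).pvalue)
    else:
        p = 1.0 if bias == 0 else 0.0
    return AgreementResult(bias=bias, sd_diff=sd,
                           loa_low=bias - 1.96 * sd, loa_high=bias + 1.96 * sd,
                           p_paired=p, n=len(a))


def correlate(x, y, method: str = "pearson") -> CorrelationResult:
    """Pearson correlation with regression line, or Spearman rank correlation.

    Zero-variance input is flagged undefined rather than raising.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or len(x) < 3:
        raise ValueError("need equal-length arrays with >= 3 observations")
    if np.std(x) == 0 or np.std(y) == 0:
        return CorrelationResult(r=float("nan"), p=float("nan"), method=method,
                                 defined=False)
    if method == "pearson":
        lin = stats.linregress(x, y)
        return CorrelationResult(r=float(lin.rvalue), p=float(lin.pvalue),
                                 method=method, slope=float(lin.slope),
                                 intercept=float(lin.intercept))
    if method == "spearman":
        rho, p = stats.spearmanr(x, y)
        return CorrelationResult(r=float(rho), p=float(p), method=method)
    raise ValueError(f"unknown correlation method {method!r}")


def simulate_lmm_study(rng, n_lesions: int = 13, n_animals: int = 11,
                       intercept: float = 1.20, slope: float = 0.003,
                       animal_sd: float = 0.1, residual_sd: float = 0.15,
                       n_times: int = 5,
                       t_range: tuple[float, float] = (10.0, 180.0)) -> pd.DataFrame:
    """Draw one longitudinal table directly from the random-intercept model.

    Used for parameter-recovery simulation: y_it = b0 + b1 t + u_i + e_it at
    ``n_times`` random times per lesion, lesions assigned to animals with the
    first ``n_lesions - n_animals`` animals carrying two lesions.
    """
    rows = []
    offsets = rng.normal(0.0, animal_sd, n_animals)
    for i in range(n_lesions):
        animal = i if i < n_animals else i - n_animals
        times = np.sort(rng.uniform(*t_range, size=n_times))
        for t in times:
            y = intercept + slope * t + offsets[animal] + rng.normal(0, residual_sd)
            rows.append({"animal_id": f"A{animal + 1:02d}",
                         "lesion_id": f"L{i + 1:02d}",
                         "contrast": "T2-edema", "t_min": float(t),
                         "volume_mL": float("nan"),
                         "normalized_volume": float(y)})
    return pd.DataFrame(rows)
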