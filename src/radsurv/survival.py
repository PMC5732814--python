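"""Univariate survival machinery.

Three pieces, matching the screening pipeline:

1. **Censoring imputation** — each censored patient receives the mean
   survival time of deceased patients whose time-to-death is at least the
   censored patient's last-visit time; the rank correlation screen then
   treats all patients alike.
2. **Spearman screening with Holm-Bonferroni** — per patient group
   (e.g. NSCLC subtype), the rank correlation between every feature (the
   24 radiomic features plus age) and imputed survival; p-values are
   step-down corrected over the grouping-wide family (number of group
   levels x 25 tests).
3. **Median-split Kaplan-Meier / log-rank** — each feature splits its group
   at the median value (below vs at-or-above), arm survival is estimated by
   the product-limit estimator, arms are compared by the log-rank test, and
   the hazard ratio of the above-median arm is estimated from the
   observed/expected event ratio of the log-rank table (a Cox fit is
   available as an alternative estimator).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "CLINICAL_COLUMNS",
    "load_cohort",
    "impute_censored",
    "spearman",
    "holm_bonferroni",
    "screen_group",
    "km_estimate",
    "logrank",
    "median_split_km",
    "km_report_table",
    "KMReport",
    "LogrankResult",
]

#: Required clinical columns of a cohort table.
CLINICAL_COLUMNS = ("id", "age", "sex", "subtype", "T", "N", "M", "stage", "time", "event")

DAYS_PER_MONTH = 30.44  # mean Gregorian month, used only for report formatting


def load_cohort(feature_csv, clinical_csv) -> pd.DataFrame:
    """Join a feature table and a clinical table on patient id."""
    feats = pd.read_csv(feature_csv)
    clin = pd.read_csv(clinical_csv)
    for frame, what in ((feats, "feature"), (clin, "clinical")):
        if "id" not in frame.columns:
            raise ValueError(f"{what} table has no 'id' column")
    merged = clin.merge(feats, on="id", how="inner", validate="one_to_one")
    if merged.empty:
        raise ValueError("no patients shared between feature and clinical tables")
    return merged


# ---------------------------------------------------------------------------
# censoring imputation


def impute_censored(times, events) -> np.ndarray:
    """Impute censored survival times from later deaths.

    A censored patient with last-visit time ``c`` is assigned
    ``mean{t_j : event_j = 1, t_j >= c}``.  Uncensored times are returned
    unchanged.  A censored patient beyond the last death keeps its
    censoring time (there is no qualifying death to average); imputation
    therefore never decreases any patient's time.
    """
    times = np.asarray(times, dtype=np.float64)
    events = np.asarray(events, dtype=int)
    if times.shape != events.shape or times.ndim != 1:
        raise ValueError("times and events must be aligned 1D arrays")
    if not set(np.unique(events)) <= {0, 1}:
        raise ValueError("events must be 0 (censored) or 1 (death)")
    death_times = times[events == 1]
    if death_times.size == 0:
        raise ValueError("cannot impute with no uncensored patient")
    out = times.copy()
    for k in np.flatnonzero(events == 0):
        later = death_times[death_times >= times[k]]
        if later.size:
            out[k] = later.mean()
    return out


# ---------------------------------------------------------------------------
# correlation screen


def spearman(x, y) -> tuple[float, float]:
    """Spearman rank correlation with average ranks for ties.

    The two-sided p-value uses the t-distribution approximation under the
    no-correlation null.  A constant input vector has no rank ordering;
    the correlation is defined as 0 with p = 1.
    """
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.size != y.size or x.size < 3:
        raise ValueError("need two aligned vectors with n >= 3")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("inputs must be finite")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return 0.0, 1.0
    rho, p = stats.spearmanr(x, y)
    return float(rho), float(p)


def holm_bonferroni(p_raw, alpha: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Holm step-down adjustment of a family of p-values.

    Returns ``(p_adj, reject)`` where ``p_adj(k) = max_{j<=k}
    min(1, (m-j+1) * p_(j))`` in ascending order of the raw p-values.
    """
    p_raw = np.asarray(p_raw, dtype=np.float64)
    if p_raw.size == 0:
        return p_raw.copy(), np.zeros(0, dtype=bool)
    if ((p_raw < 0) | (p_raw > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    reject, p_adj, _, _ = multipletests(p_raw, alpha=alpha, method="holm")
    return p_adj, reject


def screen_group(
    cohort: pd.DataFrame,
    grouping: str,
    features: list[str] | None = None,
    alpha: float = 0.05,
    uncensored_only: bool = False,
    include_age: bool = True,
    min_group: int = 3,
) -> pd.DataFrame:
    """Spearman screen of every (group level, feature) cell of one grouping.

    ``uncensored_only=True`` restricts to deceased patients instead of
    imputing — the sensitivity mode that checks the imputation strategy is
    not driving the associations.  The Holm-Bonferroni family is the whole
    grouping (all levels x all screened variables); groups with fewer than
    ``min_group`` patients are skipped with a warning and do not enter the
    family.
    """
    if features is None:
        from .features import FEATURE_NAMES

        features = list(FEATURE_NAMES)
    variables = features + (["age"] if include_age else [])
    rows = []
    for level, sub in cohort.groupby(grouping, sort=True, observed=True, dropna=True):
        if uncensored_only:
            sub = sub[sub["event"] == 1]
        if len(sub) < min_group:
            warnings.warn(f"group {grouping}={level!r} has {len(sub)} patients; skipped")
            continue
        if uncensored_only:
            surv = sub["time"].to_numpy(dtype=float)
        else:
            surv = impute_censored(sub["time"].to_numpy(), sub["event"].to_numpy())
        for var in variables:
            rho, p = spearman(sub[var].to_numpy(dtype=float), surv)
            rows.append(
                {"grouping": grouping, "group": level, "feature": var,
                 "n": len(sub), "rho": rho, "p_raw": p}
            )
    result = pd.DataFrame(rows)
    if result.empty:
        raise ValueError(f"no group of {grouping!r} has >= {min_group} patients")
    p_adj, reject = holm_bonferroni(result["p_raw"].to_numpy(), alpha=alpha)
    result["p_adj"] = p_adj
    result["significant"] = reject
    result["family_size"] = len(result)
    return result


# ---------------------------------------------------------------------------
# Kaplan-Meier / log-rank


def km_estimate(times, events) -> tuple[KaplanMeierFitter, float]:
    """Product-limit survival estimate and median survival time.

    The median is the smallest observed time with ``S(t) <= 0.5``; ``inf``
    when the curve never reaches 0.5 (heavily censored arms).
    """
    times = np.asarray(times, dtype=np.float64)
    events = np.asarray(events, dtype=int)
    kmf = KaplanMeierFitter()
    kmf.fit(times, events)
    return kmf, float(kmf.median_survival_time_)


@dataclass
class LogrankResult:
    chi2: float
    p: float
    hazard_ratio: float  # arm A relative to arm B
    observed: tuple[float, float]
    expected: tuple[float, float]


def logrank(times_a, events_a, times_b, events_b, hr_method: str = "oe") -> LogrankResult:
    """Two-sample log-rank test with a hazard-ratio estimate.

    The statistic accumulates observed-minus-expected deaths for arm A over
    the pooled risk sets at each distinct death time (all deaths tied at a
    time are processed against the same risk set);
    ``chi2 = (O_A - E_A)^2 / V`` is referred to chi-square(1).

    ``hr_method='oe'`` (default) estimates the hazard ratio of arm A vs
    arm B as ``(O_A / E_A) / (O_B / E_B)`` from the log-rank table, needing
    no further model; ``'cox'`` fits a univariate Cox proportional-hazards
    model on the arm indicator instead.
    """
    ta = np.asarray(times_a, dtype=np.float64)
    ea = np.asarray(events_a, dtype=int)
    tb = np.asarray(times_b, dtype=np.float64)
    eb = np.asarray(events_b, dtype=int)
    if ta.size == 0 or tb.size == 0:
        raise ValueError("both arms must be non-empty")
    if ea.sum() + eb.sum() == 0:
        raise ValueError("need at least one observed event")

    death_times = np.unique(np.concatenate([ta[ea == 1], tb[eb == 1]]))
    o_a = e_a = var = 0.0
    o_b = e_b = 0.0
    for t in death_times:
        n_a = float((ta >= t).sum())
        n_b = float((tb >= t).sum())
        n = n_a + n_b
        d_a = float(((ta == t) & (ea == 1)).sum())
        d_b = float(((tb == t) & (eb == 1)).sum())
        d = d_a + d_b
        o_a += d_a
        o_b += d_b
        e_a += d * n_a / n
        e_b += d * n_b / n
        if n > 1:
            var += d * (n_a / n) * (n_b / n) * (n - d) / (n - 1)

    if var <= 0:
        return LogrankResult(0.0, 1.0, float("nan"), (o_a, o_b), (e_a, e_b))
    chi2 = (o_a - e_a) ** 2 / var
    p = float(stats.chi2.sf(chi2, df=1))

    if hr_method == "oe":
        if e_a > 0 and e_b > 0 and o_b > 0:
            hr = (o_a / e_a) / (o_b / e_b)
        else:
            hr = float("nan")
    elif hr_method == "cox":
        df = pd.DataFrame(
            {"time": np.concatenate([ta, tb]),
             "event": np.concatenate([ea, eb]),
             "arm": np.concatenate([np.ones_like(ta), np.zeros_like(tb)])}
        )
        cph = CoxPHFitter()
        cph.fit(df, duration_col="time", event_col="event")
        hr = float(np.exp(cph.params_["arm"]))
    else:
        raise ValueError(f"unknown hr_method {hr_method!r}")
    return LogrankResult(float(chi2), p, float(hr), (o_a, o_b), (e_a, e_b))


@dataclass
class KMReport:
    """Median-split survival comparison for one feature in one group."""

    feature: str
    cutoff: float
    n_below: int
    n_above: int
    median_below: float  # days; inf if the KM curve never reaches 0.5
    median_above: float
    chi2: float = float("nan")
    p_raw: float = float("nan")
    p_adj: float = float("nan")
    hazard_ratio: float = float("nan")  # above-median arm vs below-median arm
    degenerate: bool = False
    below: KaplanMeierFitter | None = field(default=None, repr=False)
    above: KaplanMeierFitter | None = field(default=None, repr=False)


def median_split_km(
    group: pd.DataFrame, feature: str, hr_method: str = "oe"
) -> KMReport:
    """Split one patient group at the median feature value and compare arms.

    Patients with feature value strictly below the group median form one
    arm; those at or above the median form the other.  When ties at the
    median empty one arm the report is flagged degenerate and no test is
    run.
    """
    if len(group) < 4:
        raise ValueError("group too small for a median split (need >= 4)")
    values = group[feature].to_numpy(dtype=float)
    cutoff = float(np.median(values))
    below = group[values < cutoff]
    above = group[values >= cutoff]
    if len(below) == 0 or len(above) == 0:
        return KMReport(feature, cutoff, len(below), len(above),
                        float("nan"), float("nan"), degenerate=True)
    km_b, med_b = km_estimate(below["time"], below["event"])
    km_a, med_a = km_estimate(above["time"], above["event"])
    if int(below["event"].sum()) + int(above["event"].sum()) == 0:
        return KMReport(feature, cutoff, len(below), len(above), med_b, med_a,
                        degenerate=True, below=km_b, above=km_a)
    res = logrank(above["time"], above["event"], below["time"], below["event"],
                  hr_method=hr_method)
    return KMReport(
        feature=feature, cutoff=cutoff, n_below=len(below), n_above=len(above),
        median_below=med_b, median_above=med_a, chi2=res.chi2, p_raw=res.p,
        hazard_ratio=res.hazard_ratio, below=km_b, above=km_a,
    )


def km_report_table(
    cohort: pd.DataFrame,
    grouping: str,
    features: list[str] | None = None,
    alpha: float = 0.05,
    include_age: bool = True,
    min_group: int = 4,
    hr_method: str = "oe",
) -> pd.DataFrame:
    """Median-split KM/log-rank over every (group level, feature) cell.

    Corrected p-values use the same grouping-wide Holm-Bonferroni family as
    the correlation screen; degenerate splits are reported but excluded
    from the family.
    """
    if features is None:
        from .features import FEATURE_NAMES

        features = list(FEATURE_NAMES)
    variables = features + (["age"] if include_age else [])
    rows = []
    for level, sub in cohort.groupby(grouping, sort=True, observed=True, dropna=True):
        if len(sub) < min_group:
            warnings.warn(f"group {grouping}={level!r} has {len(sub)} patients; skipped")
            continue
        for var in variables:
            rep = median_split_km(sub, var, hr_method=hr_method)
            rows.append(
                {"grouping": grouping, "group": level, "feature": var, "n": len(sub),
                 "cutoff": rep.cutoff, "n_below": rep.n_below, "n_above": rep.n_above,
                 "median_below_days": rep.median_below, "median_above_days": rep.median_above,
                 "median_below_months": rep.median_below / DAYS_PER_MONTH,
                 "median_above_months": rep.median_above / DAYS_PER_MONTH,
                 "chi2": rep.chi2, "p_raw": rep.p_raw,
                 "hazard_ratio": rep.hazard_ratio, "degenerate": rep.degenerate}
            )
    result = pd.DataFrame(rows)
    if result.empty:
        raise ValueError(f"no group of {grouping!r} has >= {min_group} patients")
    tested = ~result["degenerate"]
    p_adj = np.full(len(result), np.nan)
    sig = np.zeros(len(result), dtype=bool)
    if tested.any():
        adj, rej = holm_bonferroni(result.loc[tested, "p_raw"].to_numpy(), alpha=alpha)
        p_adj[tested.to_numpy()] = adj
        sig[tested.to_numpy()] = rej
    result["p_adj"] = p_adj
    result["significant"] = sig
    result["family_size"] = int(tested.sum())
    return result
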