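"""Association statistics: group tests, FDR, survival curves, Cox models.

The analysis layer links per-patient spatial features (densities,
co-localization indices, nearest-neighbour summaries) to outcome:

* relapsed vs non-relapsed comparisons with a two-sided unpaired rank-sum
  (Mann-Whitney) test — exact enumeration when both groups have n <= 8,
  tie-corrected normal approximation otherwise;
* Benjamini-Hochberg step-up correction within a declared feature family;
* Kaplan-Meier curves for a cohort median split (ties to the low arm) with
  a two-tailed log-rank test;
* multivariate Cox proportional-hazards regression of time to progression
  on continuous features plus the FLIPI risk category (ordinal 0/1/2 by
  default), via lifelines;
* Spearman rank correlation, exact for n <= 9.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.exceptions import ConvergenceError, ConvergenceWarning
from lifelines.statistics import logrank_test
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "TestResult",
    "compare_groups",
    "bh_adjust",
    "SurvivalComparison",
    "median_split_km",
    "CoxResult",
    "cox_multivariate",
    "encode_flipi",
    "spearman_assoc",
    "run_association_suite",
]

FLIPI_ORDINAL = {"low": 0, "intermediate": 1, "high": 2}


@dataclass
class TestResult:
    feature: str
    statistic: float  # Mann-Whitney U of group 1
    p_raw: float
    group_medians: dict[str, float]
    n_per_group: dict[str, int]
    p_bh: float | None = None
    method: str = "exact"


def _exact_ranksum_p(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Exact two-sided rank-sum p by full enumeration of group assignments.

    Uses midranks, so ties are handled; the two-sided p is the proportion
    of arrangements whose U deviates from its null mean at least as much
    as observed.
    """
    n, m = len(x), len(y)
    combined = np.concatenate([x, y])
    ranks = stats.rankdata(combined)
    u_obs = ranks[:n].sum() - n * (n + 1) / 2.0
    mean_u = n * m / 2.0
    dev_obs = abs(u_obs - mean_u)
    count = 0
    total = 0
    for idx in itertools.combinations(range(n + m), n):
        u = ranks[list(idx)].sum() - n * (n + 1) / 2.0
        if abs(u - mean_u) >= dev_obs - 1e-12:
            count += 1
        total += 1
    return float(u_obs), count / total


def compare_groups(values_by_group: dict[str, np.ndarray], feature: str = "feature",
                   exact_max_n: int = 8) -> TestResult:
    """Two-sided unpaired rank-sum comparison of exactly two groups.

    Missing values are dropped per group. Exact enumeration when both
    groups have at most `exact_max_n` observations, otherwise the
    tie-corrected normal approximation.
    """
    if len(values_by_group) != 2:
        raise ValueError("compare_groups expects exactly two groups")
    (name_a, a), (name_b, b) = values_by_group.items()
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    a = a[~np.isnan(a)]
    b = b[~np.isnan(b)]
    if len(a) == 0 or len(b) == 0:
        raise ValueError(f"group empty for feature {feature!r}")
    if len(a) <= exact_max_n and len(b) <= exact_max_n:
        u, p = _exact_ranksum_p(a, b)
        method = "exact"
    else:
        res = stats.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
        u, p = float(res.statistic), float(res.pvalue)
        method = "asymptotic"
    return TestResult(
        feature=feature, statistic=u, p_raw=min(p, 1.0),
        group_medians={name_a: float(np.median(a)), name_b: float(np.median(b))},
        n_per_group={name_a: len(a), name_b: len(b)}, method=method,
    )


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (order preserved)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p <= 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


@dataclass
class SurvivalComparison:
    statistic: float
    p: float
    n_high: int
    n_low: int
    median_ttp_high: float
    median_ttp_low: float
    km_high: pd.DataFrame = field(repr=False, default=None)
    km_low: pd.DataFrame = field(repr=False, default=None)


def median_split_km(values, ttp, event) -> SurvivalComparison:
    """Median-split survival comparison (high 50% vs low 50%).

    Patients strictly above the cohort median form the high arm; ties go
    to the low arm. Returns KM curves per arm and the two-tailed log-rank
    statistic and p.
    """
    v = np.asarray(values, dtype=float)
    t = np.asarray(ttp, dtype=float)
    e = np.asarray(event, dtype=int)
    med = np.median(v)
    high = v > med
    if high.sum() < 2 or (~high).sum() < 2:
        raise ValueError("degenerate median split: need at least 2 patients per arm")
    res = logrank_test(t[high], t[~high], e[high], e[~high])
    curves = []
    for arm in (high, ~high):
        kmf = KaplanMeierFitter()
        kmf.fit(t[arm], e[arm])
        curves.append(
            (float(kmf.median_survival_time_),
             kmf.survival_function_.reset_index().set_axis(["time", "survival"], axis=1))
        )
    return SurvivalComparison(
        statistic=float(res.test_statistic), p=float(res.p_value),
        n_high=int(high.sum()), n_low=int((~high).sum()),
        median_ttp_high=curves[0][0], median_ttp_low=curves[1][0],
        km_high=curves[0][1], km_low=curves[1][1],
    )


@dataclass
class CoxResult:
    table: pd.DataFrame  # covariate, coef, hr, ci_low, ci_high, p
    n: int
    n_events: int
    converged: bool


def encode_flipi(flipi, one_hot: bool = False) -> pd.DataFrame:
    """FLIPI risk category as an ordinal score (default) or one-hot columns."""
    s = pd.Series(flipi)
    bad = set(s.unique()) - set(FLIPI_ORDINAL)
    if bad:
        raise ValueError(f"unknown FLIPI levels: {sorted(bad)}")
    if one_hot:
        d = pd.get_dummies(pd.Categorical(s, categories=list(FLIPI_ORDINAL)), prefix="flipi")
        return d.iloc[:, 1:].astype(float)  # low = reference level
    return pd.DataFrame({"flipi": s.map(FLIPI_ORDINAL).astype(float)})


def cox_multivariate(features: pd.DataFrame, ttp, event) -> CoxResult:
    """Multivariate Cox PH fit (Efron ties) with Wald CIs, via lifelines.

    `features` holds the numeric covariates (continuous spatial features
    and an encoded FLIPI). Non-convergence or monotone likelihood is
    reported through the `converged` flag, never silently.
    """
    t = np.asarray(ttp, dtype=float)
    e = np.asarray(event, dtype=int)
    k = features.shape[1]
    if e.sum() < k + 1:
        raise ValueError(f"need at least {k + 1} events for {k} covariates, got {int(e.sum())}")
    df = features.astype(float).copy()
    df["ttp_years"] = t
    df["event"] = e
    cph = CoxPHFitter()
    converged = True
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        try:
            cph.fit(df, duration_col="ttp_years", event_col="event")
        except ConvergenceError:
            return CoxResult(pd.DataFrame(), len(df), int(e.sum()), converged=False)
        if any(issubclass(w.category, ConvergenceWarning) for w in caught):
            converged = False
    s = cph.summary
    table = pd.DataFrame({
        "covariate": s.index,
        "coef": s["coef"].to_numpy(),
        "hr": s["exp(coef)"].to_numpy(),
        "ci_low": s["exp(coef) lower 95%"].to_numpy(),
        "ci_high": s["exp(coef) upper 95%"].to_numpy(),
        "p": s["p"].to_numpy(),
    }).reset_index(drop=True)
    return CoxResult(table, len(df), int(e.sum()), converged)


def spearman_assoc(x, y, exact_max_n: int = 9) -> tuple[float, float]:
    """Spearman rank correlation; exact permutation p for n <= `exact_max_n`.

    Returns (rho, p); (nan, nan) for constant input.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    keep = ~(np.isnan(x) | np.isnan(y))
    x, y = x[keep], y[keep]
    if len(x) < 5:
        raise ValueError("need at least 5 paired observations")
    if np.all(x == x[0]) or np.all(y == y[0]):
        return float("nan"), float("nan")
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    rho = float(np.corrcoef(rx, ry)[0, 1])
    n = len(x)
    if n <= exact_max_n:
        rxc = rx - rx.mean()
        sy = ry - ry.mean()
        denom = np.sqrt((rxc**2).sum() * (sy**2).sum())
        perms = np.array(list(itertools.permutations(sy)))
        rhos = perms @ rxc / denom
        p = float(np.mean(np.abs(rhos) >= abs(rho) - 1e-12))
    else:
        p = float(stats.spearmanr(x, y).pvalue)
    return rho, p


def run_association_suite(table: pd.DataFrame, features: list[str],
                          headline_pair: tuple[str, str] | None = None,
                          max_missing: float = 0.5) -> pd.DataFrame:
    """Relapse comparison + median-split KM + Cox-vs-FLIPI for each feature.

    `table` needs patient_id, ttp_years, event, flipi plus the feature
    columns. BH correction is applied within feature families inferred
    from the name prefix (``density_…`` and ``coloc_…`` are separate
    families; anything else forms a third). When `headline_pair` is given,
    a joint Cox model with both features plus FLIPI is fitted and reported
    in the ``joint_…`` columns of those two rows.
    """
    if len(table) < 10 or table["event"].sum() < 1:
        raise ValueError("need at least 10 patients and 1 event")
    kept = []
    for f in features:
        if table[f].isna().mean() > max_missing:
            warnings.warn(f"feature {f!r} dropped: >{max_missing:.0%} missing")
        else:
            kept.append(f)
    flipi = encode_flipi(table["flipi"])

    rows = []
    for f in kept:
        vals = table[f]
        ok = ~vals.isna()
        relapsed = vals[ok & (table["event"] == 1)].to_numpy()
        nonrel = vals[ok & (table["event"] == 0)].to_numpy()
        if len(relapsed) == 0 or len(nonrel) == 0:
            # one relapse group absent (e.g. every patient progressed):
            # the comparison is undefined, the survival models still run
            warnings.warn(f"feature {f!r}: a relapse group is empty, rank-sum skipped")
            tr = TestResult(feature=f, statistic=float("nan"), p_raw=float("nan"),
                            group_medians={"relapsed": float(np.median(relapsed)) if len(relapsed) else float("nan"),
                                           "not_relapsed": float(np.median(nonrel)) if len(nonrel) else float("nan")},
                            n_per_group={"relapsed": len(relapsed), "not_relapsed": len(nonrel)},
                            method="undefined")
        else:
            tr = compare_groups({"relapsed": relapsed, "not_relapsed": nonrel}, feature=f)
        try:
            km = median_split_km(vals[ok], table.loc[ok, "ttp_years"], table.loc[ok, "event"])
            logrank_p, logrank_stat = km.p, km.statistic
        except ValueError:
            logrank_p = logrank_stat = float("nan")
        X = pd.concat([vals[ok].rename(f).reset_index(drop=True),
                       flipi[ok.to_numpy()].reset_index(drop=True)], axis=1)
        cox = cox_multivariate(X, table.loc[ok, "ttp_years"], table.loc[ok, "event"])
        crow = cox.table[cox.table["covariate"] == f]
        rows.append({
            "feature": f,
            "family": f.split("_", 1)[0] if f.split("_", 1)[0] in ("density", "coloc") else "other",
            "n": int(ok.sum()),
            "median_relapsed": tr.group_medians["relapsed"],
            "median_not_relapsed": tr.group_medians["not_relapsed"],
            "u_statistic": tr.statistic,
            "p_raw": tr.p_raw,
            "logrank_stat": logrank_stat,
            "logrank_p": logrank_p,
            "cox_coef": float(crow["coef"].iloc[0]) if len(crow) else float("nan"),
            "cox_hr": float(crow["hr"].iloc[0]) if len(crow) else float("nan"),
            "cox_p": float(crow["p"].iloc[0]) if len(crow) else float("nan"),
            "cox_converged": cox.converged,
        })
    out = pd.DataFrame(rows)
    out["p_bh"] = np.nan
    for _, idx in out.groupby("family").groups.items():
        p = out.loc[idx, "p_raw"].to_numpy()
        defined = np.isfinite(p)
        if defined.any():
            adj = np.full(len(p), np.nan)
            adj[defined] = bh_adjust(p[defined])
            out.loc[idx, "p_bh"] = adj

    if headline_pair is not None:
        f1, f2 = headline_pair
        ok = ~(table[f1].isna() | table[f2].isna())
        X = pd.concat([table.loc[ok, [f1, f2]].reset_index(drop=True),
                       flipi[ok.to_numpy()].reset_index(drop=True)], axis=1)
        cox = cox_multivariate(X, table.loc[ok, "ttp_years"], table.loc[ok, "event"])
        for f in (f1, f2):
            crow = cox.table[cox.table["covariate"] == f]
            if len(crow):
                sel = out["feature"] == f
                out.loc[sel, "joint_cox_coef"] = float(crow["coef"].iloc[0])
                out.loc[sel, "joint_cox_hr"] = float(crow["hr"].iloc[0])
                out.loc[sel, "joint_cox_p"] = float(crow["p"].iloc[0])
    return out
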