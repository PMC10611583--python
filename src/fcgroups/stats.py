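"""Independent statistical validation of selected connectivity groups.

Everything here consumes only data that played no part in the clustering:
personality (TCI) scores, symptom composites and demographics, plus the raw
connectivity values for direction classification. Machinery: one-way ANOVA
and Welch pairwise t-tests with Bonferroni correction and the effect size
r = sqrt(t^2 / (t^2 + df)); chi-squared tests for categorical confounders;
and forward-stepwise logistic regression measuring how much of group
membership the seven TCI dimensions explain (reported as the R^2 of an OLS
regression of the 0/1 membership on the fitted probabilities, with its F,
p and RMSE).
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps

from .atlas import NETWORKS, TCI_DIMENSIONS

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# primitives


def anova_oneway(groups: list[np.ndarray]) -> tuple[float, float]:
    """One-way ANOVA F and p across the given groups.

    Degenerate input (zero within-group variance everywhere) is resolved by
    exact equality: identical means give (0, 1), different means give
    (inf, 0); both are logged.
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2 or any(len(g) < 2 for g in groups):
        raise ValueError("need >= 2 groups with >= 2 observations each")
    if all(g.var() == 0 for g in groups):
        means = [g.mean() for g in groups]
        if np.ptp(means) == 0:
            logger.warning("ANOVA on identical constant groups: F=0, p=1")
            return 0.0, 1.0
        logger.warning("ANOVA with zero within-group variance: F=inf, p=0")
        return float("inf"), 0.0
    f, p = sps.f_oneway(*groups)
    return float(f), float(p)


def welch_t(x: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    """Welch t statistic, its degrees of freedom, and the two-sided p."""
    res = sps.ttest_ind(x, y, equal_var=False)
    return float(res.statistic), float(res.df), float(res.pvalue)


def effect_size_r(t: float, df: float) -> float:
    """r = sqrt(t^2 / (t^2 + df)), the correlation-coefficient effect size."""
    if not np.isfinite(t):
        return 1.0
    return float(np.sqrt(t * t / (t * t + df)))


def bonferroni(p: float, m_tests: int) -> float:
    """Bonferroni-adjusted p-value, capped at 1."""
    if m_tests < 1:
        raise ValueError("m_tests must be >= 1")
    return min(1.0, m_tests * p)


def pairwise_t_bonferroni(
    groups: dict[str, np.ndarray], m_tests: int
) -> pd.DataFrame:
    """Welch t-tests for every pair of labelled groups with Bonferroni
    correction over ``m_tests`` comparisons. Pairs involving a group with
    fewer than 2 observations are skipped and logged."""
    rows = []
    for (la, xa), (lb, xb) in itertools.combinations(groups.items(), 2):
        if len(xa) < 2 or len(xb) < 2:
            logger.warning("skipping pair (%s, %s): group too small", la, lb)
            continue
        t, df, p = welch_t(np.asarray(xa, float), np.asarray(xb, float))
        rows.append(
            {
                "group_a": la, "group_b": lb,
                "mean_a": float(np.mean(xa)), "mean_b": float(np.mean(xb)),
                "t": t, "df": df, "p_raw": p,
                "p_adj": bonferroni(p, m_tests),
                "effect_r": effect_size_r(t, df),
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# direction classification (reference-table style)


def network_test_table(
    block_values: pd.DataFrame,
    member_ids: list[str],
    control_ids: list[str],
    patient_ids: list[str],
) -> pd.DataFrame:
    """Per-network statistics for one group.

    ``block_values`` is subjects x networks (within-network mean deviation
    from the control mean). For every network we report group means, the
    three-way ANOVA (members / other patients / controls), and the Welch
    t-test of members vs controls with Bonferroni correction over the
    number of networks tested.
    """
    nets = list(block_values.columns)
    members = [s for s in member_ids if s in block_values.index]
    others = [s for s in patient_ids if s not in set(member_ids)]
    m_tests = len(nets)
    rows = []
    for net in nets:
        xm = block_values.loc[members, net].to_numpy(float)
        xo = block_values.loc[others, net].to_numpy(float)
        xc = block_values.loc[control_ids, net].to_numpy(float)
        f, p_anova = anova_oneway([xm, xo, xc])
        t, df, p_raw = welch_t(xm, xc)
        to, dfo, p_raw_o = welch_t(xm, xo)
        rows.append(
            {
                "network": net,
                "member_mean": xm.mean(), "other_mean": xo.mean(),
                "control_mean": xc.mean(),
                "anova_F": f, "anova_p": p_anova,
                "t_vs_control": t, "p_raw_vs_control": p_raw,
                "p_adj_vs_control": bonferroni(p_raw, m_tests),
                "r_vs_control": effect_size_r(t, df),
                "t_vs_others": to, "p_raw_vs_others": p_raw_o,
                "p_adj_vs_others": bonferroni(p_raw_o, m_tests),
                "r_vs_others": effect_size_r(to, dfo),
            }
        )
    return pd.DataFrame(rows)


def classify_directions(
    table: pd.DataFrame, p_sig: float = 0.05, p_bold: float = 0.001
) -> pd.DataFrame:
    """Classify each network Positive / Negative / "--" for one group.

    Positive (resp. Negative) when the member mean exceeds (resp. falls
    below) the control mean with Bonferroni-adjusted p below ``p_sig``;
    bold marks adjusted p below ``p_bold``.
    """
    if not 0 < p_bold < p_sig:
        raise ValueError("need 0 < p_bold < p_sig")
    out = table.copy()
    sig = out["p_adj_vs_control"] < p_sig
    higher = out["member_mean"] > out["control_mean"]
    out["direction"] = np.where(
        sig & higher, "Positive", np.where(sig & ~higher, "Negative", "--")
    )
    out["bold"] = sig & (out["p_adj_vs_control"] < p_bold)
    return out


def diagnosis_within_group(
    member_values: np.ndarray, is_sz: np.ndarray
) -> dict[str, int | bool]:
    """Count features with weak (0.01 < p < 0.05) and strong (p < 0.01)
    SZ-vs-BP differences among a group's members (Welch t per feature)."""
    is_sz = np.asarray(is_sz, dtype=bool)
    if is_sz.all() or (~is_sz).all() or is_sz.sum() < 2 or (~is_sz).sum() < 2:
        return {"applicable": False, "weak": 0, "strong": 0, "n_features": 0}
    x = np.asarray(member_values, float)
    res = sps.ttest_ind(x[is_sz], x[~is_sz], equal_var=False, axis=0)
    p = np.atleast_1d(res.pvalue)
    return {
        "applicable": True,
        "weak": int(((p > 0.01) & (p < 0.05)).sum()),
        "strong": int((p < 0.01).sum()),
        "n_features": int(p.size),
    }


# ---------------------------------------------------------------------------
# TCI explanatory power


@dataclass
class TCIRegressionResult:
    group: str
    predictors: list[str]
    r2_percent: float
    f_stat: float
    p_value: float
    rmse: float
    used_ridge_fallback: bool = False


def _logit_fit(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, float, bool]:
    """Fit a logistic regression; fall back to a small-ridge penalized fit
    under (quasi-)separation. Returns (fitted probabilities, AIC, fallback)."""
    Xc = sm.add_constant(X, has_constant="add")
    try:
        with np.errstate(all="ignore"), warnings.catch_warnings():
            warnings.simplefilter("ignore")  # separation warnings handled below
            res = sm.Logit(y, Xc).fit(disp=0, maxiter=200, warn_convergence=False)
        if np.all(np.isfinite(res.params)) and np.max(np.abs(res.params)) < 50:
            return np.asarray(res.predict(Xc)), float(res.aic), False
        raise sps.FitError("parameter blow-up indicates separation")
    except Exception:
        logger.warning("logistic separation detected; using ridge-penalized fit")
        n, k = Xc.shape
        with np.errstate(all="ignore"):
            res = sm.GLM(y, Xc, family=sm.families.Binomial()).fit_regularized(
                alpha=1e-3, L1_wt=0.0
            )
        eta = Xc @ np.asarray(res.params)
        fitted = 1.0 / (1.0 + np.exp(-eta))
        fitted = np.clip(fitted, 1e-9, 1 - 1e-9)
        ll = float(np.sum(y * np.log(fitted) + (1 - y) * np.log(1 - fitted)))
        return fitted, -2.0 * ll + 2.0 * k, True


def tci_explanatory_power(
    tci: pd.DataFrame,
    membership: np.ndarray,
    group_name: str = "",
    min_aic_improvement: float = 2.0,
) -> TCIRegressionResult:
    """Explanatory power of the TCI dimensions for one group's membership.

    Forward-stepwise logistic regression (predictors enter while they
    improve AIC by at least ``min_aic_improvement``), then an OLS of the
    0/1 membership on the fitted probabilities supplies R^2 (percent), F,
    p and RMSE. Invariant to affine rescaling of the predictors.
    """
    y = np.asarray(membership, dtype=float)
    predictors = [c for c in TCI_DIMENSIONS if c in tci.columns]
    if not predictors:
        raise ValueError("no TCI columns found")
    if y.sum() < 5 or (1 - y).sum() < 5:
        raise ValueError("need >= 5 members and >= 5 non-members")
    X_all = tci[predictors].to_numpy(float)

    chosen: list[int] = []
    fitted = np.full(y.shape, y.mean())
    base_p = np.clip(y.mean(), 1e-9, 1 - 1e-9)
    current_aic = -2.0 * float(
        np.sum(y * np.log(base_p) + (1 - y) * np.log(1 - base_p))
    ) + 2.0
    fallback_any = False
    while len(chosen) < len(predictors):
        best = None
        for j in range(len(predictors)):
            if j in chosen:
                continue
            f, aic, fb = _logit_fit(X_all[:, chosen + [j]], y)
            if best is None or aic < best[1]:
                best = (j, aic, f, fb)
        if best is None or current_aic - best[1] < min_aic_improvement:
            break
        chosen.append(best[0])
        current_aic = best[1]
        fitted = best[2]
        fallback_any = fallback_any or best[3]

    if not chosen or np.ptp(fitted) < 1e-12:
        resid = y - y.mean()
        return TCIRegressionResult(
            group=group_name, predictors=[], r2_percent=0.0, f_stat=0.0,
            p_value=1.0, rmse=float(np.sqrt(np.mean(resid**2))),
            used_ridge_fallback=fallback_any,
        )
    ols = sm.OLS(y, sm.add_constant(fitted)).fit()
    resid = ols.resid
    return TCIRegressionResult(
        group=group_name,
        predictors=[predictors[j] for j in chosen],
        r2_percent=float(100.0 * ols.rsquared),
        f_stat=float(ols.fvalue),
        p_value=float(ols.f_pvalue),
        rmse=float(np.sqrt(np.mean(resid**2))),
        used_ridge_fallback=fallback_any,
    )


# ---------------------------------------------------------------------------
# confounders


_CONTINUOUS = ("age", "illness_duration")
_CATEGORICAL = ("sex", "ethnicity", "handedness", "antipsychotic", "mood_stabilizer")


def confounder_tests(
    cohort: pd.DataFrame, memberships: dict[str, list[str]]
) -> pd.DataFrame:
    """Confounder screen: for each demographic variable and each group,
    test members against the other patients (Welch t or chi-squared, plus a
    members / other patients / controls ANOVA for continuous variables).
    Effect sizes are mapped to the correlation scale (r or Cramér's V)."""
    if not memberships:
        raise ValueError("no groups to test")
    patients = cohort[cohort["status"] != "control"]
    controls = cohort[cohort["status"] == "control"]
    rows = []
    for gname, member_ids in memberships.items():
        mem = set(member_ids)
        in_g = patients["subject_id"].isin(mem)
        for var in _CONTINUOUS:
            xm = patients.loc[in_g, var].to_numpy(float)
            xo = patients.loc[~in_g, var].to_numpy(float)
            if len(xm) < 2 or len(xo) < 2:
                logger.warning("confounder %s for %s: group too small", var, gname)
                continue
            t, df, p = welch_t(xm, xo)
            rows.append(
                {"variable": var, "group": gname, "test": "t",
                 "statistic": t, "p": p, "effect_r": effect_size_r(t, df)}
            )
            xc = controls[var].to_numpy(float)
            if len(xc) >= 2:
                f, pa = anova_oneway([xm, xo, xc])
                dfw = max(len(xm) + len(xo) + len(xc) - 3, 1)
                r_f = 1.0 if not np.isfinite(f) else float(np.sqrt(f / (f + dfw)))
                rows.append(
                    {"variable": var, "group": gname, "test": "ANOVA",
                     "statistic": f, "p": pa, "effect_r": r_f}
                )
        for var in _CATEGORICAL:
            tab = pd.crosstab(in_g, patients[var])
            if tab.shape[0] < 2 or tab.shape[1] < 2:
                rows.append(
                    {"variable": var, "group": gname, "test": "chi2",
                     "statistic": 0.0, "p": 1.0, "effect_r": 0.0}
                )
                continue
            try:
                chi2, p, _, expected = sps.chi2_contingency(tab)
                if (expected < 1).any() and tab.shape == (2, 2):
                    raise ValueError("sparse 2x2 table")
            except ValueError:
                logger.warning("sparse table for %s/%s: Fisher exact fallback", var, gname)
                _, p = sps.fisher_exact(tab.iloc[:2, :2])
                chi2 = float("nan")
            n = tab.to_numpy().sum()
            kdim = min(tab.shape) - 1
            v = float(np.sqrt(chi2 / (n * kdim))) if np.isfinite(chi2) else float("nan")
            rows.append(
                {"variable": var, "group": gname, "test": "chi2",
                 "statistic": float(chi2), "p": float(p),
                 "effect_r": min(v, 1.0) if np.isfinite(v) else 1.0}
            )
    return pd.DataFrame(rows)
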