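"""Density-adjusted group statistics for connectome metrics.

The battery mirrors the analysis plan of a two-group (healthy control vs
progressive-MS) comparison:

* ANCOVA — OLS of metric ~ group + covariates, p from the two-sided
  t-test on the group coefficient (numerically identical to the 1-df
  ANCOVA F-test); run once with age + sex and once adding network
  density, to separate density-driven from density-independent effects;
* partial correlation of global metrics with lesion volume and grey-
  matter fraction, controlling age + sex;
* two-block stepwise regression for clinical outcomes: age + sex forced
  in block 1, network properties entering/leaving block 2 by partial-F
  p-value (defaults p_enter = 0.05, p_remove = 0.10);
* Bonferroni thresholds alpha/m with m = 6 global metrics and m = 14
  nodes; comparisons use the unrounded threshold, display rounds to 3
  decimals.

Group is coded 0 = HC, 1 = patient (negative beta means lower in
patients); sex is coded 0 = F, 1 = M.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
import statsmodels.api as sm

from .errors import (ContractError, ParameterError, SingularDesignError)

__all__ = [
    "StatTestResult", "ancova_group_test", "partial_correlation",
    "stepwise_blocks", "bonferroni_threshold", "display_threshold",
    "BatteryConfig", "analysis_battery", "encode_binary",
]

_CONDITION_CAP = 1e10


@dataclass
class StatTestResult:
    """Uniform result record for every test in the battery."""

    test: str
    estimate: float | None = None
    se: float | None = None
    statistic: float | None = None
    p: float | None = None
    df: float | None = None
    covariates: tuple[str, ...] = ()
    n: int = 0
    r: float | None = None
    r2: float | None = None
    significant: bool | None = None
    detail: dict = field(default_factory=dict)

    def apply_threshold(self, threshold: float) -> "StatTestResult":
        self.significant = (self.p is not None and not np.isnan(self.p)
                            and self.p < threshold)
        return self


def encode_binary(series: pd.Series, levels: tuple[str, str]) -> np.ndarray:
    """Map a two-level categorical to 0/1 in the order given."""
    vals = set(series.unique())
    if not vals <= set(levels):
        raise ContractError(f"unexpected levels {vals - set(levels)}")
    return (series == levels[1]).to_numpy(dtype=float)


def _design(cohort: pd.DataFrame, columns: list[str]) -> np.ndarray:
    cols = []
    for c in columns:
        if c == "group":
            cols.append(encode_binary(cohort["group"], ("HC", "PMS")))
        elif c == "sex":
            cols.append(encode_binary(cohort["sex"], ("F", "M")))
        else:
            cols.append(cohort[c].to_numpy(dtype=float))
    X = np.column_stack(cols) if cols else np.empty((len(cohort), 0))
    X = np.column_stack([np.ones(len(cohort)), X])
    if np.linalg.cond(X) > _CONDITION_CAP:
        raise SingularDesignError("collinear covariates in design matrix")
    return X


def ancova_group_test(cohort: pd.DataFrame, metric: str,
                      covariates: tuple[str, ...] = ("age", "sex"),
                      ) -> StatTestResult:
    """Covariate-adjusted group comparison of one metric.

    OLS of ``metric ~ group + covariates``; the reported p is the
    two-sided t-test on the group coefficient.  A zero-variance metric is
    flagged (beta 0, p 1) instead of failing.
    """
    y = cohort[metric].to_numpy(dtype=float)
    n = y.size
    if np.all(y == y[0]):
        return StatTestResult(test="ancova", estimate=0.0, se=0.0,
                              statistic=0.0, p=1.0, covariates=covariates,
                              n=n, detail={"zero_variance": True,
                                           "metric": metric})
    X = _design(cohort, ["group", *covariates])
    model = sm.OLS(y, X).fit()
    return StatTestResult(
        test="ancova", estimate=float(model.params[1]),
        se=float(model.bse[1]), statistic=float(model.tvalues[1]),
        p=float(model.pvalues[1]), df=float(model.df_resid),
        covariates=covariates, n=n,
        detail={"metric": metric, "group_means": {
            g: float(cohort.loc[cohort["group"] == g, metric].mean())
            for g in ("HC", "PMS")}},
    )


def _residuals(values: np.ndarray, Z: np.ndarray) -> np.ndarray:
    beta, *_ = np.linalg.lstsq(Z, values, rcond=None)
    return values - Z @ beta


def partial_correlation(cohort: pd.DataFrame, x: str, y: str,
                        covariates: tuple[str, ...] = ("age", "sex"),
                        ) -> StatTestResult:
    """Pearson correlation of x and y after regressing out covariates.

    p from the t distribution with n - len(covariates) - 2 df.  With an
    empty covariate set this is the plain Pearson correlation.
    """
    n = len(cohort)
    k = len(covariates)
    if n <= k + 2:
        raise ParameterError("need n > len(covariates) + 2")
    Z = _design(cohort, list(covariates))
    rx = _residuals(cohort[x].to_numpy(dtype=float), Z)
    ry = _residuals(cohort[y].to_numpy(dtype=float), Z)
    if rx.std() == 0 or ry.std() == 0:
        return StatTestResult(test="partial_correlation", r=float("nan"),
                              p=float("nan"), covariates=covariates, n=n,
                              detail={"constant_residuals": True})
    r = float(np.corrcoef(rx, ry)[0, 1])
    df = n - k - 2
    r_ = min(max(r, -1.0), 1.0)
    if abs(r_) == 1.0:
        t, p = np.inf * np.sign(r_), 0.0
    else:
        t = r_ * np.sqrt(df / (1 - r_**2))
        p = 2 * sps.t.sf(abs(t), df)
    return StatTestResult(test="partial_correlation", statistic=float(t),
                          p=float(p), df=df, covariates=covariates, n=n, r=r)


def stepwise_blocks(cohort: pd.DataFrame, outcome: str,
                    block1_forced: tuple[str, ...] = ("age", "sex"),
                    block2_candidates: tuple[str, ...] = (),
                    p_enter: float = 0.05,
                    p_remove: float = 0.10) -> StatTestResult:
    """Two-block stepwise regression.

    Block-1 variables are always retained; block-2 candidates enter by
    smallest partial-F p-value below ``p_enter``, and entered variables
    are removed again when their p rises above ``p_remove``.  Reports the
    final model R², overall F-test p and standardized betas of selected
    block-2 variables.
    """
    if not block2_candidates:
        raise ParameterError("block2_candidates must be nonempty")
    if not (0 < p_enter <= p_remove):
        raise ParameterError("require 0 < p_enter <= p_remove")
    y = cohort[outcome].to_numpy(dtype=float)
    selected: list[str] = []
    remaining = list(block2_candidates)

    def fit(terms: list[str]):
        X = _design(cohort, list(block1_forced) + terms)
        return sm.OLS(y, X).fit(), X

    for _ in range(4 * len(block2_candidates) + 4):  # cycling guard
        # forward step
        best_p, best_var = None, None
        for cand in remaining:
            model, _ = fit(selected + [cand])
            p = float(model.pvalues[-1])
            if best_p is None or p < best_p:
                best_p, best_var = p, cand
        if best_var is not None and best_p < p_enter:
            selected.append(best_var)
            remaining.remove(best_var)
        else:
            break
        # backward step over entered variables
        changed = True
        while changed and selected:
            model, _ = fit(selected)
            offset = 1 + len(block1_forced)
            pvals = {v: float(model.pvalues[offset + i])
                     for i, v in enumerate(selected)}
            worst = max(pvals, key=pvals.get)
            if pvals[worst] > p_remove:
                selected.remove(worst)
                remaining.append(worst)
            else:
                changed = False

    model, X = fit(selected)
    # standardized betas for selected block-2 terms
    zs = {}
    if selected:
        zc = cohort.copy()
        ysd = y.std(ddof=1)
        Xz = _design(zc, list(block1_forced) + selected)
        zmodel = sm.OLS((y - y.mean()) / ysd if ysd > 0 else y, Xz).fit()
        offset = 1 + len(block1_forced)
        for i, v in enumerate(selected):
            sd = cohort[v].to_numpy(dtype=float).std(ddof=1)
            zs[v] = float(zmodel.params[offset + i] * sd)
    return StatTestResult(
        test="stepwise", p=float(model.f_pvalue), r2=float(model.rsquared),
        df=float(model.df_resid), covariates=block1_forced, n=len(cohort),
        detail={"outcome": outcome, "selected": list(selected),
                "standardized_beta": zs,
                "block1_only": not selected},
    )


def bonferroni_threshold(alpha: float, m: int) -> float:
    """Family-wise threshold alpha/m (comparisons use the exact value)."""
    if not (0 < alpha < 1):
        raise ParameterError("alpha must be in (0, 1)")
    if m < 1:
        raise ParameterError("m must be at least 1")
    return alpha / m


def display_threshold(alpha: float, m: int) -> float:
    """Threshold rounded to 3 decimals, for table display only."""
    return round(bonferroni_threshold(alpha, m), 3)


@dataclass
class BatteryConfig:
    """Configuration of the full statistical battery."""

    global_metrics: tuple[str, ...] = ("modularity", "global_efficiency",
                                       "clustering_coefficient",
                                       "mean_strength", "assortativity",
                                       "density")
    nodal_metrics: tuple[str, ...] = ()
    correlates: tuple[str, ...] = ("t2_lesion_volume", "smn_gmf")
    outcomes: tuple[str, ...] = ()
    covariates: tuple[str, ...] = ("age", "sex")
    density_column: str = "density"
    alpha: float = 0.05
    m_global: int = 6
    m_nodal: int = 14
    p_enter: float = 0.05
    p_remove: float = 0.10


def analysis_battery(cohort: pd.DataFrame,
                     config: BatteryConfig | None = None) -> pd.DataFrame:
    """Run the full battery and return one tidy row per test.

    Per metric: ANCOVA with age + sex (``p_a``) and with density added
    (``p_b``; left blank for density itself), flagged against the
    appropriate Bonferroni threshold; partial correlations of global
    metrics with the structural correlates; stepwise models per outcome.
    """
    if config is None:
        config = BatteryConfig()
    rows = []
    thr_g = bonferroni_threshold(config.alpha, config.m_global)
    thr_n = bonferroni_threshold(config.alpha, config.m_nodal)

    for metrics, thr, family in ((config.global_metrics, thr_g, "global"),
                                 (config.nodal_metrics, thr_n, "nodal")):
        for metric in metrics:
            res_a = ancova_group_test(cohort, metric, config.covariates)
            res_a.apply_threshold(thr)
            row = {"family": family, "metric": metric, "test": "ancova",
                   "n": res_a.n, "beta_group": res_a.estimate,
                   "p_a": res_a.p, "sig_a": res_a.significant,
                   "p_b": None, "sig_b": None,
                   "hc_mean": res_a.detail.get("group_means", {}).get("HC"),
                   "pms_mean": res_a.detail.get("group_means", {}).get("PMS")}
            if metric != config.density_column:
                res_b = ancova_group_test(
                    cohort, metric,
                    (*config.covariates, config.density_column))
                res_b.apply_threshold(thr)
                row["p_b"] = res_b.p
                row["sig_b"] = res_b.significant
            rows.append(row)

    for metric in config.global_metrics:
        for corr in config.correlates:
            if corr not in cohort.columns:
                continue
            res = partial_correlation(cohort, metric, corr, config.covariates)
            res.apply_threshold(config.alpha)
            rows.append({"family": "correlation", "metric": metric,
                         "test": f"partial_corr[{corr}]", "n": res.n,
                         "r": res.r, "p_a": res.p, "sig_a": res.significant})

    candidates = tuple(config.global_metrics) + tuple(config.nodal_metrics)
    for outcome in config.outcomes:
        if outcome not in cohort.columns:
            continue
        res = stepwise_blocks(cohort, outcome, config.covariates, candidates,
                              config.p_enter, config.p_remove)
        rows.append({"family": "stepwise", "metric": outcome,
                     "test": "stepwise", "n": res.n, "r2": res.r2,
                     "p_a": res.p,
                     "selected": ";".join(res.detail["selected"]),
                     "standardized_beta": str(res.detail["standardized_beta"])})
    return pd.DataFrame(rows)
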