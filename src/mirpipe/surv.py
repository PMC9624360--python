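"""Expression-stratified survival analysis.

Patients are binned by the cohort z-score of a miRNA's expression into
low / mid / high groups (default cuts at -0.43 / +0.43, the normal-theory
tertile boundaries), and the association of expression with overall
survival is quantified three ways: Kaplan-Meier product-limit curves per
bin, the k-group log-rank test, and Cox proportional-hazards regression on
the continuous z-score (Efron tie handling, Wald intervals).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.exceptions import ConvergenceWarning
from lifelines.statistics import multivariate_logrank_test

CUT_LOW_DEFAULT = -0.43
CUT_HIGH_DEFAULT = 0.43

BIN_ORDER = ("low", "mid", "high")


class StratificationError(ValueError):
    pass


@dataclass
class Stratification:
    mirna_id: str
    z_scores: pd.Series
    bins: pd.Series  # values in {"low", "mid", "high"}
    cut_low: float
    cut_high: float

    @property
    def bin_sizes(self) -> dict[str, int]:
        counts = self.bins.value_counts()
        return {b: int(counts.get(b, 0)) for b in BIN_ORDER}


def stratify(
    cohort: pd.DataFrame,
    mirna_id: str,
    cut_low: float = CUT_LOW_DEFAULT,
    cut_high: float = CUT_HIGH_DEFAULT,
) -> Stratification:
    """Standardize a miRNA's expression over the cohort and bin patients.

    bin = high iff z >= cut_high, low iff z <= cut_low, mid otherwise.
    """
    if cut_low >= cut_high:
        raise StratificationError(f"cut_low {cut_low} must be < cut_high {cut_high}")
    if len(cohort) < 3:
        raise StratificationError("need >= 3 patients to stratify")
    x = cohort[mirna_id].astype(float)
    sd = x.std(ddof=1)
    if not np.isfinite(sd) or sd == 0:
        raise StratificationError(
            f"{mirna_id}: zero expression variance, cannot standardize"
        )
    z = (x - x.mean()) / sd
    bins = pd.Series("mid", index=cohort.index)
    bins[z >= cut_high] = "high"
    bins[z <= cut_low] = "low"
    return Stratification(mirna_id, z, bins, cut_low, cut_high)


def kaplan_meier(times, events, bin_mask=None) -> pd.DataFrame:
    """Product-limit survival curve, optionally restricted to one bin.

    Returns the step function as a table (time, at_risk, events, censored,
    survival); survival starts at 1 and is non-increasing.
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    if bin_mask is not None:
        bin_mask = np.asarray(bin_mask, dtype=bool)
        times, events = times[bin_mask], events[bin_mask]
    if len(times) == 0:
        raise ValueError("empty bin: no subjects to estimate survival for")
    kmf = KaplanMeierFitter()
    kmf.fit(times, events)
    table = kmf.event_table
    surv = kmf.survival_function_["KM_estimate"]
    return pd.DataFrame(
        {
            "time": table.index.values,
            "at_risk": table["at_risk"].values,
            "events": table["observed"].values,
            "censored": table["censored"].values,
            "survival": surv.loc[table.index].values,
        }
    )


def logrank(times, events, bins) -> tuple[float, float]:
    """k-group log-rank test; returns (chi2, p) with k-1 df."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    bins = pd.Series(bins).reset_index(drop=True)
    occupied = bins.value_counts()
    if (occupied > 0).sum() < 2:
        raise ValueError("log-rank test needs >= 2 non-empty groups")
    if events.sum() == 0:
        warnings.warn(
            "all subjects censored: log-rank chi2 = 0", RuntimeWarning, stacklevel=2
        )
        return 0.0, 1.0
    res = multivariate_logrank_test(times, bins.values, events)
    return float(res.test_statistic), float(res.p_value)


@dataclass
class CoxResult:
    hr: float
    ci_low: float
    ci_high: float
    p_value: float
    beta: float
    separation_flag: bool = False


def cox_fit(times, events, covariate) -> CoxResult:
    """Univariate Cox proportional-hazards fit (Efron ties, Wald CI/p).

    Monotone likelihood (complete separation) is flagged and the CI
    reported as unbounded on the diverging side.
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    cov = np.asarray(covariate, dtype=float)
    if len(np.unique(cov)) < 2:
        raise ValueError("covariate is constant: Cox model not identified")
    if events.sum() == 0:
        raise ValueError("no events observed: Cox model not identified")
    df = pd.DataFrame({"time": times, "event": events, "x": cov})
    cph = CoxPHFitter()
    separation = False
    with warnings.catch_warnings():
        warnings.simplefilter("error", ConvergenceWarning)
        try:
            cph.fit(df, duration_col="time", event_col="event")
        except ConvergenceWarning:
            separation = True
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                cph.fit(df, duration_col="time", event_col="event")
    beta = float(cph.params_["x"])
    s = cph.summary.loc["x"]
    ci_low = float(np.exp(s["coef lower 95%"]))
    ci_high = float(np.exp(s["coef upper 95%"]))
    if separation:
        ci_low, ci_high = (0.0, np.inf)
    return CoxResult(
        hr=float(np.exp(beta)),
        ci_low=ci_low,
        ci_high=ci_high,
        p_value=float(s["p"]),
        beta=beta,
        separation_flag=separation,
    )


def screen_mirnas(
    cohort: pd.DataFrame,
    mirna_list,
    cut_low: float = CUT_LOW_DEFAULT,
    cut_high: float = CUT_HIGH_DEFAULT,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-miRNA stratify + log-rank + Cox association screen.

    Failures on individual miRNAs are logged (warning) and skipped; the
    result is ranked by log-rank p. ``significant`` marks logrank_p < alpha.
    """
    rows = []
    for mid in mirna_list:
        if mid not in cohort.columns:
            warnings.warn(f"{mid}: not in cohort, skipped", RuntimeWarning, stacklevel=2)
            continue
        try:
            strat = stratify(cohort, mid, cut_low, cut_high)
            chi2, p = logrank(cohort["time"], cohort["event"], strat.bins)
            cox = cox_fit(cohort["time"], cohort["event"], strat.z_scores)
        except (ValueError, StratificationError) as exc:
            warnings.warn(f"{mid}: {exc}", RuntimeWarning, stacklevel=2)
            continue
        sizes = strat.bin_sizes
        rows.append(
            {
                "mirna_id": mid,
                "logrank_chi2": chi2,
                "logrank_p": p,
                "cox_hr": cox.hr,
                "cox_ci_low": cox.ci_low,
                "cox_ci_high": cox.ci_high,
                "cox_p": cox.p_value,
                "n_low": sizes["low"],
                "n_mid": sizes["mid"],
                "n_high": sizes["high"],
                "significant": p < alpha,
            }
        )
    out = pd.DataFrame(
        rows,
        columns=[
            "mirna_id", "logrank_chi2", "logrank_p", "cox_hr", "cox_ci_low",
            "cox_ci_high", "cox_p", "n_low", "n_mid", "n_high", "significant",
        ],
    )
    return out.sort_values("logrank_p").reset_index(drop=True)


def km_tables(cohort: pd.DataFrame, strat: Stratification) -> dict[str, pd.DataFrame]:
    """Per-bin KM step-function tables, plot-ready."""
    out = {}
    for b in BIN_ORDER:
        mask = (strat.bins == b).values
        if mask.any():
            out[b] = kaplan_meier(cohort["time"], cohort["event"], mask)
    return out
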