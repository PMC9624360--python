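"""Mature-miRNA differential expression from probeset-summary arrays.

The normalization chain mirrors the standard miRNA 4.0 array workflow after
probeset summarization: the per-array mean of the anti-genomic background
probesets is subtracted from every probeset, negative values are floored to
0, probesets not detected above background (DABG p > alpha) are set to 0,
and values are log2-transformed with a pseudo-count of 1 so exact zeros map
to zero. Only human mature-miRNA probesets are carried forward.

Differential expression between pooled control (CON) and induced (IK1)
samples uses Tukey's HSD: the studentized-range statistic on the CON-vs-IK1
contrast with the within-group mean square pooled over the configured
one-way layout (plain CON vs IK1 by default; a cell_line x condition
four-group layout is available), followed by
Benjamini-Hochberg FDR. A miRNA is called up/down when the pooled mean
difference exceeds ``diff_threshold`` (strictly) and FDR < ``fdr_alpha``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import studentized_range
from statsmodels.stats.multitest import multipletests

HUMAN_MATURE = "human_mature_mirna"
ANTIGENOMIC = "antigenomic"

CONDITIONS = ("CON", "IK1")


class NormalizationError(ValueError):
    pass


class StatisticsError(ValueError):
    pass


@dataclass(frozen=True)
class DEConfig:
    """Thresholds for detection and differential-expression calling.

    dabg_alpha      detection p-value cutoff; p > alpha masks the value to 0
    diff_threshold  minimum |mean_IK1 - mean_CON| in log2 units (strict >)
    fdr_alpha       BH-adjusted p cutoff (strict <)
    grouping        'four_group' pools the within-group variance over the
                    cell_line x condition layout (k = 2 x lines);
                    'two_group' uses the plain CON vs IK1 layout (k = 2)
    """

    dabg_alpha: float = 0.05
    diff_threshold: float = 1.0
    fdr_alpha: float = 0.05
    grouping: str = "two_group"

    def __post_init__(self):
        for name in ("dabg_alpha", "fdr_alpha"):
            v = getattr(self, name)
            if not 0 < v < 1:
                raise ValueError(f"{name} must be in (0,1), got {v}")
        if self.diff_threshold <= 0:
            raise ValueError(f"diff_threshold must be > 0, got {self.diff_threshold}")
        if self.grouping not in ("two_group", "four_group"):
            raise ValueError(f"unknown grouping {self.grouping!r}")


@dataclass
class ProbesetMatrix:
    """Probeset x sample intensities with detection p-values.

    intensities and dabg_p are DataFrames indexed by probeset_id with one
    column per sample_id; probe_class is a Series over the same index with
    values in {human_mature_mirna, antigenomic, other}; samples is the
    sample sheet (sample_id, cell_line, condition, replicate).
    """

    intensities: pd.DataFrame
    dabg_p: pd.DataFrame
    probe_class: pd.Series
    samples: pd.DataFrame

    def __post_init__(self):
        if (self.intensities.values < 0).any():
            raise ValueError("negative intensity: input must be linear-scale >= 0")
        if ((self.dabg_p.values < 0) | (self.dabg_p.values > 1)).any():
            raise ValueError("detection p-values must lie in [0, 1]")
        if not self.intensities.index.equals(self.dabg_p.index) or list(
            self.intensities.columns
        ) != list(self.dabg_p.columns):
            raise ValueError("intensity and detection-p tables must align")
        if set(self.samples["sample_id"]) != set(self.intensities.columns):
            raise ValueError("sample sheet does not match matrix columns")
        if not set(self.samples["condition"]) <= set(CONDITIONS):
            raise ValueError(f"conditions must be in {CONDITIONS}")


@dataclass
class NormalizedMatrix:
    """log2 background-normalized mature-miRNA expression.

    values: miRNA x sample, log2(1 + max(intensity - background, 0)) with
    DABG-masked entries at 0. expressed: per-miRNA flag 'expressed above
    background in both cell lines' (normalized value > 0 in at least half
    of each cell line's samples).
    """

    values: pd.DataFrame
    expressed: pd.Series
    samples: pd.DataFrame = field(repr=False)


def normalize(matrix: ProbesetMatrix, cfg: DEConfig = DEConfig()) -> NormalizedMatrix:
    """Background-subtract, DABG-mask, and log2-transform mature miRNAs."""
    anti = matrix.probe_class == ANTIGENOMIC
    mature = matrix.probe_class == HUMAN_MATURE
    if not anti.any():
        raise NormalizationError("no antigenomic probesets: cannot estimate background")
    if not mature.any():
        raise NormalizationError("no human mature miRNA probesets")

    background = matrix.intensities.loc[anti].mean(axis=0)  # per array
    values = matrix.intensities.loc[mature].sub(background, axis=1).clip(lower=0.0)
    values = values.where(matrix.dabg_p.loc[mature] <= cfg.dabg_alpha, 0.0)
    values = np.log2(1.0 + values)

    # expressed in BOTH cell lines: > 0 in >= half of each line's samples
    expressed = pd.Series(True, index=values.index)
    for _, line_samples in matrix.samples.groupby("cell_line"):
        cols = line_samples["sample_id"].tolist()
        frac = (values[cols] > 0).mean(axis=1)
        expressed &= frac >= 0.5
    return NormalizedMatrix(values=values, expressed=expressed, samples=matrix.samples)


def _group_labels(samples: pd.DataFrame, grouping: str) -> pd.Series:
    if grouping == "two_group":
        return samples.set_index("sample_id")["condition"]
    combined = samples["cell_line"] + ":" + samples["condition"]
    return pd.Series(combined.values, index=samples["sample_id"].values)


def tukey_hsd(normalized: NormalizedMatrix, cfg: DEConfig = DEConfig()) -> pd.DataFrame:
    """Studentized-range test on the pooled CON vs IK1 contrast.

    Returns one row per expressed miRNA with mean_con, mean_ik1,
    difference (= IK1 - CON), q_stat, p_value and a zero_variance flag.
    Flagged rows carry p = 0 when the means differ and p = 1 otherwise.
    """
    samples = normalized.samples
    labels = _group_labels(samples, cfg.grouping)
    values = normalized.values.loc[normalized.expressed]
    values = values[labels.index]  # column order = sample sheet order

    group_counts = labels.value_counts()
    if (group_counts < 2).any():
        bad = group_counts[group_counts < 2].index.tolist()
        raise StatisticsError(f"fewer than 2 replicates in group(s) {bad}")

    k = len(group_counts)
    n_total = len(labels)
    df = n_total - k

    X = values.values
    ssw = np.zeros(X.shape[0])
    for g in group_counts.index:
        cols = (labels == g).values
        xg = X[:, cols]
        ssw += ((xg - xg.mean(axis=1, keepdims=True)) ** 2).sum(axis=1)
    msw = ssw / df

    con_cols = (labels == "CON").values if cfg.grouping == "two_group" else (
        samples.set_index("sample_id").loc[labels.index, "condition"] == "CON"
    ).values
    n1 = int(con_cols.sum())
    n2 = n_total - n1
    mean_con = X[:, con_cols].mean(axis=1)
    mean_ik1 = X[:, ~con_cols].mean(axis=1)
    diff = mean_ik1 - mean_con

    se = np.sqrt(msw / 2.0 * (1.0 / n1 + 1.0 / n2))
    with np.errstate(divide="ignore", invalid="ignore"):
        q = np.abs(diff) / se
    zero_var = msw <= 0
    p = np.ones_like(q)
    ok = ~zero_var
    p[ok] = studentized_range.sf(q[ok], k, df)
    if zero_var.any():
        warnings.warn(
            f"{int(zero_var.sum())} miRNA(s) with zero within-group variance",
            RuntimeWarning,
            stacklevel=2,
        )
        p[zero_var] = np.where(diff[zero_var] != 0, 0.0, 1.0)
        q[zero_var] = np.where(diff[zero_var] != 0, np.inf, 0.0)

    return pd.DataFrame(
        {
            "mirna_id": values.index,
            "mean_con": mean_con,
            "mean_ik1": mean_ik1,
            "difference": diff,
            "q_stat": q,
            "p_value": p,
            "zero_variance": zero_var,
        }
    ).set_index("mirna_id")


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order."""
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return p
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def call_de(stats: pd.DataFrame, cfg: DEConfig = DEConfig()) -> pd.DataFrame:
    """Attach FDR and direction calls; sort by fdr then |difference|."""
    out = stats.copy()
    out["fdr"] = bh_adjust(out["p_value"].values)
    significant = out["fdr"] < cfg.fdr_alpha
    out["direction"] = "ns"
    out.loc[significant & (out["difference"] > cfg.diff_threshold), "direction"] = "up"
    out.loc[significant & (out["difference"] < -cfg.diff_threshold), "direction"] = "down"
    out = out.sort_values(
        ["fdr", "difference"], key=lambda s: s if s.name == "fdr" else -s.abs()
    )
    return out


def run_de(matrix: ProbesetMatrix, cfg: DEConfig = DEConfig()) -> pd.DataFrame:
    """normalize -> tukey_hsd -> call_de in one step."""
    normalized = normalize(matrix, cfg)
    return call_de(tukey_hsd(normalized, cfg), cfg)


def ma_table(normalized: NormalizedMatrix, de: pd.DataFrame) -> pd.DataFrame:
    """Mean expression vs difference table for MA-style plotting."""
    mean_expr = normalized.values.loc[de.index].mean(axis=1)
    return pd.DataFrame(
        {
            "mean_expression": mean_expr,
            "difference": de["difference"],
            "direction": de["direction"],
        }
    )
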