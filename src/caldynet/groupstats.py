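"""Scalar assays and group-comparison statistics.

Covers the small computations reported alongside the imaging analysis:
cell-viability percentages from dead/total nucleus counts, relative gene
expression by the delta-delta-Ct method against a housekeeping gene, and
the group-comparison conventions (Mann-Whitney U, one-way ANOVA with
Tukey's post hoc, significance at p < 0.05, median [Q1; Q3] reporting).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ALPHA",
    "viability_pct",
    "ddct_fold_change",
    "compare_groups",
    "MedianIQR",
    "median_iqr",
]

ALPHA = 0.05


# ---------------------------------------------------------------------------
# viability
# ---------------------------------------------------------------------------

def viability_pct(counts: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-field viability and group summaries.

    *counts* needs columns ``dead`` and ``total`` (nucleus counts per
    imaging field) and optionally ``group``; viability is
    100 x (1 - dead/total).  Returns ``(per_field, summary)`` where the
    summary holds mean viability and its standard error per group.
    """
    df = counts.copy()
    if (df["total"] <= 0).any():
        raise ValueError("total nucleus counts must be positive")
    if (df["dead"] < 0).any() or (df["dead"] > df["total"]).any():
        raise ValueError("dead counts must satisfy 0 <= dead <= total")
    df["viable_pct"] = 100.0 * (1.0 - df["dead"] / df["total"])
    if "group" not in df.columns:
        df["group"] = "all"
    summary = (
        df.groupby("group")["viable_pct"]
        .agg(mean="mean", sem=lambda v: stats.sem(v, ddof=1) if len(v) > 1 else np.nan,
             n="size")
        .reset_index()
    )
    return df, summary


# ---------------------------------------------------------------------------
# relative qPCR quantification
# ---------------------------------------------------------------------------

def ddct_fold_change(
    ct: pd.DataFrame,
    target_gene: str,
    reference_gene: str,
    control_group: str,
) -> pd.DataFrame:
    """Relative expression by the delta-delta-Ct method.

    *ct* needs columns ``sample_id, group, gene, ct``.  Per sample,
    dCt = Ct(target) - Ct(reference); per group,
    ddCt = mean dCt(group) - mean dCt(control) and
    fold change = 2**(-ddCt), so the control group is 1 by construction.
    Per-sample fold changes (against the control-group mean dCt) are used
    for the SEM column.
    """
    required = {"sample_id", "group", "gene", "ct"}
    if not required.issubset(ct.columns):
        raise ValueError(f"ct table must have columns {sorted(required)}")
    wide = ct.pivot_table(index=["sample_id", "group"], columns="gene",
                          values="ct", aggfunc="mean")
    for gene in (target_gene, reference_gene):
        if gene not in wide.columns:
            raise ValueError(f"gene {gene!r} missing from Ct table")
    missing_ref = wide.index[wide[reference_gene].isna()]
    if len(missing_ref):
        sample = missing_ref[0][0]
        raise ValueError(
            f"reference gene {reference_gene!r} not measured for sample {sample!r}"
        )
    wide = wide.dropna(subset=[target_gene])
    dct = (wide[target_gene] - wide[reference_gene]).rename("dct").reset_index()
    if control_group not in set(dct["group"]):
        raise ValueError(f"control group {control_group!r} not present")

    control_mean = dct.loc[dct["group"] == control_group, "dct"].mean()
    dct["fold_change_sample"] = 2.0 ** (-(dct["dct"] - control_mean))
    out = (
        dct.groupby("group")
        .agg(
            mean_dct=("dct", "mean"),
            n=("dct", "size"),
            fold_change_sem=(
                "fold_change_sample",
                lambda v: stats.sem(v, ddof=1) if len(v) > 1 else np.nan,
            ),
        )
        .reset_index()
    )
    out["ddct"] = out["mean_dct"] - control_mean
    out["fold_change"] = 2.0 ** (-out["ddct"])
    return out[["group", "n", "ddct", "fold_change", "fold_change_sem"]]


# ---------------------------------------------------------------------------
# group comparisons
# ---------------------------------------------------------------------------

def compare_groups(
    data: pd.DataFrame,
    test: str = "mann_whitney",
    value_col: str = "value",
    group_col: str = "group",
) -> pd.DataFrame:
    """Pairwise group comparisons.

    ``test`` is ``"mann_whitney"`` (two-sided U test per pair) or
    ``"anova_tukey"`` (one-way ANOVA; the reported pairwise p-values come
    from Tukey's HSD).  Each group needs at least 3 observations.
    Degenerate comparisons where all observations are identical get
    p = 1 with a warning.  Significance is flagged at p < 0.05.
    """
    groups = {g: np.asarray(v[value_col], float)
              for g, v in data.groupby(group_col)}
    labels = sorted(groups)
    if len(labels) < 2:
        raise ValueError("need at least 2 groups")
    for g, v in groups.items():
        if len(v) < 3:
            raise ValueError(f"group {g!r} has fewer than 3 observations")

    rows = []
    if test == "mann_whitney":
        for i, a in enumerate(labels):
            for b in labels[i + 1:]:
                va, vb = groups[a], groups[b]
                if np.ptp(np.concatenate([va, vb])) == 0:
                    warnings.warn(f"groups {a!r}/{b!r} are degenerate; p set to 1")
                    stat, p = float("nan"), 1.0
                else:
                    res = stats.mannwhitneyu(va, vb, alternative="two-sided")
                    stat, p = float(res.statistic), float(res.pvalue)
                rows.append((a, b, stat, p))
    elif test == "anova_tukey":
        samples = [groups[g] for g in labels]
        if np.ptp(np.concatenate(samples)) == 0:
            warnings.warn("all observations identical; p set to 1")
            for i, a in enumerate(labels):
                for b in labels[i + 1:]:
                    rows.append((a, b, float("nan"), 1.0))
        else:
            tukey = stats.tukey_hsd(*samples)
            for i, a in enumerate(labels):
                for j in range(i + 1, len(labels)):
                    rows.append(
                        (a, labels[j],
                         float(tukey.statistic[i][j]),
                         float(tukey.pvalue[i][j]))
                    )
    else:
        raise ValueError("test must be 'mann_whitney' or 'anova_tukey'")

    out = pd.DataFrame(rows, columns=["group_a", "group_b", "statistic", "p_value"])
    out["test"] = test
    out["significant"] = out["p_value"] < ALPHA
    return out


# ---------------------------------------------------------------------------
# median [Q1; Q3] reporting
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MedianIQR:
    median: float
    q1: float
    q3: float

    def __str__(self) -> str:
        fmt = lambda v: f"{v:.4g}"
        return f"{fmt(self.median)} [{fmt(self.q1)}; {fmt(self.q3)}]"


def median_iqr(values) -> MedianIQR:
    """Median with the second and third quartiles (linear-interpolation
    convention), formatted as e.g. ``0.5 [0.33; 0.68]``."""
    values = np.asarray(values, float)
    values = values[np.isfinite(values)]
    if values.size == 0:
        raise ValueError("need at least one finite value")
    q1, med, q3 = np.percentile(values, [25, 50, 75])
    return MedianIQR(float(med), float(q1), float(q3))
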