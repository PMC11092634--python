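"""Nuclear-translocation scoring from a reporter-stain intensity table.

Reporter translocation into the nucleus (e.g. β-catenin after Wnt-pathway
activation) is scored as the per-well mean nuclear intensity, and each
dose group is compared with the vehicle group by a two-sided Wilcoxon
rank-sum test.  Wells, not cells, are the statistical unit by default —
comparing cells directly treats correlated cells within a well as
independent and is anti-conservative.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)


def well_summaries(
    table: pd.DataFrame,
    intensity_col: str,
    group_cols: tuple[str, ...] = (
        "Metadata_Chemical", "Metadata_Concentration",
        "Metadata_Plate", "Metadata_Well",
    ),
) -> pd.DataFrame:
    """Per-well mean nuclear intensity for the reporter stain.

    One row per well, grouped by treatment x concentration; wells without
    cells simply do not appear (a warning is logged when the input has no
    rows for some expected group, which cannot be detected here).
    """
    if intensity_col not in table.columns:
        raise ValueError(f"intensity column {intensity_col!r} not in table")
    sub = table.dropna(subset=[intensity_col])
    n_dropped = len(table) - len(sub)
    if n_dropped:
        logger.warning("well_summaries: dropped %d cells with missing intensity", n_dropped)
    out = (
        sub.groupby(list(group_cols), sort=True, observed=True)[intensity_col]
        .agg(mean_intensity="mean", n_cells="size")
        .reset_index()
    )
    return out


def test_vs_control(
    summaries: pd.DataFrame,
    per_cell: bool = False,
    value_col: str = "mean_intensity",
) -> pd.DataFrame:
    """Two-sided Wilcoxon rank-sum test of each dose group against vehicle.

    Vehicle wells are rows with ``Metadata_Concentration == 0``.  The
    exact null distribution is enumerated for small tie-free samples and a
    tie-corrected normal approximation is used otherwise.  Groups with
    fewer than 2 wells get an undefined p-value with a warning.
    ``per_cell=True`` is available for comparison but is anti-conservative
    (cells within a well are correlated).
    """
    control = summaries.loc[
        summaries["Metadata_Concentration"] == 0, value_col
    ].to_numpy(dtype=float)
    if control.size < 2:
        raise ValueError("need >=2 vehicle wells for a rank-sum comparison")
    rows = []
    treated = summaries[summaries["Metadata_Concentration"] > 0]
    for (chem, conc), grp in treated.groupby(
        ["Metadata_Chemical", "Metadata_Concentration"], sort=True, observed=True
    ):
        vals = grp[value_col].to_numpy(dtype=float)
        if vals.size < 2:
            logger.warning(
                "test_vs_control: %s @ %g µM has <2 wells; p undefined", chem, conc
            )
            p = np.nan
        else:
            p = rank_sum_p(control, vals)
        rows.append(
            {
                "chemical": chem,
                "concentration": conc,
                "n_control": control.size,
                "n_dose": vals.size,
                "median_control": float(np.median(control)),
                "median_dose": float(np.median(vals)) if vals.size else np.nan,
                "p_value": p,
            }
        )
    return pd.DataFrame(rows)


def rank_sum_p(x, y) -> float:
    """Two-sided Wilcoxon/Mann-Whitney p for two samples.

    Exact enumeration when both samples are small (<= 12) and tie-free;
    tie-corrected normal approximation otherwise.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if np.array_equal(np.sort(x), np.sort(y)):
        return 1.0
    pooled = np.concatenate([x, y])
    tie_free = np.unique(pooled).size == pooled.size
    method = "exact" if (tie_free and max(x.size, y.size) <= 12) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return float(res.pvalue)


def plot_boxes(summaries: pd.DataFrame, value_col: str = "mean_intensity", ax=None):
    """Box plot of per-well summaries by treatment group."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(constrained_layout=True)
    groups, labels = [], []
    for (chem, conc), grp in summaries.groupby(
        ["Metadata_Chemical", "Metadata_Concentration"], sort=True, observed=True
    ):
        groups.append(grp[value_col].to_numpy(dtype=float))
        labels.append(f"{chem}\n{conc:g}")
    ax.boxplot(groups, tick_labels=labels)
    ax.set_ylabel("mean nuclear intensity")
    ax.tick_params(axis="x", labelsize=7)
    return ax
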