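"""Signed morphological fingerprints, chemical clustering and BMC
accumulation curves.

A chemical's fingerprint is the vector over features with entries +1/-1
for features showing a significant concentration-dependent increase or
decrease (prefilter pass, defined benchmark concentration, BMC no larger
than the highest tested dose) and 0 otherwise.  Features null for every
chemical are pruned; chemicals are compared by hierarchical clustering of
the signed columns, and per-chemical bioactivity is summarized as the
accumulation of features with increasing BMC.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist


def build_fingerprint(
    bmc_tables: dict[str, pd.DataFrame],
    max_doses: dict[str, float] | None = None,
    prune: bool = True,
) -> pd.DataFrame:
    """Assemble the signed features x chemicals matrix from per-chemical
    BMC tables (output of :func:`paintbench.doseresponse.run_chemical`).

    An entry is nonzero iff the feature passed the prefilter, has a
    defined BMC, and the BMC does not exceed the chemical's highest tested
    dose (``within_range``, or recomputed against ``max_doses`` when
    given).  All-zero rows are pruned by default; ``prune=False`` keeps
    the full feature namespace as rows, the appropriate enrichment
    universe when only a few chemicals were screened (with two chemicals
    a pruned universe contains nothing null for both, so a real shared
    block reads as depletion).  Rows and columns are sorted
    lexicographically.  The per-chemical max dose is kept in ``.attrs``.
    """
    chems = sorted(bmc_tables)
    all_feats: set[str] = set()
    for chem in chems:
        tab = bmc_tables[chem]
        if tab["feature"].duplicated().any():
            dup = tab.loc[tab["feature"].duplicated(), "feature"].iloc[0]
            raise ValueError(f"duplicated feature name {dup!r} in table for {chem}")
        all_feats.update(tab["feature"])
    feats = sorted(all_feats)
    mat = pd.DataFrame(0, index=feats, columns=chems, dtype=int)
    used_max: dict[str, float] = {}
    for chem in chems:
        tab = bmc_tables[chem]
        if max_doses is not None and chem in max_doses:
            dose_max = float(max_doses[chem])
            qualifies = (
                tab["prefilter_pass"].astype(bool)
                & tab["bmc"].notna()
                & (tab["bmc"] <= dose_max)
            )
            used_max[chem] = dose_max
        else:
            qualifies = (
                tab["prefilter_pass"].astype(bool)
                & tab["bmc"].notna()
                & tab["within_range"].astype(bool)
            )
            used_max[chem] = float(tab.attrs.get("dose_max", math.nan))
        sub = tab.loc[qualifies]
        signs = np.where(sub["direction"] == "UP", 1, -1)
        mat.loc[sub["feature"].to_numpy(), chem] = signs
    if prune:
        mat = mat.loc[(mat != 0).any(axis=1)]
    mat.index.name = "feature"
    mat.attrs["max_doses"] = used_max
    return mat


def cluster_chemicals(
    fp: pd.DataFrame, distance: str = "euclidean", linkage: str = "complete"
) -> tuple[np.ndarray, list[str]]:
    """Agglomerative clustering of the fingerprint columns.

    Returns the scipy linkage matrix and the leaf order (chemical names).
    Distances are computed on the signed entries; ``distance`` may also be
    "jaccard", computed on the nonzero support.
    """
    if fp.shape[1] < 2:
        raise ValueError("clustering needs at least two chemicals")
    X = fp.to_numpy(dtype=float).T
    if distance == "jaccard":
        X = (X != 0).astype(float)
    D = pdist(X, metric=distance)
    Z = hierarchy.linkage(D, method=linkage)
    order = hierarchy.leaves_list(Z)
    return Z, [fp.columns[i] for i in order]


def dendrogram_newick(Z: np.ndarray, labels: list[str]) -> str:
    """Serialize a scipy linkage matrix as a Newick tree string."""
    tree = hierarchy.to_tree(Z)

    def walk(node) -> str:
        if node.is_leaf():
            return labels[node.id]
        left, right = walk(node.get_left()), walk(node.get_right())
        dl = node.dist - node.get_left().dist
        dr = node.dist - node.get_right().dist
        return f"({left}:{dl:g},{right}:{dr:g})"

    return walk(tree) + ";"


def accumulation_curve(
    bmc_values, dose_max: float
) -> list[tuple[float, int]]:
    """Ordered (BMC, cumulative feature count) pairs for a step plot.

    BMCs above the highest tested dose are filtered out; remaining values
    are sorted ascending (stable) with ranks 1..m, so chemicals with more
    features at lower BMCs read as more bioactive.
    """
    vals = [float(v) for v in np.asarray(bmc_values, dtype=float) if math.isfinite(v)]
    vals = sorted(v for v in vals if v <= dose_max)
    return [(v, i + 1) for i, v in enumerate(vals)]


# ---------------------------------------------------------------------------
# plots


def plot_heatmap(fp: pd.DataFrame, ax=None):
    """Signed fingerprint heatmap (blue = DOWN, red = UP)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(
            figsize=(max(4, 0.5 * fp.shape[1]), 6), constrained_layout=True
        )
    ax.imshow(fp.to_numpy(), aspect="auto", cmap="bwr", vmin=-1, vmax=1)
    ax.set_xticks(range(fp.shape[1]), fp.columns, rotation=90, fontsize=7)
    ax.set_yticks([])
    ax.set_xlabel("chemical")
    ax.set_ylabel(f"{fp.shape[0]} features")
    return ax


def plot_accumulation(curves: dict[str, list[tuple[float, int]]], ax=None):
    """Step plot of BMC accumulation curves, one line per chemical."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(constrained_layout=True)
    for chem, curve in sorted(curves.items()):
        if not curve:
            continue
        x, y = zip(*curve)
        ax.step(x, y, where="post", label=chem)
    ax.set_xscale("log")
    ax.set_xlabel("benchmark concentration (µM)")
    ax.set_ylabel("cumulative features")
    ax.legend(fontsize=7)
    return ax
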