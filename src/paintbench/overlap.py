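"""Fingerprint-overlap enrichment between chemical pairs.

Two chemicals that perturb the same biology should mark overlapping sets
of features significant.  For each pair, the overlap between their
significant-feature sets (nonzero fingerprint entries, sign ignored) is
scored against the hypergeometric null with a one-sided Fisher exact
test, overall and stratified by compartment (Cells/Cytoplasm/Nuclei) and
stain (DNA/RNA/ER/Mito/AGP).  Compartment strata partition the feature
universe; stain strata may overlap (two-stain colocalization features
belong to both) and exclude stain-free shape features.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import pandas as pd
from scipy import stats

from .profiles import COMPARTMENTS, STAINS, parse_feature_name


@dataclass(frozen=True)
class OverlapCounts:
    """2x2 overlap table between two chemicals within one stratum."""

    stratum: str
    n_universe: int
    k_a: int  # significant features of A in the stratum
    k_b: int  # significant features of B
    k_overlap: int  # shared

    def __post_init__(self):
        ok = (
            0 <= self.k_overlap <= min(self.k_a, self.k_b)
            and max(self.k_a, self.k_b) <= self.n_universe
            and self.k_a + self.k_b - self.k_overlap <= self.n_universe
        )
        if not ok:
            raise ValueError(f"inconsistent overlap counts: {self}")


@dataclass(frozen=True)
class OverlapResult:
    counts: OverlapCounts
    p_value: float


def stratify(fp: pd.DataFrame, by: str = "all") -> dict[str, list[str]]:
    """Map stratum label -> feature subset of the fingerprint rows.

    ``by`` is "all" (single stratum with every row), "compartment"
    (partition) or "stain" (possibly overlapping, stain-free features in
    no stratum).
    """
    feats = list(fp.index)
    if by == "all":
        return {"ALL": feats}
    out: dict[str, list[str]] = {}
    if by == "compartment":
        for label in COMPARTMENTS:
            out[label] = []
        for f in feats:
            key = parse_feature_name(f)
            out[key.compartment].append(f)
    elif by == "stain":
        for label in STAINS:
            out[label] = []
        for f in feats:
            key = parse_feature_name(f)
            for s in key.stains:
                out[s].append(f)
    else:
        raise ValueError(f"unknown stratification {by!r}")
    return out


def pair_overlap(
    fp: pd.DataFrame,
    chem_a: str,
    chem_b: str,
    stratum_features: list[str],
    stratum: str = "ALL",
) -> OverlapCounts:
    """Overlap counts for one chemical pair on one stratum's universe.

    Membership is sign-agnostic: up- and down-regulated features both
    count as significant.
    """
    for chem in (chem_a, chem_b):
        if chem not in fp.columns:
            raise ValueError(f"chemical {chem!r} not in fingerprint")
    sub = fp.loc[stratum_features]
    sig_a = set(sub.index[sub[chem_a] != 0])
    sig_b = set(sub.index[sub[chem_b] != 0])
    return OverlapCounts(
        stratum=stratum,
        n_universe=len(stratum_features),
        k_a=len(sig_a),
        k_b=len(sig_b),
        k_overlap=len(sig_a & sig_b),
    )


def fisher_one_sided(c: OverlapCounts) -> float:
    """One-sided enrichment p-value: P(X >= k_overlap) for
    X ~ Hypergeometric(N, K_A, K_B).

    Evaluated via the log-space survival function of the hypergeometric
    distribution, stable for universes of 10^4 features and beyond.
    """
    p = float(stats.hypergeom.sf(c.k_overlap - 1, c.n_universe, c.k_a, c.k_b))
    return min(max(p, 5e-324), 1.0)


def compare_all(
    fp: pd.DataFrame,
    pairs: list[tuple[str, str]] | None = None,
    strata: tuple[str, ...] = ("all", "compartment", "stain"),
    universe: str = "stratum",
    sign_aware: bool = False,
    bh_adjust: bool = False,
) -> pd.DataFrame:
    """Overlap enrichment for chemical pairs across strata.

    One row per (pair, stratum) with the Venn triple (A-only, shared,
    B-only) and the one-sided p-value.  ``universe="global"`` uses the
    full fingerprint row count as N for every stratum instead of the
    stratum size.  ``sign_aware=True`` additionally requires matching
    direction for a feature to count as shared.  Raw p-values by default;
    ``bh_adjust`` adds a Benjamini-Hochberg column.
    """
    if fp.empty:
        raise ValueError("empty fingerprint")
    if pairs is None:
        pairs = list(itertools.combinations(sorted(fp.columns), 2))
    rows = []
    for by in strata:
        for label, feats in stratify(fp, by).items():
            for a, b in pairs:
                if sign_aware:
                    sub = fp.loc[feats]
                    sig_a = set(sub.index[sub[a] != 0])
                    sig_b = set(sub.index[sub[b] != 0])
                    shared = {
                        f for f in sig_a & sig_b if sub.at[f, a] == sub.at[f, b]
                    }
                    c = OverlapCounts(label, len(feats), len(sig_a), len(sig_b), len(shared))
                else:
                    c = pair_overlap(fp, a, b, feats, stratum=label)
                if universe == "global":
                    c = OverlapCounts(
                        label, fp.shape[0], c.k_a, c.k_b, c.k_overlap
                    )
                rows.append(
                    {
                        "chem_a": a, "chem_b": b,
                        "strat_by": by, "stratum": c.stratum,
                        "n_universe": c.n_universe,
                        "a_only": c.k_a - c.k_overlap,
                        "shared": c.k_overlap,
                        "b_only": c.k_b - c.k_overlap,
                        "p_value": fisher_one_sided(c),
                    }
                )
    out = pd.DataFrame(rows).sort_values(
        ["strat_by", "stratum", "chem_a", "chem_b"], kind="stable"
    ).reset_index(drop=True)
    if bh_adjust:
        out["p_bh"] = _benjamini_hochberg(out["p_value"].to_numpy())
    return out


def _benjamini_hochberg(p):
    import numpy as np

    p = np.asarray(p, dtype=float)
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / (np.arange(m) + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(adj, 1.0)
    return out
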