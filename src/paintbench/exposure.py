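"""Comparison of in vitro benchmark concentrations with population
exposure-biomarker levels.

Biomarker concentrations (blood or urine, mass/volume units) are converted
to molarity with user-supplied molecular weights and compared against each
chemical's range of within-range BMCs.  Overlap between the two ranges
flags chemicals whose morphological bioactivity occurs at human-relevant
concentrations.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

#: mass-per-litre in grams for each accepted concentration unit
_UNIT_TO_G_PER_L = {
    "ug/L": 1e-6,
    "µg/L": 1e-6,
    "ng/mL": 1e-6,  # numerically identical to µg/L
    "mg/L": 1e-3,
}


def to_molar(conc: float, unit: str, mw: float) -> float:
    """Convert a mass/volume concentration to mol/L.

    ``unit`` must be one of µg/L (also spelled ug/L), ng/mL or mg/L;
    ``mw`` is the molecular weight in g/mol.
    """
    if unit not in _UNIT_TO_G_PER_L:
        raise ValueError(
            f"unsupported unit {unit!r}; expected one of {sorted(_UNIT_TO_G_PER_L)}"
        )
    if mw <= 0:
        raise ValueError(f"molecular weight must be positive, got {mw}")
    if conc < 0:
        raise ValueError(f"concentration must be non-negative, got {conc}")
    return conc * _UNIT_TO_G_PER_L[unit] / mw


def biomarker_molarities(records: pd.DataFrame) -> pd.DataFrame:
    """Add a ``molar`` column to a biomarker table.

    Expected columns: chemical, biomarker, matrix, concentration, unit,
    molecular_weight.
    """
    required = {"chemical", "concentration", "unit", "molecular_weight"}
    missing = required - set(records.columns)
    if missing:
        raise ValueError(f"biomarker table missing columns: {sorted(missing)}")
    out = records.copy()
    out["molar"] = [
        to_molar(c, u, m)
        for c, u, m in zip(
            out["concentration"], out["unit"], out["molecular_weight"]
        )
    ]
    return out


def overlap_report(bmc_um, biomarker_molar) -> dict:
    """Compare a chemical's within-range BMCs (µM) to population biomarker
    molarities (mol/L).

    Returns range intersection, the fraction of biomarker values at or
    above the minimum BMC, and the paired ranges for a comparative plot.
    An empty BMC set yields ``overlap=None`` (undefined) rather than an
    error.
    """
    bio = np.asarray(list(biomarker_molar), dtype=float)
    if bio.size == 0:
        raise ValueError("no biomarker values supplied")
    bmc_molar = np.asarray(list(bmc_um), dtype=float) * 1e-6
    bmc_molar = bmc_molar[np.isfinite(bmc_molar)]
    if bmc_molar.size == 0:
        return {
            "overlap": None,
            "fraction_above_min_bmc": None,
            "bmc_range_molar": None,
            "biomarker_range_molar": (float(bio.min()), float(bio.max())),
        }
    lo_b, hi_b = float(bmc_molar.min()), float(bmc_molar.max())
    lo_x, hi_x = float(bio.min()), float(bio.max())
    intersects = (lo_b <= hi_x) and (lo_x <= hi_b)
    frac = float(np.mean(bio >= lo_b))
    return {
        "overlap": bool(intersects),
        "fraction_above_min_bmc": frac,
        "bmc_range_molar": (lo_b, hi_b),
        "biomarker_range_molar": (lo_x, hi_x),
    }


def exposure_table(
    bmc_tables: dict[str, pd.DataFrame], biomarkers: pd.DataFrame
) -> pd.DataFrame:
    """Per-chemical exposure/BMC overlap table.

    ``bmc_tables`` maps chemical -> BMC table (within-range rows supply
    the in vitro range); ``biomarkers`` is the raw biomarker table.
    Chemicals without biomarker records are skipped.
    """
    bio = biomarker_molarities(biomarkers)
    rows = []
    for chem, tab in sorted(bmc_tables.items()):
        vals = bio.loc[bio["chemical"] == chem, "molar"]
        if vals.empty:
            continue
        bmc_um = tab.loc[tab["within_range"].astype(bool), "bmc"].dropna()
        rep = overlap_report(bmc_um, vals)
        rows.append(
            {
                "chemical": chem,
                "n_bmc": int(bmc_um.size),
                "n_biomarker": int(vals.size),
                "overlap": rep["overlap"],
                "fraction_above_min_bmc": rep["fraction_above_min_bmc"],
                "bmc_min_molar": rep["bmc_range_molar"][0] if rep["bmc_range_molar"] else np.nan,
                "bmc_max_molar": rep["bmc_range_molar"][1] if rep["bmc_range_molar"] else np.nan,
                "bio_min_molar": rep["biomarker_range_molar"][0],
                "bio_max_molar": rep["biomarker_range_molar"][1],
            }
        )
    return pd.DataFrame(rows)


def plot_ranges(table: pd.DataFrame, ax=None):
    """Comparative bar plot of biomarker vs BMC molarity ranges."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(constrained_layout=True)
    y = np.arange(len(table))
    for i, row in table.reset_index(drop=True).iterrows():
        ax.plot(
            [row["bio_min_molar"], row["bio_max_molar"]], [i - 0.15] * 2,
            lw=6, color="tab:blue",
            label="biomarker" if i == 0 else None,
        )
        if np.isfinite(row["bmc_min_molar"]):
            ax.plot(
                [row["bmc_min_molar"], row["bmc_max_molar"]], [i + 0.15] * 2,
                lw=6, color="tab:orange",
                label="BMC" if i == 0 else None,
            )
    ax.set_yticks(y, table["chemical"])
    ax.set_xscale("log")
    ax.set_xlabel("concentration (mol/L)")
    ax.legend()
    return ax
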