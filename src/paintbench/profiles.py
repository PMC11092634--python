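"""Single-cell feature QC, plate normalization and per-well aggregation.

The stage takes a merged single-cell table (one row per segmented cell,
``Metadata_*`` columns plus compartment-prefixed feature columns) and turns
it into per-well morphological profiles:

1. drop uninformative and Costes colocalization features, then incomplete
   cells (:func:`clean_features`);
2. flag cytotoxic (chemical, concentration) pairs from raw well cell counts
   (:func:`flag_cytotoxic`);
3. robust per-plate normalization to the matching vehicle controls
   (:func:`fit_normalization` / :func:`robustize`);
4. variance-stabilizing generalized-log transform (:func:`glog_transform`);
5. per-well median aggregation, excluding cytotoxic doses
   (:func:`aggregate_wells`).

Concentrations are in µM throughout; vehicle wells carry concentration 0.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

COMPARTMENTS = ("Cells", "Cytoplasm", "Nuclei")
STAINS = ("DNA", "RNA", "ER", "Mito", "AGP")

#: Imaging-channel token -> stain. Tokens already named by stain map to
#: themselves; microscope dye names map to the stain they report.
DEFAULT_CHANNEL_MAP: dict[str, str] = {
    "DNA": "DNA",
    "RNA": "RNA",
    "ER": "ER",
    "Mito": "Mito",
    "AGP": "AGP",
    "Hoechst": "DNA",
    "Syto14": "RNA",
    "ConA": "ER",
    "MitoTracker": "Mito",
    "Phalloidin": "AGP",
    "WGA": "AGP",
}

#: Measurement classes that derive from an imaging channel and are expected
#: to carry at least one stain token in their name.
_STAIN_BEARING_GROUPS = {
    "Intensity",
    "Texture",
    "Granularity",
    "Correlation",
    "RadialDistribution",
}

METADATA_COLUMNS = (
    "Metadata_Plate",
    "Metadata_Well",
    "Metadata_Chemical",
    "Metadata_Concentration",
    "Metadata_Vehicle",
    "Metadata_Replicate",
)


@dataclass(frozen=True)
class FeatureKey:
    """Parsed identity of one morphological feature column."""

    compartment: str
    group: str
    stains: tuple[str, ...]
    raw_name: str

    @property
    def is_costes(self) -> bool:
        return "Costes" in self.raw_name.split("_")


def parse_feature_name(
    raw: str, channel_map: dict[str, str] | None = None
) -> FeatureKey:
    """Parse a ``Compartment_Group_..._Channel`` feature column name.

    Stain-free measurement classes (AreaShape, Neighbors, ...) yield an
    empty stain tuple; Correlation features may carry two stains.  Unknown
    channel tokens in a stain-bearing class produce an empty stain tuple
    and a logged warning.

    Raises
    ------
    ValueError
        If the compartment token is not one of Cells/Cytoplasm/Nuclei.
    """
    channel_map = DEFAULT_CHANNEL_MAP if channel_map is None else channel_map
    tokens = raw.split("_")
    if len(tokens) < 2 or tokens[0] not in COMPARTMENTS:
        raise ValueError(
            f"feature column {raw!r}: unknown compartment token "
            f"{tokens[0] if tokens else raw!r} (expected one of {COMPARTMENTS})"
        )
    compartment, group = tokens[0], tokens[1]
    stains: list[str] = []
    for tok in tokens[2:]:
        stain = channel_map.get(tok)
        if stain is not None and stain not in stains:
            stains.append(stain)
    if not stains and group in _STAIN_BEARING_GROUPS:
        logger.warning(
            "feature %r: no recognized channel token; treating as stain-free", raw
        )
    return FeatureKey(compartment, group, tuple(stains), raw)


def feature_columns(cells: pd.DataFrame) -> list[str]:
    """Feature columns of a single-cell table = all non-reserved columns."""
    reserved = set(METADATA_COLUMNS) | {"ImageNumber", "ObjectNumber"}
    return [c for c in cells.columns if c not in reserved and not c.startswith("Metadata_")]


def clean_features(cells: pd.DataFrame) -> pd.DataFrame:
    """Remove uninformative features, Costes features, then incomplete cells.

    Order matters and is fixed: (1) features missing for every cell are
    dropped, (2) Costes colocalization features are dropped wholesale (they
    are frequently missing in a majority of cells), (3) any remaining cell
    row with a missing value is dropped.  The output is complete.

    Raises
    ------
    ValueError
        If nothing survives (zero cells or zero features).
    """
    feats = feature_columns(cells)
    if not feats:
        raise ValueError("table contains no feature columns")

    all_missing = [c for c in feats if cells[c].isna().all()]
    costes = [c for c in feats if "Costes" in c.split("_") and c not in all_missing]
    out = cells.drop(columns=all_missing + costes)
    kept = [c for c in feats if c not in all_missing and c not in costes]
    if not kept:
        raise ValueError("all feature columns removed during cleaning")

    complete = out[kept].notna().all(axis=1)
    n_dropped_cells = int((~complete).sum())
    out = out.loc[complete]
    logger.info(
        "clean_features: dropped %d all-missing features, %d Costes features, "
        "%d incomplete cells; %d cells x %d features remain",
        len(all_missing), len(costes), n_dropped_cells, len(out), len(kept),
    )
    if out.empty:
        raise ValueError("all cells removed during cleaning")
    return out.reset_index(drop=True)


def well_counts(cells: pd.DataFrame) -> pd.DataFrame:
    """Per-well raw cell counts with well metadata (one row per well)."""
    keys = list(METADATA_COLUMNS)
    counts = (
        cells.groupby(keys, sort=True, observed=True)
        .size()
        .rename("cell_count")
        .reset_index()
    )
    return counts


def flag_cytotoxic(
    counts: pd.DataFrame, threshold: float = 0.25
) -> set[tuple[str, float]]:
    """Flag (chemical, concentration) pairs whose mean cell count falls
    below ``threshold`` times the matching vehicle-well mean.

    The comparison is strict (``<``): a dose at exactly 25% of the control
    mean is retained.  Ratios are computed per plate against vehicle wells
    of the chemical's own solvent and averaged with equal plate weights for
    chemicals spanning plates.

    Raises
    ------
    ValueError
        If a treated plate lacks matching vehicle wells, or the vehicle
        mean is zero.
    """
    if not 0 < threshold < 1:
        raise ValueError(f"threshold must be in (0, 1), got {threshold}")
    treated = counts[counts["Metadata_Concentration"] > 0]
    vehicle = counts[counts["Metadata_Concentration"] == 0]
    veh_means = (
        vehicle.groupby(["Metadata_Plate", "Metadata_Vehicle"], observed=True)[
            "cell_count"
        ].mean()
    )

    flagged: set[tuple[str, float]] = set()
    grouped = treated.groupby(
        ["Metadata_Chemical", "Metadata_Concentration"], observed=True
    )
    for (chem, conc), grp in grouped:
        ratios = []
        for (plate, veh), sub in grp.groupby(
            ["Metadata_Plate", "Metadata_Vehicle"], observed=True
        ):
            if (plate, veh) not in veh_means.index:
                raise ValueError(
                    f"no {veh} vehicle wells on plate {plate} "
                    f"(needed for {chem} @ {conc} µM)"
                )
            vmean = veh_means.loc[(plate, veh)]
            if vmean <= 0:
                raise ValueError(
                    f"vehicle mean cell count is {vmean} on plate {plate}"
                )
            ratios.append(sub["cell_count"].mean() / vmean)
        if float(np.mean(ratios)) < threshold:
            flagged.add((chem, float(conc)))
    if flagged:
        logger.info("flag_cytotoxic: %d cytotoxic (chemical, dose) pairs", len(flagged))
    return flagged


@dataclass
class NormalizationParams:
    """Per-(plate, vehicle, feature) robust location/scale from vehicle wells.

    ``table`` is indexed by (plate, vehicle) with a two-level column index
    (feature, {"median", "mad"}); ``mad`` already carries the 1.4826
    normal-consistency factor.  ``dropped`` lists features removed globally
    because their control MAD was zero on some plate.
    """

    table: pd.DataFrame
    glog_offset: float = 1.0
    dropped: list[str] = field(default_factory=list)


def fit_normalization(cells: pd.DataFrame, glog_offset: float = 1.0) -> NormalizationParams:
    """Estimate robust normalization parameters from vehicle wells only."""
    feats = feature_columns(cells)
    ctrl = cells[cells["Metadata_Concentration"] == 0]
    if ctrl.empty:
        raise ValueError("no vehicle wells (Metadata_Concentration == 0) found")

    grp = ctrl.groupby(["Metadata_Plate", "Metadata_Vehicle"], observed=True)[feats]
    med = grp.median()
    # MAD scaled by the normal-consistency constant, matching R's mad()
    mad = grp.apply(
        lambda g: (g - g.median()).abs().median() * 1.4826
    )
    dropped = sorted(mad.columns[(mad <= 0).any(axis=0)])
    if dropped:
        logger.warning(
            "fit_normalization: dropping %d features with zero control MAD "
            "on some plate: %s%s",
            len(dropped), dropped[:5], "..." if len(dropped) > 5 else "",
        )
        med = med.drop(columns=dropped)
        mad = mad.drop(columns=dropped)
    table = pd.concat({"median": med, "mad": mad}, axis=1).swaplevel(axis=1)
    table = table.sort_index(axis=1)
    return NormalizationParams(table=table, glog_offset=glog_offset, dropped=dropped)


def robustize(cells: pd.DataFrame, params: NormalizationParams) -> pd.DataFrame:
    """Normalize each feature to ``(x - control median) / (1.4826 * MAD)``.

    Parameters come from vehicle wells of the matching solvent on the same
    plate; features dropped during parameter fitting are dropped here too.

    Raises
    ------
    ValueError
        If a plate/vehicle combination present in the data has no fitted
        parameters.
    """
    feats = [c for c in feature_columns(cells) if c not in set(params.dropped)]
    meta_cols = [c for c in cells.columns if c not in feats]
    pieces = []
    for (plate, veh), grp in cells.groupby(
        ["Metadata_Plate", "Metadata_Vehicle"], sort=True, observed=True
    ):
        if (plate, veh) not in params.table.index:
            raise ValueError(
                f"no normalization parameters for plate {plate!r}, vehicle {veh!r}"
            )
        row = params.table.loc[(plate, veh)]
        m = row.xs("median", level=1)[feats].to_numpy(dtype=float)
        s = row.xs("mad", level=1)[feats].to_numpy(dtype=float)
        vals = pd.DataFrame(
            (grp[feats].to_numpy(dtype=float) - m) / s,
            columns=feats, index=grp.index,
        )
        pieces.append(pd.concat([grp[meta_cols], vals], axis=1))
    return pd.concat(pieces).sort_index().reset_index(drop=True)


def glog_transform(values, c: float = 1.0):
    """Generalized log ``ln((x + sqrt(x^2 + c^2)) / 2)``.

    Monotone and defined for all real x, compressing large magnitudes of
    either sign; ``c`` controls the linear-to-log transition scale.
    """
    if c <= 0:
        raise ValueError(f"glog offset must be positive, got {c}")
    x = np.asarray(values, dtype=float)
    root = np.sqrt(x * x + c * c)
    # x + root cancels catastrophically for large negative x; use the
    # conjugate form c^2 / (root - x) there
    with np.errstate(divide="ignore"):
        out = np.where(
            x >= 0,
            np.log((x + root) / 2.0),
            np.log(c * c / (2.0 * (root - np.where(x < 0, x, 0.0)))),
        )
    if np.isscalar(values) or np.ndim(values) == 0:
        return float(out)
    return out


def apply_glog(cells: pd.DataFrame, c: float = 1.0) -> pd.DataFrame:
    """Apply the generalized-log transform to every feature column."""
    out = cells.copy()
    feats = feature_columns(cells)
    out[feats] = glog_transform(out[feats].to_numpy(dtype=float), c)
    return out


def aggregate_wells(
    cells: pd.DataFrame,
    cytotoxic: set[tuple[str, float]] | None = None,
) -> pd.DataFrame:
    """Median-aggregate cells to per-well profiles.

    Each feature becomes the median over the well's cells; ``cell_count``
    records how many cells contributed.  Wells belonging to flagged
    cytotoxic (chemical, concentration) pairs are excluded when a flag set
    is supplied.  Wells that lost every cell upstream simply do not appear.
    """
    feats = feature_columns(cells)
    keys = list(METADATA_COLUMNS)
    if cytotoxic:
        pairs = list(
            zip(cells["Metadata_Chemical"], cells["Metadata_Concentration"].astype(float))
        )
        keep = np.array([p not in cytotoxic for p in pairs])
        n_excluded = int((~keep).sum())
        if n_excluded:
            logger.info(
                "aggregate_wells: excluding %d cells in cytotoxic doses", n_excluded
            )
        cells = cells.loc[keep]
    grouped = cells.groupby(keys, sort=True, observed=True)
    prof = pd.concat(
        [grouped.size().rename("cell_count"), grouped[feats].median()], axis=1
    )
    return prof.reset_index()


def preprocess(
    cells: pd.DataFrame,
    cytotox_threshold: float = 0.25,
    glog_offset: float | None = 1.0,
) -> tuple[pd.DataFrame, set[tuple[str, float]]]:
    """Run the full preprocessing chain on a raw single-cell table.

    clean -> flag cytotoxic (raw counts) -> robustize -> glog -> aggregate,
    returning the per-well profile table and the cytotoxic flag set.
    ``glog_offset=None`` skips the transform.
    """
    cleaned = clean_features(cells)
    flags = flag_cytotoxic(well_counts(cleaned), threshold=cytotox_threshold)
    params = fit_normalization(cleaned, glog_offset=glog_offset or 1.0)
    normed = robustize(cleaned, params)
    if glog_offset is not None:
        normed = apply_glog(normed, glog_offset)
    profiles = aggregate_wells(normed, cytotoxic=flags)
    return profiles, flags
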