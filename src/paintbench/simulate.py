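"""Synthetic Cell Painting plates with known ground truth.

Emulates the screen's design — 384-well plates, ~500 cells seeded per
well, 6 replicate wells per dose, 0.5% DMSO or water vehicle controls,
four-point dose series (0.025/0.25/2.5/25 µM for population-exposure
"toxicant" chemicals, 0.01/0.1/1/10 µM for reference small molecules) and
a feature catalog spanning 3 compartments x 5 stains x the CellProfiler
measurement classes — so that every downstream stage has a recoverable
truth: which features respond, in which direction, with what benchmark
concentration, and which doses are cytotoxic.

Generative model per cell and feature::

    value = baseline(feature) + plate_offset(plate, feature)
          + hill_shift(chemical, feature, dose)
          + well_effect(well, feature)          ~ N(0, noise_sd^2)
          + cell_scatter(cell, feature)         ~ N(0, cell_sd^2)

``noise_sd`` is the replicate (well-to-well) residual SD — the scale on
which per-well profiles scatter around the dose-response curve and hence
the sigma entering the true benchmark concentration at BMR factor 1.349.
``cell_sd`` is within-well scatter; per-well median aggregation averages
it away.  Realized well cell counts are Poisson around
``cells_per_well x multiplier(chemical, dose)``, which makes the 25%
cytotoxicity rule directly testable.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .doseresponse import BMR_FACTOR
from .profiles import METADATA_COLUMNS, parse_feature_name

NHANES_DOSES = (0.025, 0.25, 2.5, 25.0)
SMALL_MOLECULE_DOSES = (0.01, 0.1, 1.0, 10.0)

_ROWS = "ABCDEFGHIJKLMNOP"  # 384-well plate: 16 rows x 24 columns


def well_name(index: int) -> str:
    if not 0 <= index < 384:
        raise ValueError("384-well plate holds wells 0..383")
    return f"{_ROWS[index // 24]}{index % 24 + 1:02d}"


# ---------------------------------------------------------------------------
# design


@dataclass(frozen=True)
class Treatment:
    """One chemical with its solvent and dose series (µM, ascending)."""

    chemical: str
    vehicle: str = "DMSO"
    doses: tuple[float, ...] = NHANES_DOSES


def default_feature_catalog(n_features: int = 3000) -> tuple[str, ...]:
    """Deterministic catalog of CellProfiler-style feature names.

    Cycles compartments x measurement classes x per-class measurements x
    stain channels until ``n_features`` names are produced.  Correlation
    features carry stain pairs; AreaShape and Neighbors carry none.
    """
    compartments = ("Cells", "Cytoplasm", "Nuclei")
    stains = ("DNA", "RNA", "ER", "Mito", "AGP")
    per_stain = {
        "Intensity": (
            "MeanIntensity", "IntegratedIntensity", "StdIntensity",
            "MaxIntensity", "MinIntensity", "MedianIntensity",
            "UpperQuartileIntensity", "LowerQuartileIntensity", "MADIntensity",
        ),
        "Texture": (
            "AngularSecondMoment", "Contrast", "Entropy", "InfoMeas1",
            "InverseDifferenceMoment", "SumAverage", "SumEntropy", "Variance",
        ),
        "Granularity": tuple(f"Granularity{i}" for i in range(1, 9)),
        "RadialDistribution": (
            "FracAtD1", "FracAtD2", "FracAtD3", "FracAtD4",
            "MeanFrac1", "MeanFrac2", "MeanFrac3", "MeanFrac4",
            "RadialCV1", "RadialCV2", "RadialCV3", "RadialCV4",
        ),
    }
    stain_free = {
        "AreaShape": (
            "Area", "Perimeter", "Compactness", "Eccentricity", "Extent",
            "FormFactor", "MajorAxisLength", "MinorAxisLength", "Solidity",
            "MaxFeretDiameter", "MinFeretDiameter", "MeanRadius",
        ),
        "Neighbors": (
            "NumberOfNeighbors", "PercentTouching",
            "FirstClosestDistance", "SecondClosestDistance",
        ),
    }
    per_comp: list[list[str]] = []
    for comp in compartments:
        block: list[str] = []
        for group, measures in per_stain.items():
            for meas in measures:
                for stain in stains:
                    block.append(f"{comp}_{group}_{meas}_{stain}")
        for group, measures in stain_free.items():
            for meas in measures:
                block.append(f"{comp}_{group}_{meas}")
        for s1, s2 in itertools.combinations(stains, 2):
            block.append(f"{comp}_Correlation_Correlation_{s1}_{s2}")
            block.append(f"{comp}_Correlation_Overlap_{s1}_{s2}")
        per_comp.append(block)
    # interleave compartments so truncated catalogs still span all three
    names: list[str] = [
        name for triple in zip(*per_comp) for name in triple
    ]
    if n_features > len(names):
        # extend with numbered texture variants to reach large catalogs
        extra = []
        i = 0
        while len(names) + len(extra) < n_features:
            comp = compartments[i % 3]
            stain = stains[(i // 3) % 5]
            extra.append(f"{comp}_Texture_SumVariance{i // 15 + 1}_{stain}")
            i += 1
        names += extra
    return tuple(names[:n_features])


@dataclass
class PlateDesign:
    """Layout of the simulated screen.

    Treatments are distributed round-robin over ``plates``; each plate
    carries its own vehicle wells for every solvent it hosts (at least 6,
    default 24 — high-content plates devote generous real estate to
    controls).
    """

    treatments: list[Treatment]
    plates: tuple[str, ...] = ("Plate1",)
    replicates_per_dose: int = 6
    cells_per_well: float = 500.0
    vehicle_wells_per_plate: int = 24
    features: tuple[str, ...] = field(default_factory=default_feature_catalog)

    def validate(self) -> None:
        if not self.features:
            raise ValueError("feature catalog is empty")
        if not self.treatments:
            raise ValueError("no treatments specified")
        if self.vehicle_wells_per_plate < 6:
            raise ValueError("need >=6 vehicle wells per vehicle per plate")
        for t in self.treatments:
            d = np.asarray(t.doses, dtype=float)
            if (d <= 0).any() or not (np.diff(d) > 0).all():
                raise ValueError(
                    f"{t.chemical}: dose series must be strictly increasing and positive"
                )
        for name in self.features:
            parse_feature_name(name)

    def plate_of(self, treatment_index: int) -> str:
        return self.plates[treatment_index % len(self.plates)]

    def max_dose(self, chemical: str) -> float:
        for t in self.treatments:
            if t.chemical == chemical:
                return float(max(t.doses))
        raise KeyError(chemical)


# ---------------------------------------------------------------------------
# effects


@dataclass(frozen=True)
class HillEffect:
    """Planted mean shift ``nu * d^n / (k^n + d^n)`` (µM-scale Hill curve).

    The sign of ``nu`` is the planted direction.
    """

    nu: float
    k: float
    n: float = 1.0

    def shift(self, doses: np.ndarray) -> np.ndarray:
        d = np.asarray(doses, dtype=float)
        dn = np.where(d > 0, d, 1.0) ** self.n
        return self.nu * np.where(d > 0, dn / (self.k**self.n + dn), 0.0)

    def true_bmc(self, noise_sd: float, bmr_factor: float = BMR_FACTOR) -> float:
        """Closed-form dose at which |shift| = bmr_factor * noise_sd."""
        bmr = bmr_factor * noise_sd
        if abs(self.nu) <= bmr:
            return math.nan
        r = bmr / abs(self.nu)
        return float(self.k * (r / (1.0 - r)) ** (1.0 / self.n))


@dataclass
class EffectSpec:
    """Planted structure: responsive features, shared blocks, count effects.

    ``responsive`` maps chemical -> {feature name -> HillEffect}.
    ``count_multipliers`` maps chemical -> {dose -> multiplier} applied to
    the Poisson cell-count mean (0.2 plants cytotoxicity, >1 plants the
    low-dose proliferation some exposures show).  ``shared_blocks`` is
    declarative bookkeeping for recovery tests and must reference features
    that are responsive in both chemicals.
    """

    responsive: dict[str, dict[str, HillEffect]] = field(default_factory=dict)
    shared_blocks: list[tuple[str, str, tuple[str, ...]]] = field(default_factory=list)
    count_multipliers: dict[str, dict[float, float]] = field(default_factory=dict)
    noise_sd: float = 1.0
    cell_sd: float = 1.0
    plate_shift_sd: float = 0.5
    missing_costes_fraction: float = 0.0

    def validate(self) -> None:
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        if self.cell_sd < 0 or self.plate_shift_sd < 0:
            raise ValueError("cell_sd and plate_shift_sd must be non-negative")
        for a, b, feats in self.shared_blocks:
            for chem in (a, b):
                have = set(self.responsive.get(chem, {}))
                missing = set(feats) - have
                if missing:
                    raise ValueError(
                        f"shared block {a}/{b}: {len(missing)} features not "
                        f"responsive in {chem}"
                    )
        for chem, mults in self.count_multipliers.items():
            if any(m <= 0 for m in mults.values()):
                raise ValueError(f"{chem}: count multipliers must be positive")

    def multiplier(self, chemical: str, dose: float) -> float:
        return self.count_multipliers.get(chemical, {}).get(dose, 1.0)


@dataclass
class GroundTruth:
    """Planted truth per (chemical, feature) and per (chemical, dose).

    ``features`` columns: chemical, feature, responsive, direction,
    true_bmc (nan when the planted amplitude cannot reach the BMR).
    ``cytotoxicity`` columns: chemical, dose, multiplier, cytotoxic.
    """

    features: pd.DataFrame
    cytotoxicity: pd.DataFrame
    max_dose: dict[str, float]


# ---------------------------------------------------------------------------
# generation


def _plate_layout(design: PlateDesign):
    """Assign wells: per plate, vehicle wells first, then treatment wells."""
    per_plate_treatments: dict[str, list[Treatment]] = {p: [] for p in design.plates}
    for i, t in enumerate(design.treatments):
        per_plate_treatments[design.plate_of(i)].append(t)
    layout = []  # rows: (plate, well, chemical, conc, vehicle, replicate)
    for plate in design.plates:
        treatments = per_plate_treatments[plate]
        if not treatments:
            continue
        vehicles = sorted({t.vehicle for t in treatments})
        idx = 0
        for veh in vehicles:
            for rep in range(design.vehicle_wells_per_plate):
                layout.append((plate, well_name(idx), veh, 0.0, veh, rep + 1))
                idx += 1
        for t in treatments:
            for dose in t.doses:
                for rep in range(design.replicates_per_dose):
                    layout.append(
                        (plate, well_name(idx), t.chemical, float(dose), t.vehicle, rep + 1)
                    )
                    idx += 1
    return layout


def generate_plate_set(
    design: PlateDesign, effects: EffectSpec, seed: int
) -> tuple[pd.DataFrame, GroundTruth]:
    """Simulate a plate set; returns (single-cell table, ground truth).

    Deterministic: identical (design, effects, seed) yield identical
    tables regardless of dict iteration order (features are processed in
    catalog order, wells in a fixed plate layout order).
    """
    design.validate()
    effects.validate()
    rng = np.random.default_rng(seed)
    feats = list(design.features)
    n_feat = len(feats)
    feat_index = {f: i for i, f in enumerate(feats)}

    # per-feature baselines on a log-uniform scale: intensity-like and
    # shape-like features get very different magnitudes, which exercises
    # normalization downstream
    baselines = 10.0 ** rng.uniform(-1.0, 2.0, size=n_feat)
    plate_offsets = {
        p: rng.normal(0.0, effects.plate_shift_sd, size=n_feat)
        for p in design.plates
    }

    layout = _plate_layout(design)
    frames = []
    image_number = 0
    for plate, well, chem, conc, veh, rep in layout:
        image_number += 1
        mult = effects.multiplier(chem, conc) if conc > 0 else 1.0
        n_cells = int(rng.poisson(design.cells_per_well * mult))
        if n_cells == 0:
            continue
        mean = baselines + plate_offsets[plate]
        if conc > 0 and chem in effects.responsive:
            for fname, eff in effects.responsive[chem].items():
                mean[feat_index[fname]] += float(eff.shift(np.array([conc]))[0])
        well_eff = rng.normal(0.0, effects.noise_sd, size=n_feat)
        values = (
            mean + well_eff
            + rng.normal(0.0, effects.cell_sd, size=(n_cells, n_feat))
        )
        df = pd.DataFrame(values, columns=feats)
        df.insert(0, "ImageNumber", image_number)
        df.insert(1, "ObjectNumber", np.arange(1, n_cells + 1))
        df["Metadata_Plate"] = plate
        df["Metadata_Well"] = well
        df["Metadata_Chemical"] = chem
        df["Metadata_Concentration"] = conc
        df["Metadata_Vehicle"] = veh
        df["Metadata_Replicate"] = rep
        frames.append(df)
    cells = pd.concat(frames, ignore_index=True)
    cells = cells[["ImageNumber", "ObjectNumber", *METADATA_COLUMNS, *feats]]

    if effects.missing_costes_fraction > 0:
        costes = [f for f in feats if "Costes" in f.split("_")]
        for f in costes:
            mask = rng.random(len(cells)) < effects.missing_costes_fraction
            cells.loc[mask, f] = np.nan

    truth = _build_truth(design, effects)
    return cells, truth


def _build_truth(design: PlateDesign, effects: EffectSpec) -> GroundTruth:
    chems = [t.chemical for t in design.treatments]
    rows = []
    for chem in chems:
        planted = effects.responsive.get(chem, {})
        for feat in design.features:
            eff = planted.get(feat)
            if eff is None:
                rows.append((chem, feat, False, None, math.nan))
            else:
                rows.append(
                    (
                        chem, feat, True,
                        "UP" if eff.nu >= 0 else "DOWN",
                        eff.true_bmc(effects.noise_sd),
                    )
                )
    features = pd.DataFrame(
        rows, columns=["chemical", "feature", "responsive", "direction", "true_bmc"]
    )
    cyto_rows = []
    for t in design.treatments:
        for dose in t.doses:
            m = effects.multiplier(t.chemical, float(dose))
            cyto_rows.append((t.chemical, float(dose), m, m < 0.25))
    cytotoxicity = pd.DataFrame(
        cyto_rows, columns=["chemical", "dose", "multiplier", "cytotoxic"]
    )
    max_dose = {t.chemical: float(max(t.doses)) for t in design.treatments}
    return GroundTruth(features, cytotoxicity, max_dose)


def truth_fingerprint(truth: GroundTruth) -> pd.DataFrame:
    """Signed truth matrix (features x chemicals, entries in {-1, 0, +1}).

    A (chemical, feature) entry is nonzero iff the feature is responsive
    with a defined true BMC no larger than the chemical's highest tested
    dose; rows that are zero for every chemical are pruned.  Matches the
    layout of the estimated fingerprint for direct comparison.
    """
    chems = sorted(truth.max_dose)
    feats = sorted(truth.features["feature"].unique())
    mat = pd.DataFrame(0, index=feats, columns=chems, dtype=int)
    for row in truth.features.itertuples(index=False):
        if not row.responsive or not math.isfinite(row.true_bmc):
            continue
        if row.true_bmc > truth.max_dose[row.chemical]:
            continue
        mat.loc[row.feature, row.chemical] = 1 if row.direction == "UP" else -1
    mat = mat.loc[(mat != 0).any(axis=1)]
    mat.index.name = "feature"
    return mat


# ---------------------------------------------------------------------------
# convenience constructors for planted scenarios


def plant_hill_effects(
    effects: EffectSpec,
    chemical: str,
    features: list[str],
    nu: float,
    k: float,
    n: float = 1.0,
    alternate_sign: bool = True,
) -> None:
    """Register the same Hill effect for a batch of features (directions
    alternate UP/DOWN when ``alternate_sign``)."""
    planted = effects.responsive.setdefault(chemical, {})
    for i, feat in enumerate(features):
        sign = -1.0 if (alternate_sign and i % 2) else 1.0
        planted[feat] = HillEffect(nu=sign * nu, k=k, n=n)
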