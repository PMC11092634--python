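import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from paintbench.simulate import (
    EffectSpec,
    PlateDesign,
    Treatment,
    default_feature_catalog,
    generate_plate_set,
    plant_hill_effects,
)

SEED = 20240915


@pytest.fixture(scope="session")
def small_catalog():
    return default_feature_catalog(60)


@pytest.fixture(scope="session")
def planted_plate(small_catalog):
    """One chemical, 20 responsive features (Hill, 3-sigma top-dose effect),
    40 null features; used by several recovery tests."""
    design = PlateDesign(treatments=[Treatment("ChemA")], features=small_catalog)
    effects = EffectSpec()
    plant_hill_effects(
        effects, "ChemA", list(small_catalog[:20]), nu=3.0, k=2.5, n=2.0
    )
    cells, truth = generate_plate_set(design, effects, seed=SEED)
    return cells, truth, design, effects


@pytest.fixture()
def tiny_cells():
    """Minimal hand-built single-cell table: 1 plate, 2 wells, 3 features."""
    rows = []
    for img, (well, chem, conc, rep) in enumerate(
        [("A01", "DMSO", 0.0, 1), ("A02", "DMSO", 0.0, 2), ("B01", "X", 1.0, 1)],
        start=1,
    ):
        for obj in range(1, 6):
            rows.append(
                {
                    "ImageNumber": img,
                    "ObjectNumber": obj,
                    "Metadata_Plate": "P1",
                    "Metadata_Well": well,
                    "Metadata_Chemical": chem,
                    "Metadata_Concentration": conc,
                    "Metadata_Vehicle": "DMSO",
                    "Metadata_Replicate": rep,
                    "Nuclei_Intensity_MeanIntensity_DNA": float(obj),
                    "Cells_AreaShape_Area": 10.0 * obj,
                    "Cells_Correlation_Costes_DNA_RNA": np.nan if obj % 2 else 0.5,
                }
            )
    return pd.DataFrame(rows)
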