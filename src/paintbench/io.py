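"""Readers and writers for the pipeline's standard text formats.

CellProfiler ExportToSpreadsheet dialect: one CSV per compartment
(Nuclei, Cells, Cytoplasm) with ImageNumber/ObjectNumber keys and
unprefixed feature columns, plus a plate-metadata CSV keyed by
ImageNumber.  Per-well profiles round-trip through a BMDExpress-style
tab-delimited matrix: three metadata header rows (treatment,
concentration, replicate) above the data block, first column = feature
name, one column per well.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .profiles import COMPARTMENTS, METADATA_COLUMNS, feature_columns

_META_CSV_COLUMNS = (
    "ImageNumber",
    "Metadata_Plate",
    "Metadata_Well",
    "Metadata_Chemical",
    "Metadata_Concentration",
    "Metadata_Vehicle",
    "Metadata_Replicate",
)

_FLOAT_FMT = "%.17g"  # full float round-trip


def write_cellprofiler(cells: pd.DataFrame, outdir: str | Path) -> dict[str, Path]:
    """Write a merged single-cell table as per-compartment CSVs + metadata.

    The compartment prefix is stripped from feature column names, matching
    the files CellProfiler itself exports.  Returns the written paths.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    feats = feature_columns(cells)
    paths: dict[str, Path] = {}
    for comp in COMPARTMENTS:
        comp_feats = [f for f in feats if f.startswith(comp + "_")]
        if not comp_feats:
            continue
        sub = cells[["ImageNumber", "ObjectNumber", *comp_feats]].copy()
        sub.columns = ["ImageNumber", "ObjectNumber"] + [
            f[len(comp) + 1:] for f in comp_feats
        ]
        path = outdir / f"{comp}.csv"
        sub.to_csv(path, index=False, float_format=_FLOAT_FMT)
        paths[comp] = path
    meta = (
        cells[list(_META_CSV_COLUMNS)]
        .drop_duplicates("ImageNumber")
        .sort_values("ImageNumber")
    )
    meta_path = outdir / "metadata.csv"
    meta.to_csv(meta_path, index=False, float_format=_FLOAT_FMT)
    paths["metadata"] = meta_path
    return paths


def read_cellprofiler(
    compartment_csvs: dict[str, str | Path], metadata_csv: str | Path
) -> pd.DataFrame:
    """Join per-compartment CellProfiler CSVs with the plate metadata.

    Feature columns are prefixed with their compartment; compartment files
    are joined on (ImageNumber, ObjectNumber) and every object's image
    must appear in the metadata.

    Raises
    ------
    ValueError
        On ImageNumbers absent from the metadata, or on duplicate columns
        after prefixing.
    """
    merged: pd.DataFrame | None = None
    for comp, path in sorted(compartment_csvs.items()):
        if comp not in COMPARTMENTS:
            raise ValueError(f"unknown compartment {comp!r}")
        df = pd.read_csv(path)
        feats = [c for c in df.columns if c not in ("ImageNumber", "ObjectNumber")]
        df = df.rename(columns={f: f"{comp}_{f}" for f in feats})
        if merged is None:
            merged = df
        else:
            dup = set(merged.columns) & set(df.columns) - {"ImageNumber", "ObjectNumber"}
            if dup:
                raise ValueError(f"duplicate columns after prefixing: {sorted(dup)[:5]}")
            merged = merged.merge(df, on=["ImageNumber", "ObjectNumber"], how="inner")
    if merged is None:
        raise ValueError("no compartment CSVs supplied")

    meta = pd.read_csv(metadata_csv)
    missing = set(merged["ImageNumber"].unique()) - set(meta["ImageNumber"])
    if missing:
        raise ValueError(
            f"ImageNumbers missing from metadata: {sorted(missing)[:10]}"
        )
    out = merged.merge(meta, on="ImageNumber", how="left")
    ordered = ["ImageNumber", "ObjectNumber", *METADATA_COLUMNS]
    feats = [c for c in out.columns if c not in ordered]
    return out[ordered + feats]


# ---------------------------------------------------------------------------
# BMDExpress-style per-well matrix


def write_bmdexpress_matrix(profiles: pd.DataFrame, path: str | Path) -> Path:
    """Write per-well profiles as the tab-delimited dose-response matrix.

    Layout: three header rows named treatment, concentration and
    replicate (one column per well), then one row per feature with the
    feature name in the first column.
    """
    if profiles.empty:
        raise ValueError("no profiles to write")
    feats = [
        c for c in feature_columns(profiles) if c != "cell_count"
    ]
    well_ids = (
        profiles["Metadata_Plate"].astype(str) + ":" + profiles["Metadata_Well"].astype(str)
    )
    if well_ids.duplicated().any():
        raise ValueError("duplicate well columns in profile table")
    lines = []
    lines.append("\t".join(["treatment", *profiles["Metadata_Chemical"].astype(str)]))
    lines.append(
        "\t".join(
            ["concentration"]
            + [_FLOAT_FMT % v for v in profiles["Metadata_Concentration"]]
        )
    )
    lines.append(
        "\t".join(["replicate", *profiles["Metadata_Replicate"].astype(str)])
    )
    mat = profiles[feats].to_numpy(dtype=float).T
    for feat, row in zip(feats, mat):
        lines.append("\t".join([feat] + [_FLOAT_FMT % v for v in row]))
    path = Path(path)
    path.write_text("\n".join(lines) + "\n")
    return path


def read_bmdexpress_matrix(path: str | Path) -> pd.DataFrame:
    """Read the matrix written by :func:`write_bmdexpress_matrix` back to a
    per-well profile table (without plate/well/vehicle metadata, which the
    format does not carry; wells become synthetic W1..Wn)."""
    lines = Path(path).read_text().splitlines()
    if len(lines) < 4:
        raise ValueError("matrix file too short: need 3 header rows + data")
    header = {}
    for i, name in enumerate(("treatment", "concentration", "replicate")):
        parts = lines[i].split("\t")
        if parts[0] != name:
            raise ValueError(f"expected header row {name!r}, found {parts[0]!r}")
        header[name] = parts[1:]
    n_wells = len(header["treatment"])
    feats, rows = [], []
    for line in lines[3:]:
        if not line:
            continue
        parts = line.split("\t")
        if len(parts) != n_wells + 1:
            raise ValueError(f"row {parts[0]!r} has {len(parts) - 1} values, expected {n_wells}")
        feats.append(parts[0])
        rows.append([float(v) for v in parts[1:]])
    data = np.asarray(rows, dtype=float).T
    out = pd.DataFrame(data, columns=feats)
    out.insert(0, "Metadata_Plate", "NA")
    out.insert(1, "Metadata_Well", [f"W{i + 1}" for i in range(n_wells)])
    out.insert(2, "Metadata_Chemical", header["treatment"])
    out.insert(3, "Metadata_Concentration", [float(v) for v in header["concentration"]])
    out.insert(4, "Metadata_Vehicle", "NA")
    out.insert(5, "Metadata_Replicate", [int(float(v)) for v in header["replicate"]])
    return out


# ---------------------------------------------------------------------------
# simple TSV result writers


def write_tsv(df: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)
    return path


def write_fingerprint(fp: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    fp.to_csv(path, sep="\t")
    return path


def read_fingerprint(path: str | Path) -> pd.DataFrame:
    fp = pd.read_csv(path, sep="\t", index_col=0)
    return fp.astype(int)


def write_ground_truth(truth, path: str | Path) -> Path:
    """Serialize a GroundTruth's per-feature table as TSV."""
    return write_tsv(truth.features, path)
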