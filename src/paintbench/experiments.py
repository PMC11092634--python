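"""Validation experiments on synthetic plates.

Each function runs one self-contained check of the pipeline against an
independent reference — closed forms, exhaustive enumeration, grid
search, or the generator's planted ground truth — and returns the
measured quantities.  They are exercised by the acceptance checks and can
be reproduced from ``scripts/acceptance.py``.

All experiments are seeded; problem sizes are chosen so the whole battery
runs in a few minutes on one core (the per-experiment docstrings state
the sizes used).
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd

from .doseresponse import (
    BMR_FACTOR,
    DoseSeries,
    HillModel,
    fit_model,
    run_chemical,
)
from .fingerprint import build_fingerprint
from .overlap import OverlapCounts, compare_all, fisher_one_sided
from .profiles import METADATA_COLUMNS, flag_cytotoxic, preprocess
from .simulate import (
    EffectSpec,
    HillEffect,
    PlateDesign,
    Treatment,
    default_feature_catalog,
    generate_plate_set,
    plant_hill_effects,
)

PAPER_DOSES = np.array([0.0, 0.025, 0.25, 2.5, 25.0])


# ---------------------------------------------------------------------------
# independent oracles


def grid_llf_oracle(series: DoseSeries, n_grid: int = 50) -> float:
    """Exhaustive Hill-likelihood reference: a dense (nu, k, n) grid with
    the intercept solved analytically; returns the best log-likelihood
    found.  Used as a lower bound the optimizer must reach."""
    d, y = series.doses, series.values
    pos = d[d > 0]
    ks = np.exp(np.linspace(np.log(pos.min() / 10), np.log(pos.max() * 10), n_grid))
    ns = np.linspace(1.0, 8.0, n_grid)
    r = float(y.max() - y.min()) or 1.0
    nus = np.linspace(-2 * r, 2 * r, n_grid)
    kk, nn = np.meshgrid(ks, ns, indexing="ij")
    dn = d[None, None, :] ** nn[..., None]
    frac = np.where(d[None, None, :] > 0, dn / (kk[..., None] ** nn[..., None] + dn), 0.0)
    yc = y - y.mean()
    fc = frac - frac.mean(axis=-1, keepdims=True)
    A = float(yc @ yc)
    B = np.tensordot(fc, yc, axes=([-1], [0]))
    C = (fc * fc).sum(axis=-1)
    sse = A - 2 * nus[None, None, :] * B[..., None] + nus[None, None, :] ** 2 * C[..., None]
    best_sse = float(sse.min())
    n = y.size
    sig2 = max(best_sse / n, 1e-24)
    return -0.5 * n * (math.log(2 * math.pi * sig2) + best_sse / (n * sig2))


def hypergeom_tail_enum(N: int, K: int, n: int, k: int) -> float:
    """P(X >= k) for X ~ Hypergeometric(N, K, n) by exact enumeration."""
    total = math.comb(N, n)
    return sum(
        math.comb(K, i) * math.comb(N - K, n - i) for i in range(k, min(K, n) + 1)
    ) / total


# ---------------------------------------------------------------------------
# experiments


def closed_form_bmc_check() -> dict:
    """BMC inversion identities at the default benchmark response factor.

    Checks (i) power(beta=1, delta=1, sigma=1) has BMC equal to the BMR
    factor, (ii) a Hill curve with amplitude twice the BMR crosses it
    exactly at k, and (iii) the polynomial root-finder agrees with the
    power closed form on a shared linear curve.
    """
    rng = np.random.default_rng(0)
    d = np.repeat(PAPER_DOSES, 6)
    y = d + rng.normal(0, 1.0, d.size)
    power = fit_model(DoseSeries(d, y), "power")
    power.params.update(gamma=0.0, beta=1.0, delta=1.0)
    power.sigma = 1.0
    power_bmc = power.bmc().bmc

    hill = fit_model(DoseSeries(d, y), "hill")
    k0 = 2.5
    hill.params.update(gamma=0.0, nu=2 * BMR_FACTOR * hill.sigma, k=k0, n=1.7)
    hill_rel_err = abs(hill.bmc().bmc - k0) / k0

    poly = fit_model(DoseSeries(d, 0.5 + 0.8 * d + rng.normal(0, 0.7, d.size)), "poly", degree=1)
    closed = BMR_FACTOR * poly.sigma / abs(poly.params["coefs"][1])
    root_rel_err = abs(poly.bmc().bmc - closed) / closed
    return {
        "power_bmc": power_bmc,
        "hill_bmc_rel_err": hill_rel_err,
        "poly_root_rel_err": root_rel_err,
    }


def likelihood_oracle_check(n_series: int = 20, seed: int = 0) -> dict:
    """Worst-case log-likelihood deficit of the Hill fit vs the grid
    oracle over ``n_series`` seeded 5-dose series (positive deficit means
    the optimizer fell short of the grid)."""
    rng = np.random.default_rng(seed)
    worst = -math.inf
    for i in range(n_series):
        nu = rng.uniform(2, 8) * (1 if rng.random() < 0.5 else -1)
        k = rng.uniform(0.05, 20)
        n = rng.uniform(1, 5)
        sig = rng.uniform(0.2, 1.5)
        d = np.repeat(PAPER_DOSES, 6)
        y = nu * np.where(d > 0, d, 1) ** n / (k**n + np.where(d > 0, d, 1) ** n) * (d > 0)
        y = y + rng.normal(0, sig, d.size)
        series = DoseSeries(d, y)
        fit = fit_model(series, "hill", seed=i)
        worst = max(worst, grid_llf_oracle(series) - fit.llf)
    return {"max_llf_deficit": worst, "n_series": n_series}


def fisher_enumeration_check(max_n: int = 12) -> dict:
    """Max absolute error of the one-sided test vs exhaustive enumeration
    over every valid 2x2 table with universe size up to ``max_n``."""
    worst = 0.0
    n_tables = 0
    for N in range(1, max_n + 1):
        for K in range(N + 1):
            for n in range(N + 1):
                for k in range(max(0, K + n - N), min(K, n) + 1):
                    c = OverlapCounts("ALL", N, K, n, k)
                    err = abs(fisher_one_sided(c) - hypergeom_tail_enum(N, K, n, k))
                    worst = max(worst, err)
                    n_tables += 1
    return {"max_abs_err": worst, "n_tables": n_tables}


def recovery_experiment(seed: int = 0, n_planted: int = 100, n_null: int = 100) -> dict:
    """Parameter recovery at the screen's design.

    One chemical, vehicle plus 0.025/0.25/2.5/25 µM at 6 replicate wells,
    ``n_planted`` Hill-responsive features with 3-sigma top-dose effects
    and in-range true BMCs (k and the Hill power vary across features),
    ``n_null`` untouched features.  Reports the fraction of detected
    features with the correct direction, the median absolute log10 ratio
    of estimated to true BMC, and the null prefilter pass rate.
    """
    feats = default_feature_catalog(n_planted + n_null)
    planted = list(feats[:n_planted])
    design = PlateDesign(treatments=[Treatment("ChemA")], features=feats)
    effects = EffectSpec()
    shapes = [(2.5, 2.0), (0.25, 1.0), (2.5, 1.0), (0.25, 2.0)]
    reg = effects.responsive.setdefault("ChemA", {})
    for i, f in enumerate(planted):
        k, n = shapes[i % len(shapes)]
        sign = -1.0 if i % 2 else 1.0
        # nu chosen so the top-dose effect is 3 residual SDs
        top = 25.0**n / (k**n + 25.0**n)
        reg[f] = HillEffect(nu=sign * 3.0 / top, k=k, n=n)
    cells, truth = generate_plate_set(design, effects, seed=seed)
    profiles, _ = preprocess(cells)
    table = run_chemical(profiles, "ChemA", compute_bmcl_flag=False, seed=seed)
    table = table.set_index("feature")
    tr = truth.features.set_index("feature")

    planted_tab = table.loc[planted]
    detected = planted_tab[planted_tab["prefilter_pass"] & planted_tab["bmc"].notna()]
    dir_ok = (detected["direction"] == tr.loc[detected.index, "direction"]).mean()
    log_err = np.abs(np.log10(detected["bmc"] / tr.loc[detected.index, "true_bmc"]))
    nulls = table.loc[[f for f in feats if f not in set(planted)]]
    return {
        "n_detected": int(len(detected)),
        "direction_correct_pct": 100.0 * float(dir_ok),
        "median_abs_log10_bmc_err": float(np.median(log_err)),
        "null_prefilter_pass_pct": 100.0 * float(nulls["prefilter_pass"].mean()),
    }


def bmcl_coverage_experiment(n_sim: int = 200, seed: int = 0) -> dict:
    """Coverage of the one-sided 95% profile-likelihood BMCL.

    ``n_sim`` power-model data sets (beta=0.3, delta=1, sigma=0.5) at the
    screen's dose design; counts how often the BMCL falls below the true
    BMC (nominally >= 95% minus profile approximation error).
    """
    beta, sigma = 0.3, 0.5
    true_bmc = BMR_FACTOR * sigma / beta
    rng = np.random.default_rng(seed)
    d = np.repeat(PAPER_DOSES, 6)
    hits = 0
    defined = 0
    for i in range(n_sim):
        y = beta * d + rng.normal(0, sigma, d.size)
        fit = fit_model(DoseSeries(d, y), "power", seed=i)
        b = fit.bmc(compute_bmcl=True)
        if math.isfinite(b.bmcl):
            defined += 1
            if b.bmcl < true_bmc:
                hits += 1
    return {
        "coverage_pct": 100.0 * hits / max(defined, 1),
        "n_sim": n_sim,
        "n_defined": defined,
    }


def cytotoxicity_boundary_check() -> dict:
    """The 25% rule at its boundary: 24.75% of the vehicle mean is
    excluded, exactly 25.0% is retained (strict inequality)."""
    def counts(dose_mean):
        rows = []
        for i in range(6):
            rows.append(("P1", f"A{i:02d}", "DMSO", 0.0, "DMSO", i + 1, 400))
            rows.append(("P1", f"B{i:02d}", "X", 25.0, "DMSO", i + 1, dose_mean))
        return pd.DataFrame(rows, columns=[*METADATA_COLUMNS, "cell_count"])

    below = flag_cytotoxic(counts(99))  # 24.75%
    at = flag_cytotoxic(counts(100))  # exactly 25%
    return {
        "flagged_below_boundary": int(("X", 25.0) in below),
        "retained_at_boundary": int(("X", 25.0) not in at),
    }


def overlap_recovery_experiment(seed: int = 0, n_features: int = 500, block: int = 50) -> dict:
    """End-to-end fingerprint-overlap recovery.

    Two chemicals share a planted ``block``-feature responsive block (high
    signal: 6-sigma top-dose effects) out of ``n_features``; the full
    feature namespace is the enrichment universe.  Reports the shared
    count and one-sided p-value.
    """
    feats = default_feature_catalog(n_features)
    shared = list(feats[:block])
    design = PlateDesign(
        treatments=[Treatment("ChemA"), Treatment("ChemB")], features=feats
    )
    effects = EffectSpec()
    plant_hill_effects(effects, "ChemA", shared, nu=6.0, k=2.5, n=2.0)
    plant_hill_effects(effects, "ChemB", shared, nu=6.0, k=2.5, n=2.0)
    effects.shared_blocks.append(("ChemA", "ChemB", tuple(shared)))
    cells, _ = generate_plate_set(design, effects, seed=seed)
    profiles, flags = preprocess(cells)
    tables = {}
    for chem in ("ChemA", "ChemB"):
        tables[chem] = run_chemical(profiles, chem, compute_bmcl_flag=False, seed=seed)
    fp = build_fingerprint(tables, prune=False)
    res = compare_all(fp, pairs=[("ChemA", "ChemB")], strata=("all",))
    row = res.iloc[0]
    return {
        "shared": int(row["shared"]),
        "p_value": float(row["p_value"]),
        "n_universe": int(row["n_universe"]),
    }


def null_overlap_calibration(n_pairs: int = 1000, seed: int = 0, n_features: int = 500) -> dict:
    """Type-I calibration of the overlap test on independent random
    fingerprints: fraction of ``n_pairs`` with p < 0.05 (should not
    exceed the nominal rate by much; the discrete test is conservative).
    """
    rng = np.random.default_rng(seed)
    n_sig = 0
    for _ in range(n_pairs):
        k_a = rng.integers(20, 80)
        k_b = rng.integers(20, 80)
        a = rng.choice(n_features, k_a, replace=False)
        b = rng.choice(n_features, k_b, replace=False)
        k = len(set(a.tolist()) & set(b.tolist()))
        c = OverlapCounts("ALL", n_features, int(k_a), int(k_b), k)
        if fisher_one_sided(c) < 0.05:
            n_sig += 1
    return {"frac_below_0p05": n_sig / n_pairs, "n_pairs": n_pairs}


def determinism_roundtrip_check(tmpdir, seed: int = 0) -> dict:
    """Generator determinism and writer/reader closure.

    Generates a small plate set twice under one seed (tables must be
    identical), round-trips it through the CellProfiler CSV dialect and
    the per-well matrix format, and verifies the three metadata header
    rows of the matrix layout.
    """
    from pathlib import Path

    from . import io as pio

    tmpdir = Path(tmpdir)
    design = PlateDesign(
        treatments=[Treatment("A")],
        features=default_feature_catalog(12),
        cells_per_well=30,
        vehicle_wells_per_plate=6,
    )
    cells1, _ = generate_plate_set(design, EffectSpec(), seed=seed)
    cells2, _ = generate_plate_set(design, EffectSpec(), seed=seed)
    identical = cells1.equals(cells2)

    paths = pio.write_cellprofiler(cells1, tmpdir / "cp")
    comp = {c: p for c, p in paths.items() if c != "metadata"}
    back = pio.read_cellprofiler(comp, paths["metadata"])
    feats = [c for c in cells1.columns if c not in ("ImageNumber", "ObjectNumber") and not c.startswith("Metadata_")]
    csv_err = float(np.abs(cells1[feats].to_numpy() - back[feats].to_numpy()).max())

    profiles, _ = preprocess(cells1)
    mpath = pio.write_bmdexpress_matrix(profiles, tmpdir / "matrix.tsv")
    lines = mpath.read_text().splitlines()
    headers_ok = [l.split("\t")[0] for l in lines[:3]] == [
        "treatment", "concentration", "replicate",
    ]
    mat_back = pio.read_bmdexpress_matrix(mpath)
    pf = [c for c in feats if c in mat_back.columns]
    mat_err = float(
        np.abs(profiles[pf].to_numpy() - mat_back[pf].to_numpy()).max()
    )
    return {
        "generator_identical": int(identical),
        "csv_roundtrip_max_err": csv_err,
        "matrix_roundtrip_max_err": mat_err,
        "matrix_headers_ok": int(headers_ok),
    }
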