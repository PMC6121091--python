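"""End-to-end worked-example pipeline.

Stage order follows the basic aquaphotomics methodology: raw inspection →
difference spectra → preprocessing (smoothing, second derivative) → PCA →
PLSR → collation of consistently repeating activated bands → aquagram.
Every stage writes a CSV report; a run log records the package version, the
seed and all parameters (never wall-clock time, so repeated runs are
byte-identical).
"""

from __future__ import annotations

import warnings
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .aquagram import (
    aquagram_bootstrap_ci,
    classic_aquagram,
    fit_temperature_calibration,
    temperature_aquagram,
)
from .chemometrics import find_bands, pca_fit, plsr_crossvalidate, plsr_fit
from .dataset import (
    SpectraSet,
    group_average,
    read_spectra_csv,
    select_wavelength_range,
)
from .design import generate_measurement_plan
from .difference import subtract_mean_reference
from .preprocess import PretreatmentRecipe, savitzky_golay
from .synthetic import default_grid, default_model, simulate_dataset, \
    simulate_reference_library
from .wamacs import WAMACSTable, default_wamacs_table

__all__ = ["run_workflow", "collate_bands", "DEFAULT_CONFIG"]

DEFAULT_CONFIG: dict = {
    "seed": 42,
    "range": [1300.0, 1600.0],
    "simulate": {
        "n_levels": 10,
        "n_replicates": 2,
        "n_consecutives": 3,
        "control_interval": 5,
        "concentration_step_mM": 10.0,
        "t_nominal": 28.0,
        "noise_sd": 2e-4,
        "scatter_sd": 0.01,
        "consecutive_drift": 0.05,
    },
    "recipe": [
        {"step": "savgol", "window": 21, "polyorder": 2, "deriv": 0},
        {"step": "msc"},
    ],
    "plsr": {"y": "concentration", "cv_key": "concentration", "max_lv": 10},
    "bands": {
        # prominence relative to the vector's max |value|
        "min_prominence": 0.1,
        "min_separation_nm": 6.0,
        "collate_k": 2,
        "collate_window_nm": 3.0,
    },
    "aquagram": {"mode": "classic", "pretreatment": "msc", "B": 1000,
                 "alpha": 0.05},
    "reference_library": {"t_min": 20.0, "t_max": 36.0, "t_step": 1.0,
                          "replicates": 3},
}


def _merged(config: dict) -> dict:
    out = {k: (dict(v) if isinstance(v, dict) else v)
           for k, v in DEFAULT_CONFIG.items()}
    for k, v in config.items():
        if isinstance(v, dict) and isinstance(out.get(k), dict):
            out[k].update(v)
        else:
            out[k] = v
    return out


def collate_bands(
    band_lists: dict[str, pd.DataFrame], k: int = 2, window_nm: float = 3.0
) -> pd.DataFrame:
    """Wavelengths where bands repeat across analyses ("activated" bands).

    A wavelength is activated when bands within ±``window_nm`` of it appear
    in at least ``k`` of the analyses.  Nearby activated candidates are
    merged to their mean position.
    """
    rows = []
    for analysis, bands in band_lists.items():
        for r in bands.itertuples():
            rows.append((float(r.wavelength), analysis, int(r.sign)))
    if not rows:
        return pd.DataFrame(columns=["wavelength", "n_analyses", "analyses"])
    pool = pd.DataFrame(rows, columns=["wavelength", "analysis", "sign"])
    pool = pool.sort_values("wavelength").reset_index(drop=True)
    activated = []
    for w in pool["wavelength"]:
        near = pool[np.abs(pool["wavelength"] - w) <= window_nm]
        analyses = sorted(near["analysis"].unique())
        if len(analyses) >= k:
            activated.append((w, len(analyses), "+".join(analyses)))
    if not activated:
        return pd.DataFrame(columns=["wavelength", "n_analyses", "analyses"])
    act = pd.DataFrame(activated, columns=["wavelength", "n_analyses", "analyses"])
    # merge candidates closer than window_nm into one reported band
    merged, cluster = [], [act.iloc[0]]
    for _, row in act.iloc[1:].iterrows():
        if row["wavelength"] - cluster[-1]["wavelength"] <= window_nm:
            cluster.append(row)
        else:
            merged.append(cluster)
            cluster = [row]
    merged.append(cluster)
    out = []
    for cl in merged:
        df = pd.DataFrame(cl)
        best = df.loc[df["n_analyses"].idxmax()]
        out.append(
            {
                "wavelength": round(float(df["wavelength"].mean()), 1),
                "n_analyses": int(best["n_analyses"]),
                "analyses": best["analyses"],
            }
        )
    return pd.DataFrame(out)


def _load_or_simulate(cfg: dict) -> SpectraSet:
    if "input" in cfg and cfg["input"]:
        inp = cfg["input"]
        if "spectra" not in inp or "meta" not in inp:
            raise ValueError("config input needs 'spectra' and 'meta' paths")
        return read_spectra_csv(inp["spectra"], inp["meta"])
    sim = cfg["simulate"]
    plan = generate_measurement_plan(
        sim["n_levels"], sim["n_replicates"], sim["n_consecutives"],
        sim["control_interval"], rng_seed=cfg["seed"],
    )
    model = default_model(
        noise_sd=sim["noise_sd"], scatter_sd=sim["scatter_sd"],
        consecutive_drift=sim["consecutive_drift"],
    )
    mapping = {
        lvl: lvl * sim["concentration_step_mM"]
        for lvl in range(1, sim["n_levels"] + 1)
    }
    return simulate_dataset(model, plan, mapping, sim["t_nominal"])


def run_workflow(config_path, output_dir=None) -> Path:
    """Run the full pipeline from a YAML config; returns the output directory."""
    config_path = Path(config_path)
    cfg = _merged(yaml.safe_load(config_path.read_text()) or {})
    out = Path(output_dir or cfg.get("output_dir") or
               config_path.with_suffix("")).resolve()
    seed = int(cfg["seed"])

    def stage(name):
        def fail(exc):
            raise RuntimeError(f"stage {name!r} failed: {exc}") from exc
        return fail

    # --- load / simulate ---------------------------------------------------
    try:
        full = _load_or_simulate(cfg)
    except Exception as exc:  # noqa: BLE001 - aborts with the stage name
        stage("input")(exc)
    out.mkdir(parents=True, exist_ok=True)

    lo, hi = cfg["range"]
    sset = select_wavelength_range(full, lo, hi)
    wamacs = (
        WAMACSTable.from_csv(cfg["wamacs"]) if cfg.get("wamacs")
        else default_wamacs_table()
    )
    band_cfg = cfg["bands"]

    def _bands(vector: np.ndarray) -> pd.DataFrame:
        # prominence is relative: each model vector is scaled to unit max |v|
        scale = np.max(np.abs(vector)) or 1.0
        return find_bands(
            vector / scale, sset.grid,
            min_prominence=band_cfg["min_prominence"],
            min_separation_nm=band_cfg["min_separation_nm"],
        )

    band_lists: dict[str, pd.DataFrame] = {}

    # --- raw inspection + difference spectra -------------------------------
    try:
        controls = sset.meta["role"] == "control"
        samples_only = SpectraSet(
            sset.grid, sset.intensities[~controls.to_numpy()],
            sset.meta[~controls], sset.unit,
        )
        if controls.any():
            water = SpectraSet(
                sset.grid, sset.intensities[controls.to_numpy()],
                sset.meta[controls], sset.unit,
            )
        else:
            water = samples_only
        smoothed = savitzky_golay(sset, 21, 2, 0)
        avg = group_average(smoothed, ["group"])
        avg.meta.to_csv(out / "group_average_meta.csv", index=False)
        diff = subtract_mean_reference(
            group_average(
                savitzky_golay(samples_only, 21, 2, 0), ["group"]
            ),
            savitzky_golay(water, 21, 2, 0),
        )
        _write_matrix(diff.intensities, diff.grid.values,
                      diff.meta["group"], out / "difference_spectra.csv")
        mean_diff = diff.intensities.mean(axis=0)
        band_lists["difference"] = _bands(mean_diff)
    except Exception as exc:
        stage("difference")(exc)

    # --- preprocessing ------------------------------------------------------
    try:
        recipe = PretreatmentRecipe(
            [(d["step"], {k: v for k, v in d.items() if k != "step"})
             for d in cfg["recipe"]]
        )
        pre = recipe.apply(sset)
        deriv2 = savitzky_golay(sset, 21, 2, 2)
        band_lists["second_derivative"] = _bands(
            -deriv2.intensities.mean(axis=0)
        )
    except Exception as exc:
        stage("preprocess")(exc)

    # --- PCA ----------------------------------------------------------------
    try:
        pca = pca_fit(pre)
        n_report = min(6, pca.n_components)
        pca.summary().head(n_report).to_csv(out / "pca_variance.csv", index=False)
        _write_matrix(pca.loadings[:n_report], pca.wavelengths,
                      [f"PC{i+1}" for i in range(n_report)],
                      out / "pca_loadings.csv")
        scores = pd.DataFrame(
            pca.scores[:, :n_report],
            columns=[f"PC{i+1}" for i in range(n_report)],
        )
        scores.insert(0, "group", sset.meta["group"])
        scores.to_csv(out / "pca_scores.csv", index=False)
        for i in range(n_report):
            band_lists[f"pca_loading_{i+1}"] = _bands(pca.loadings[i])
    except Exception as exc:
        stage("pca")(exc)

    # --- PLSR ---------------------------------------------------------------
    try:
        pls_cfg = cfg["plsr"]
        mask = (sset.meta["role"] == "sample").to_numpy()
        xs = SpectraSet(pre.grid, pre.intensities[mask],
                        pre.meta[mask], pre.unit)
        y = xs.meta[pls_cfg["y"]].to_numpy(dtype=float)
        cv = plsr_crossvalidate(xs, y, pls_cfg["cv_key"], pls_cfg["max_lv"])
        model = plsr_fit(xs, y, cv.chosen_lv)
        model.rmsecv, model.r2cv, model.chosen_lv = cv.rmsecv, cv.r2cv, cv.chosen_lv
        cv.summary().to_csv(out / "plsr_rmsecv.csv", index=False)
        pd.DataFrame(
            {"wavelength": model.wavelengths, "b": model.regression_vector}
        ).to_csv(out / "plsr_regression_vector.csv", index=False)
        model.summary().to_csv(out / "plsr_summary.csv", index=False)
        band_lists["plsr_regression_vector"] = _bands(
            model.regression_vector
        )
    except Exception as exc:
        stage("plsr")(exc)

    # --- band collation -----------------------------------------------------
    try:
        for name, bl in band_lists.items():
            bl.to_csv(out / f"bands_{name}.csv", index=False)
        activated = collate_bands(
            band_lists, k=band_cfg["collate_k"],
            window_nm=band_cfg["collate_window_nm"],
        )
        activated.to_csv(out / "activated_bands.csv", index=False)
    except Exception as exc:
        stage("bands")(exc)

    # --- aquagram -----------------------------------------------------------
    try:
        aq_cfg = cfg["aquagram"]
        mode = aq_cfg["mode"]
        if mode == "classic":
            res = classic_aquagram(sset, group_field="group",
                                   pretreatment=aq_cfg["pretreatment"],
                                   wamacs=wamacs)
        elif mode in ("classic_ci", "classic-ci"):
            res = aquagram_bootstrap_ci(
                sset, group_field="group",
                pretreatment=aq_cfg["pretreatment"], B=aq_cfg["B"],
                alpha=aq_cfg["alpha"], rng_seed=seed, wamacs=wamacs,
            )
        elif mode in ("temp", "temp_ci", "temp-ci", "temperature",
                      "temperature_ci"):
            ref_cfg = cfg["reference_library"]
            sim = cfg["simulate"]
            ref_model = default_model(
                noise_sd=sim["noise_sd"], scatter_sd=sim["scatter_sd"],
                consecutive_drift=0.0,
            )
            temps = np.arange(ref_cfg["t_min"],
                              ref_cfg["t_max"] + ref_cfg["t_step"] / 2,
                              ref_cfg["t_step"])
            library = simulate_reference_library(
                ref_model, temps, ref_cfg["replicates"], sset.grid,
                rng_seed=seed + 1,
            )
            calib = fit_temperature_calibration(library, wamacs)
            with_ci = mode.endswith(("ci", "-ci"))
            res = temperature_aquagram(
                sset, calib, wamacs, group_field="group",
                nominal_temperature=cfg["simulate"]["t_nominal"],
                with_ci=with_ci, B=aq_cfg["B"], alpha=aq_cfg["alpha"],
                rng_seed=seed, clamp=True,
            )
        else:
            raise ValueError(f"unknown aquagram mode {mode!r}")
        res.to_frame().to_csv(out / "aquagram.csv")
        res.to_linear_frame().to_csv(out / "aquagram_linear.csv")
        if res.significance is not None:
            res.significance.to_csv(out / "aquagram_significance.csv",
                                    index=False)
    except Exception as exc:
        stage("aquagram")(exc)

    # --- run log ------------------------------------------------------------
    (out / "params.yml").write_text(yaml.safe_dump(cfg, sort_keys=True))
    (out / "run_log.txt").write_text(
        "aquaphot workflow run\n"
        f"version: {__version__}\n"
        f"seed: {seed}\n"
        f"spectra: {full.n_spectra}\n"
        f"range: {lo}-{hi} nm\n"
        f"stages: difference, preprocess, pca, plsr, bands, aquagram\n"
    )
    return out


def _write_matrix(matrix, wavelengths, row_labels, path) -> None:
    pd.DataFrame(
        np.atleast_2d(matrix), index=pd.Index(row_labels, name="row"),
        columns=[repr(float(w)) for w in wavelengths],
    ).to_csv(path)
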