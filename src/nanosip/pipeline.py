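"""End-to-end orchestration: simulate -> correct -> segment -> quantify ->
summarize -> fluxes -> cluster, driven by a YAML/dict configuration.

All randomness is funneled through one top-level seed; a rerun with the
same config and seed produces byte-identical summary tables and the same
manifest hash. Every planted cell is either quantified or listed in a
rejects table with a reason (no silent drops).
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import fluxes as flux_mod
from . import guilds as guild_mod
from . import population_stats as stats_mod
from .constants import DEFAULT_DEAD_TIME_NS
from .ion_imaging import accumulate, correct_dead_time, register_cycles, write_experiment_h5
from .isotope_quant import (
    SubstrateSpec,
    coefficient_of_dispersion,
    quantify_rois,
    records_to_frame,
)
from .segmentation import classify_and_flag, segment_cn
from .synthetic_data import (
    GeneratorConfig,
    IonYields,
    generate_strain_population,
    place_cells_grid,
    render_ion_stacks,
)

__all__ = ["load_config", "run_pipeline"]


class PipelineError(RuntimeError):
    """A stage failure carrying the stage name and offending input."""

    def __init__(self, stage: str, detail: str):
        super().__init__(f"[{stage}] {detail}")
        self.stage = stage


def load_config(path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)


def _generator_config(cfg: dict, seed: int) -> GeneratorConfig:
    acq = cfg.get("acquisition", {})
    yields = IonYields(**acq.get("ion_yields", {}))
    return GeneratorConfig(
        raster_um=acq.get("raster_um", 20.0),
        pixels=acq.get("pixels", 256),
        cycles=acq.get("cycles", 24),
        dwell_ms=acq.get("dwell_ms", 1.0),
        ion_yields=yields,
        seed=seed,
    )


def _substrate(cfg: dict) -> SubstrateSpec:
    return SubstrateSpec(**cfg["substrate"])


def _build_strain_cells(strain: dict, substrate, gen_cfg: GeneratorConfig, seed: int):
    """Planted bacterial (and optional algal) cells for one strain's field."""
    n = strain["n_cells"]
    days = substrate.duration_days
    f13 = generate_strain_population(
        strain["median_xnet_C_daily"], strain.get("cd_C", 0.3), days,
        substrate, n, seed=seed * 7919 + 1, element="C",
    )
    f15 = generate_strain_population(
        strain["median_xnet_N_daily"], strain.get("cd_N", 0.3), days,
        substrate, n, seed=seed * 7919 + 2, element="N",
    )
    cells = place_cells_grid(
        n, strain.get("radius_um", 0.35), gen_cfg,
        kind="bacterial", f13C=f13, f15N=f15,
    )
    n_algal = strain.get("n_algal", 0)
    if n_algal:
        f13_a = generate_strain_population(
            strain["remin_C_daily"], strain.get("cd_remin", 0.2), days,
            substrate, n_algal, seed=seed * 7919 + 3, element="C",
        )
        f15_a = generate_strain_population(
            strain["remin_N_daily"], strain.get("cd_remin", 0.2), days,
            substrate, n_algal, seed=seed * 7919 + 4, element="N",
        )
        # algal cells occupy a reserved band at the bottom of the field
        algal = place_cells_grid(
            n_algal, strain.get("algal_radius_um", 1.5), gen_cfg,
            kind="algal", f13C=f13_a, f15N=f15_a,
            start_id=max(c.cell_id for c in cells) + 1,
        )
        # shift algal cells away from the bacterial grid rows if they collide
        taken = {c.center for c in cells}
        algal = [a for a in algal if a.center not in taken]
        cells = _drop_colliding_bacteria(cells, algal, gen_cfg)
    return cells


def _drop_colliding_bacteria(bacteria, algal, gen_cfg):
    """Remove bacteria whose disk would intersect a (larger) algal disk."""
    px_per_um = gen_cfg.pixels / gen_cfg.raster_um
    kept = []
    for b in bacteria:
        rb = max(b.radii_um) * px_per_um
        ok = True
        for a in algal:
            ra = max(a.radii_um) * px_per_um
            dist = np.hypot(b.center[0] - a.center[0], b.center[1] - a.center[1])
            if dist < ra + rb + 3:
                ok = False
                break
        if ok:
            kept.append(b)
    return kept + list(algal)


def _process_field(stacks, tau_ns: float, seg_cfg: dict, do_register: bool):
    """Dead-time correct, optionally register, accumulate CN, segment."""
    corrected = {name: correct_dead_time(s, tau_ns) for name, s in stacks.items()}
    if do_register:
        _, corrected = register_cycles(
            corrected, reference_species="12C14N",
            max_shift_px=seg_cfg.get("max_shift_px", 8),
        )
    cn_sum = accumulate(corrected["12C14N"])
    labels = segment_cn(cn_sum, min_area_px=seg_cfg.get("min_area_px", 5))
    rois = classify_and_flag(
        labels,
        algal_min_area_px=seg_cfg.get("algal_min_area_px", 80),
        adjacency_px=seg_cfg.get("adjacency_px", 2),
        raster_um=corrected["12C14N"].raster_um,
    )
    return corrected, labels, rois


def _match_truth(truth: pd.DataFrame, labels: np.ndarray) -> pd.DataFrame:
    """Map each planted cell to the ROI label at its center (0 = unmatched)."""
    rows = np.clip(truth["center_row"].round().astype(int), 0, labels.shape[0] - 1)
    cols = np.clip(truth["center_col"].round().astype(int), 0, labels.shape[1] - 1)
    out = truth.copy()
    out["roi_id"] = labels[rows, cols]
    return out


def _strain_summary_row(name: str, df: pd.DataFrame, element: str) -> dict:
    col = f"xnet_{element}_daily"
    vals = df[col].to_numpy()
    row = {
        f"n_{element}": len(vals),
        f"median_xnet_{element}_daily": float(np.median(vals)),
        f"q1_xnet_{element}_daily": float(np.quantile(vals, 0.25)),
        f"q3_xnet_{element}_daily": float(np.quantile(vals, 0.75)),
        f"enriched_fraction_{element}": float(df[f"enriched_{element}"].mean()),
    }
    try:
        row[f"cd_{element}"] = coefficient_of_dispersion(vals)
    except ValueError:
        row[f"cd_{element}"] = np.nan
    return row


def run_pipeline(config: dict | str | Path, out_dir: str | Path, seed: int | None = None) -> dict:
    """Run every stage and write all tables under ``out_dir``.

    Returns a dict with the in-memory tables (per_cell, strain_summary,
    fluxes, guilds, rejects) and the manifest.
    """
    if not isinstance(config, dict):
        config = load_config(config)
    if seed is None:
        seed = int(config.get("seed", 0))
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    substrate = _substrate(config)
    tau_ns = config.get("dead_time_ns", DEFAULT_DEAD_TIME_NS)
    seg_cfg = config.get("segmentation", {})
    do_register = bool(config.get("register_cycles", False))

    # --- stage: killed control ------------------------------------------
    killed_cfg = config.get("killed_control", {})
    gen_killed = _generator_config(config, seed=seed * 104729 + 11)
    killed_cells = place_cells_grid(
        killed_cfg.get("n_cells", 60),
        killed_cfg.get("radius_um", 0.35),
        gen_killed,
        kind="bacterial",
    )
    n_algal_killed = killed_cfg.get("n_algal", 0)
    if n_algal_killed:
        algal = place_cells_grid(
            n_algal_killed, killed_cfg.get("algal_radius_um", 1.5), gen_killed,
            kind="algal", start_id=len(killed_cells) + 1,
        )
        killed_cells = _drop_colliding_bacteria(killed_cells, algal, gen_killed)
    try:
        killed_stacks, killed_truth = render_ion_stacks(killed_cells, gen_killed)
        killed_corr, killed_labels, killed_rois = _process_field(
            killed_stacks, tau_ns, seg_cfg, do_register
        )
        killed_records = quantify_rois(killed_corr, killed_rois, substrate)
    except ValueError as exc:
        raise PipelineError("killed_control", str(exc)) from exc
    killed_df = records_to_frame(killed_records)
    killed_fractions = {
        kind: {
            "C": killed_df.loc[killed_df["kind"] == kind, "f13C"].to_numpy(),
            "N": killed_df.loc[killed_df["kind"] == kind, "f15N"].to_numpy(),
        }
        for kind in killed_df["kind"].unique()
    }

    # --- stage: per-strain fields ---------------------------------------
    per_cell_frames = []
    reject_rows = []
    summary_rows = []
    abundances = {}
    for idx, strain in enumerate(config.get("strains", [])):
        name = strain["name"]
        strain_seed = seed * 104729 + 100 + idx
        gen_cfg = _generator_config(config, seed=strain_seed)
        try:
            cells = _build_strain_cells(strain, substrate, gen_cfg, strain_seed)
            stacks, truth = render_ion_stacks(cells, gen_cfg)
            if config.get("save_stacks", False):
                sim_dir = out_dir / "simulated"
                sim_dir.mkdir(exist_ok=True)
                write_experiment_h5(sim_dir / f"{name}.h5", stacks, seed=strain_seed)
                truth.to_csv(sim_dir / f"{name}_truth.csv", index=False)
            corrected, labels, rois = _process_field(stacks, tau_ns, seg_cfg, do_register)
            roi_by_kind = {k: [r for r in rois if r.kind == k] for k in ("bacterial", "algal")}
            records = []
            for kind, kind_rois in roi_by_kind.items():
                if not kind_rois:
                    continue
                kf = killed_fractions.get(kind) or killed_fractions.get("bacterial")
                records.extend(quantify_rois(corrected, kind_rois, substrate, killed_fractions=kf))
        except ValueError as exc:
            raise PipelineError(f"strain:{name}", str(exc)) from exc

        df = records_to_frame(records)
        df.insert(0, "strain", name)
        per_cell_frames.append(df)

        matched = _match_truth(truth, labels)
        for _, t in matched[matched["roi_id"] == 0].iterrows():
            reject_rows.append(
                {"strain": name, "cell_id": int(t["cell_id"]), "reason": "not segmented"}
            )

        bact = df[df["kind"] == "bacterial"]
        if bact.empty:
            raise PipelineError(f"strain:{name}", "no bacterial ROIs recovered")
        row = {"strain": name}
        for element in ("C", "N"):
            row.update(_strain_summary_row(name, bact, element))
        row["median_area_um2"] = float(bact["area_um2"].median())
        algal_df = df[df["kind"] == "algal"]
        row["remin_C_daily"] = (
            float(algal_df["xnet_C_daily"].median()) if len(algal_df) else np.nan
        )
        row["remin_N_daily"] = (
            float(algal_df["xnet_N_daily"].median()) if len(algal_df) else np.nan
        )
        # significance vs killed controls (Dunn's test after Kruskal-Wallis)
        for element in ("C", "N"):
            kf = killed_fractions.get("bacterial", {}).get(element)
            cell_vals = bact["f13C" if element == "C" else "f15N"].to_numpy()
            if kf is not None and len(kf) >= 2 and len(cell_vals) >= 2:
                groups = {"strain": cell_vals, "killed": kf}
                _, p_kw = stats_mod.kruskal_wallis(groups)
                comp = stats_mod.dunns_test(groups, control="killed")[0]
                row[f"p_vs_killed_{element}"] = comp.p_adjusted
                row[f"significant_{element}"] = bool(
                    p_kw < config.get("stats", {}).get("alpha", 0.05)
                    and comp.p_adjusted < config.get("stats", {}).get("alpha", 0.05)
                )
        summary_rows.append(row)
        if "cells_per_ml" in strain:
            abundances[name] = float(strain["cells_per_ml"])

    per_cell = (
        pd.concat(per_cell_frames, ignore_index=True) if per_cell_frames else pd.DataFrame()
    )
    strain_summary = pd.DataFrame(summary_rows).set_index("strain") if summary_rows else pd.DataFrame()

    # --- stage: fluxes ---------------------------------------------------
    flux_table = pd.DataFrame()
    if abundances and not strain_summary.empty:
        flux_table = flux_mod.strain_flux_table(
            strain_summary, abundances,
            allometry=config.get("allometry"),
        )

    # --- stage: guilds ---------------------------------------------------
    guild_table = pd.DataFrame()
    inertia_table = pd.DataFrame()
    if not strain_summary.empty:
        feats = strain_summary.rename(
            columns={
                "median_xnet_C_daily": "xnet_C_daily",
                "median_xnet_N_daily": "xnet_N_daily",
            }
        )
        complete = feats.loc[:, list(guild_mod.FEATURE_COLUMNS)].dropna()
        if len(complete) >= 4:
            clu = config.get("clustering", {})
            result = guild_mod.assign_guilds(
                feats,
                k_range=tuple(clu.get("k_range", (1, 6))),
                seed=seed,
                n_init=clu.get("n_init", 10),
            )
            guild_table = pd.DataFrame(
                {"strain": list(result.labels), "guild": list(result.labels.values())}
            ).set_index("strain")
            inertia_table = pd.DataFrame(
                {"k": list(result.inertia_by_k), "inertia": list(result.inertia_by_k.values())}
            )

    # --- stage: outputs + manifest ---------------------------------------
    rejects = pd.DataFrame(reject_rows, columns=["strain", "cell_id", "reason"])
    outputs = {
        "per_cell.csv": per_cell,
        "strain_summary.csv": strain_summary.reset_index() if not strain_summary.empty else strain_summary,
        "killed_control.csv": killed_df,
        "fluxes.csv": flux_table.reset_index() if not flux_table.empty else flux_table,
        "guilds.csv": guild_table.reset_index() if not guild_table.empty else guild_table,
        "inertia.csv": inertia_table,
        "rejects.csv": rejects,
    }
    file_hashes = {}
    for fname, df in outputs.items():
        path = out_dir / fname
        df.to_csv(path, index=False, float_format="%.10g")
        file_hashes[fname] = hashlib.sha256(path.read_bytes()).hexdigest()

    config_hash = hashlib.sha256(
        json.dumps(config, sort_keys=True, default=str).encode()
    ).hexdigest()
    manifest = {
        "version": 1,
        "seed": seed,
        "config_hash": config_hash,
        "files": file_hashes,
    }
    manifest["manifest_hash"] = hashlib.sha256(
        json.dumps(manifest, sort_keys=True).encode()
    ).hexdigest()
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))

    return {
        "per_cell": per_cell,
        "strain_summary": strain_summary,
        "killed_control": killed_df,
        "fluxes": flux_table,
        "guilds": guild_table,
        "inertia": inertia_table,
        "rejects": rejects,
        "manifest": manifest,
    }
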