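"""End-to-end demonstration pipelines wired to the synthetic generator.

Two pipelines mirror the study designs the package analyses:

* drug & release by microscopy: repeated imaging of the same organoids over
  several timepoints, thresholded, particle-classified and integrated into
  per-organoid alive/dead series normalized to pre-treatment alive signal;
* plate screen: raw combination-plate signals normalized into a dose matrix,
  4PL fits of monotherapy and diagonal curves, ΔIC50 between two lines, and
  Bliss-excess maps.

Both consume a single :class:`RunConfig` (JSON-serializable, unknown keys
rejected), derive all randomness from one seed, and write a manifest that
echoes every applied parameter so a rerun is byte-identical.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .doseresponse import (
    PRESET_GRIDS,
    bliss_excess,
    delta_ic50,
    fit_curve_from_matrix,
    normalize_viability,
    plot_heatmap,
    smooth_matrix,
)
from .imaging import (
    binarize_channel,
    classify_particles,
    estimate_size_cutoff,
    find_particles,
    masks_from_labels,
    quantify_lower_half,
)
from .synthgen import EventSchedule, OrganoidSimParams, make_plate_reads, make_timelapse

logger = logging.getLogger("organoidquant")

__all__ = ["RunConfig", "run_drugrelease_pipeline", "run_plate_pipeline"]


@dataclass
class RunConfig:
    """Configuration of one pipeline run; every field lands in the manifest."""

    seed: int = 0
    out_dir: str = "run_out"
    # --- drug & release pipeline ---
    # the microscopy assay analyzes 12-15 organoids per well/condition
    n_organoids: int = 12
    timepoints: tuple[int, ...] = (0, 3, 7)
    # scenario: timepoint -> (n_alive, n_dead); "arrest" keeps counts flat,
    # "death" fragments half of the nuclei from the second timepoint on
    scenario: str = "arrest"
    n_alive0: int = 20
    snr: float = 5.0
    stack_shape: tuple[int, int, int] = (96, 96, 12)
    threshold: float | str = "midpoint"
    size_cutoff_px: float | str = "auto"
    # --- plate pipeline ---
    preset: str = "matrix14"
    lines: dict = field(default_factory=lambda: {
        "parental": {"drug_a": [-7.3, 1.0], "drug_b": [-6.7, 1.2]},
        "mutant": {"drug_a": [-5.3, 1.0], "drug_b": [-6.7, 1.2]},
    })
    bliss_excess: float = 0.0
    noise_cv: float = 0.0
    vehicle_signal: float = 1_000_000.0
    plateau_signal: float = 20_000.0
    smooth_window: int = 3
    figures: bool = False

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**d)
        if cfg.scenario not in ("arrest", "death"):
            raise ValueError(f"unknown scenario {cfg.scenario!r}")
        if cfg.preset not in PRESET_GRIDS:
            raise ValueError(f"unknown preset {cfg.preset!r}; have {sorted(PRESET_GRIDS)}")
        return cfg

    @classmethod
    def from_json(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))

    def to_manifest(self, extra: dict | None = None) -> dict:
        manifest = {
            "organoidquant_version": __version__,
            "config": {
                k: (list(v) if isinstance(v, tuple) else v)
                for k, v in dataclasses.asdict(self).items()
            },
        }
        if extra:
            manifest["derived"] = extra
        return manifest


def _write_manifest(out: Path, manifest: dict) -> None:
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")


# ---------------------------------------------------------------------------


def _scenario_schedule(config: RunConfig) -> EventSchedule:
    """Event schedule realizing the configured scenario.

    'arrest' freezes the organoid (no events); 'death' fragments half of the
    nuclei between the first and second imaging timepoints.
    """
    if config.scenario == "arrest":
        return EventSchedule(())
    t_death = (config.timepoints[0] + config.timepoints[1]) / 2.0
    return EventSchedule(
        tuple((t_death, "apoptosis", oid) for oid in range(config.n_alive0 // 2))
    )


def run_drugrelease_pipeline(config: RunConfig) -> pd.DataFrame:
    """Image-based drug & release quantification on synthetic organoid stacks.

    For every organoid and timepoint: generate the stack, threshold the H2B
    channel, detect particles, classify them by size, and integrate
    alive/dead pixel areas over the lower half of the organoid's z-extent.
    Particles are detected volumetrically (3D) here so that whole objects,
    not individual sphere cross-sections, are classified; the per-slice mode
    remains available through the imaging module.  Series are normalized to
    each organoid's pre-treatment alive signal.  Writes viability.csv and
    manifest.json to the output directory and returns the per-organoid table.
    """
    if len(config.timepoints) < 2:
        raise ValueError("need stacks for at least 2 timepoints")
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    logger.info("drug & release pipeline: %d organoids, timepoints %s",
                config.n_organoids, config.timepoints)

    timepoints = [float(t) for t in config.timepoints]
    rows = []
    derived: dict = {}
    for org in range(config.n_organoids):
        # the same organoid is re-imaged at every timepoint (paired design):
        # one persistent placement, transformed by the scenario's events
        params = OrganoidSimParams(
            stack_shape=tuple(config.stack_shape),
            n_alive=config.n_alive0,
            n_dead=0,
            # a dying nucleus shatters into fragments that together keep
            # roughly its voxel volume: 8 fragments at half the radius
            fragments_per_dead=8,
            fragment_radius_px=2.45,
            snr=config.snr,
            seed=int((config.seed * 1009 + org * 101) % 2**31),
        )
        interval = np.gcd.reduce(np.asarray(config.timepoints, dtype=int)[1:])
        stack, _log, _ft = make_timelapse(
            params,
            _scenario_schedule(config),
            frame_interval_min=float(interval),
            duration_min=timepoints[-1],
        )
        if config.threshold == "midpoint":
            thr = params.background_level * (1 + params.snr) / 2
        else:
            thr = float(config.threshold)
        cutoff = None
        for day in timepoints:
            frame = int(round(day / interval))
            mask = binarize_channel(stack, "H2B", thr, t=frame)
            particles = find_particles(mask, mode="volume3d")
            if cutoff is None:
                cutoff = (
                    estimate_size_cutoff(particles)
                    if config.size_cutoff_px == "auto"
                    else float(config.size_cutoff_px)
                )
                derived.setdefault("size_cutoff_px", {})[str(org)] = cutoff
            classified = classify_particles(particles, cutoff)
            alive_mask, dead_mask = masks_from_labels(classified, mask.mask.shape)
            extent = mask.z_support()
            if extent is None:
                raise ValueError(f"organoid {org} day {day}: empty mask")
            quant = quantify_lower_half(alive_mask, dead_mask, extent,
                                        organoid_id=org, timepoint=day)
            rows.append(
                dict(
                    organoid_id=org,
                    timepoint=day,
                    alive_px=quant.alive_px,
                    dead_px=quant.dead_px,
                    z_lo=quant.z_range[0],
                    z_hi=quant.z_range[1],
                    threshold=thr,
                    size_cutoff_px=cutoff,
                )
            )
    table = pd.DataFrame(rows)
    # normalize to pre-treatment alive signal
    base = table[table["timepoint"] == config.timepoints[0]].set_index("organoid_id")[
        "alive_px"
    ]
    table["alive_norm"] = table["alive_px"] / table["organoid_id"].map(base)
    table["dead_norm"] = table["dead_px"] / table["organoid_id"].map(base)
    table["dead_fraction"] = table["dead_px"] / (table["alive_px"] + table["dead_px"])

    table.to_csv(out / "viability.csv", index=False)
    _write_manifest(out, config.to_manifest(extra=derived))
    return table


# ---------------------------------------------------------------------------


def run_plate_pipeline(config: RunConfig) -> dict:
    """Plate screen: normalize, fit, compare and score synthetic dose matrices.

    Generates raw combination-plate reads for every configured line, then
    produces the normalized dose matrix, monotherapy and equimolar-diagonal
    4PL fits, a ΔIC50 table between all line pairs, and the (optionally
    smoothed) Bliss-excess matrix.  Writes CSV/JSON reports and returns the
    in-memory results keyed by line.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    grid = PRESET_GRIDS[config.preset]
    results: dict = {}
    fits_rows = []
    try:
        for li, (line, drugs) in enumerate(sorted(config.lines.items())):
            reads = make_plate_reads(
                drug_a=tuple(drugs["drug_a"]),
                drug_b=tuple(drugs["drug_b"]),
                grid_a_nM=grid,
                grid_b_nM=grid,
                bliss_excess=config.bliss_excess,
                vehicle_signal=config.vehicle_signal,
                plateau_signal=config.plateau_signal,
                noise_cv=config.noise_cv,
                seed=int((config.seed * 2003 + li) % 2**31),
            )
            if (reads["role"] == "treated").sum() == 0:
                raise ValueError("no treated wells on the plate")
            reads.to_csv(out / f"reads_{line}.csv", index=False)
            matrix = normalize_viability(reads)
            matrix.to_frame().to_csv(out / f"dosematrix_{line}.csv")
            bliss = bliss_excess(matrix)
            bliss_s = smooth_matrix(bliss, config.smooth_window)
            bliss_s.to_frame().to_csv(out / f"bliss_{line}.csv")
            fits = {
                mode: fit_curve_from_matrix(matrix, mode)
                for mode in ("row_a_mono", "col_b_mono", "fixed_ratio_diagonal")
            }
            for mode, f in fits.items():
                fits_rows.append(
                    dict(line=line, curve=mode, log10_ic50_M=f.log10_ic50,
                         hill_slope=f.hill_slope, rss=f.rss, n=f.n_points,
                         converged=f.converged)
                )
            if config.figures:
                plot_heatmap(matrix, out / f"heatmap_{line}.png", title=line)
                plot_heatmap(bliss_s, out / f"blissmap_{line}.png",
                             title=f"{line} Bliss excess")
            results[line] = dict(matrix=matrix, bliss=bliss_s, fits=fits)
    except ValueError as err:
        raise RuntimeError(f"plate pipeline failed at stage 'normalize/fit': {err}") from err

    fit_table = pd.DataFrame(fits_rows)
    fit_table.to_csv(out / "ic50_fits.csv", index=False)

    delta_rows = []
    lines = sorted(results)
    for i, la in enumerate(lines):
        for lb in lines[i + 1:]:
            for mode in ("row_a_mono", "col_b_mono", "fixed_ratio_diagonal"):
                delta_rows.append(
                    dict(
                        line_a=la,
                        line_b=lb,
                        curve=mode,
                        delta_log10_ic50=delta_ic50(
                            results[la]["fits"][mode], results[lb]["fits"][mode]
                        ),
                    )
                )
    delta_table = pd.DataFrame(delta_rows)
    delta_table.to_csv(out / "delta_ic50.csv", index=False)
    results["delta_ic50"] = delta_table
    results["fit_table"] = fit_table
    _write_manifest(out, config.to_manifest())
    return results
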