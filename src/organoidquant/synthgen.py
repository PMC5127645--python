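"""Ground-truthed synthetic data emulating organoid drug-response experiments.

Generators for the four data modalities the analysis modules consume:

* 3D confocal-like stacks of H2B-labelled nuclei, where live nuclei are
  compact bright blobs and dead cells appear as clusters of small bright
  fragments, optionally with a propidium-iodide (PI) channel that marks
  only the dead fragments;
* XYZT time-lapses driven by an explicit mitosis/apoptosis schedule;
* drug-plate raw signals drawn from four-parameter-logistic (4PL)
  viability surfaces with optional Bliss excess and multiplicative noise;
* alamarBlue-style fluorescence kinetics with a linear phase followed by
  saturation.

Every generator is a pure function of its parameters and an integer seed,
and returns the ground truth needed to score downstream quantification.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .imaging import ImageStack

__all__ = [
    "OrganoidSimParams",
    "GroundTruth",
    "EventSchedule",
    "PlacementError",
    "make_organoid_stack",
    "make_timelapse",
    "make_plate_reads",
    "make_ab_kinetics",
    "make_cellcycle_sample",
    "four_pl_viability",
]

MAX_PLACEMENT_RETRIES = 1000


class PlacementError(RuntimeError):
    """Raised when nuclei cannot be placed without overlap within the retry bound."""


@dataclass(frozen=True)
class OrganoidSimParams:
    """Parameters of one synthetic organoid stack.

    ``stack_shape`` is (nx, ny, nz) in voxels; arrays are stored (z, y, x).
    ``snr`` is the ratio of foreground blob intensity to mean background.
    Intensity units are arbitrary; background sits at ``background_level``
    with additive Gaussian noise of ``noise_sd``.
    """

    stack_shape: tuple[int, int, int] = (96, 96, 12)
    pixel_size_um: float = 1.0
    z_step_um: float = 2.0
    n_alive: int = 20
    n_dead: int = 5
    alive_radius_px: float = 5.0
    alive_radius_spread: float = 0.15
    fragment_radius_px: float = 1.8
    fragments_per_dead: int = 4
    snr: float = 5.0
    background_level: float = 100.0
    noise_sd: float = 10.0
    pi_channel: bool = False
    seed: int = 0

    def validate(self) -> None:
        nx, ny, nz = self.stack_shape
        if nx <= 0 or ny <= 0 or nz <= 0:
            raise ValueError(f"stack dimensions must be positive, got {self.stack_shape}")
        if min(self.n_alive, self.n_dead, self.fragments_per_dead) < 0:
            raise ValueError("counts must be >= 0")
        if not self.fragment_radius_px < self.alive_radius_px:
            raise ValueError("fragment_radius_px must be smaller than alive_radius_px")
        if self.snr <= 1:
            raise ValueError("snr must exceed 1 (foreground above background)")
        if self.noise_sd < 0 or self.background_level <= 0:
            raise ValueError("background_level must be > 0 and noise_sd >= 0")


@dataclass
class GroundTruth:
    """Per-object truth labels for one stack (or one time-lapse frame).

    ``objects`` has one row per object: object_id, class_label
    ('alive' | 'dead-fragment'), parent_id (dead fragments share the id of
    the cell that shattered), centroid x/y/z and voxel count.  ``voxels``
    maps object_id -> (N, 3) int array of (z, y, x) indices; voxel sets are
    disjoint across objects.
    """

    objects: pd.DataFrame
    voxels: dict[int, np.ndarray] = field(default_factory=dict)

    @property
    def n_alive(self) -> int:
        return int((self.objects["class_label"] == "alive").sum())

    @property
    def n_dead_fragments(self) -> int:
        return int((self.objects["class_label"] == "dead-fragment").sum())

    def foreground_voxel_count(self) -> int:
        return int(sum(len(v) for v in self.voxels.values()))

    def dead_voxel_fraction(self) -> float:
        """Fraction of foreground voxels that belong to dead fragments."""
        dead = sum(
            len(self.voxels[i])
            for i in self.objects.loc[
                self.objects["class_label"] == "dead-fragment", "object_id"
            ]
        )
        total = self.foreground_voxel_count()
        return dead / total if total else float("nan")

    def to_frame(self) -> pd.DataFrame:
        return self.objects.copy()


@dataclass(frozen=True)
class EventSchedule:
    """Timed mitosis/apoptosis events addressed to ground-truth object ids."""

    events: tuple[tuple[float, str, int], ...]  # (time_min, event_type, object_id)

    def __post_init__(self) -> None:
        seen_apoptosis: set[int] = set()
        for t, kind, oid in self.events:
            if t < 0:
                raise ValueError("event times must be >= 0")
            if kind not in ("mitosis", "apoptosis"):
                raise ValueError(f"unknown event type {kind!r}")
            if kind == "apoptosis":
                if oid in seen_apoptosis:
                    raise ValueError(f"object {oid} dies twice")
                seen_apoptosis.add(oid)

    def sorted(self) -> list[tuple[float, str, int]]:
        return sorted(self.events, key=lambda e: e[0])

    @property
    def latest_time(self) -> float:
        return max((e[0] for e in self.events), default=0.0)


# ---------------------------------------------------------------------------
# blob rendering


def _ellipsoid_voxels(
    center: tuple[float, float, float],
    radius_px: float,
    z_scale: float,
    shape_zyx: tuple[int, int, int],
) -> np.ndarray:
    """Voxel indices of an xy-isotropic ellipsoid; z radius shrunk by z_scale.

    z_scale = pixel_size_um / z_step_um converts an xy-pixel radius into
    z-plane units (anisotropic sampling).
    """
    cz, cy, cx = center
    rz = max(radius_px * z_scale, 0.51)  # keep at least one plane
    ry = rx = radius_px
    nz, ny, nx = shape_zyx
    z0, z1 = max(int(np.floor(cz - rz)), 0), min(int(np.ceil(cz + rz)), nz - 1)
    y0, y1 = max(int(np.floor(cy - ry)), 0), min(int(np.ceil(cy + ry)), ny - 1)
    x0, x1 = max(int(np.floor(cx - rx)), 0), min(int(np.ceil(cx + rx)), nx - 1)
    zz, yy, xx = np.mgrid[z0 : z1 + 1, y0 : y1 + 1, x0 : x1 + 1]
    d2 = ((zz - cz) / rz) ** 2 + ((yy - cy) / ry) ** 2 + ((xx - cx) / rx) ** 2
    inside = d2 <= 1.0
    return np.stack([zz[inside], yy[inside], xx[inside]], axis=1)


def _blob_profile(voxels: np.ndarray, center: tuple[float, float, float],
                  radius_px: float, z_scale: float) -> np.ndarray:
    """Gaussian intensity profile, floored so the blob edge stays at >= 0.75 peak.

    The floor keeps the whole truth voxel set above the midpoint of the
    background/foreground gap for any snr > 1, so a midpoint threshold
    recovers the truth foreground exactly in the noiseless limit.
    """
    cz, cy, cx = center
    rz = max(radius_px * z_scale, 0.51)
    d2 = (
        ((voxels[:, 0] - cz) / rz) ** 2
        + ((voxels[:, 1] - cy) / radius_px) ** 2
        + ((voxels[:, 2] - cx) / radius_px) ** 2
    )
    return np.maximum(np.exp(-1.5 * d2), 0.75)


def _dilate_voxels(
    voxels: np.ndarray, shape_zyx: tuple[int, int, int], steps: int
) -> np.ndarray:
    """Chebyshev dilation of a voxel index set, clipped to the stack bounds."""
    if steps <= 0:
        return voxels
    offsets = np.array(
        [
            (dz, dy, dx)
            for dz in range(-steps, steps + 1)
            for dy in range(-steps, steps + 1)
            for dx in range(-steps, steps + 1)
        ]
    )
    grown = (voxels[:, None, :] + offsets[None, :, :]).reshape(-1, 3)
    grown = np.clip(grown, 0, np.array(shape_zyx) - 1)
    return np.unique(grown, axis=0)


def _place_object(
    rng: np.random.Generator,
    occupancy: np.ndarray,
    radius_px: float,
    z_scale: float,
    center_hint: tuple[float, float, float] | None = None,
    hint_spread_px: float = 0.0,
    margin_px: float = 1.0,
) -> tuple[tuple[float, float, float], np.ndarray]:
    """Rejection-sample a non-overlapping position; fail after the retry bound.

    Candidate positions are tested with the radius inflated by ``margin_px``
    so placed objects are not just disjoint but separated — connected
    components of the rendered foreground then correspond to single objects.
    """
    nz, ny, nx = occupancy.shape
    rz = max(radius_px * z_scale, 0.51)
    for _ in range(MAX_PLACEMENT_RETRIES):
        if center_hint is None:
            center = (
                rng.uniform(rz, max(nz - 1 - rz, rz)),
                rng.uniform(radius_px, max(ny - 1 - radius_px, radius_px)),
                rng.uniform(radius_px, max(nx - 1 - radius_px, radius_px)),
            )
        else:
            offset = rng.uniform(-hint_spread_px, hint_spread_px, size=3)
            center = (
                float(np.clip(center_hint[0] + offset[0] * z_scale, rz, max(nz - 1 - rz, rz))),
                float(np.clip(center_hint[1] + offset[1], radius_px, max(ny - 1 - radius_px, radius_px))),
                float(np.clip(center_hint[2] + offset[2], radius_px, max(nx - 1 - radius_px, radius_px))),
            )
        voxels = _ellipsoid_voxels(center, radius_px, z_scale, occupancy.shape)
        if len(voxels) == 0:
            continue
        if not occupancy[voxels[:, 0], voxels[:, 1], voxels[:, 2]].any():
            # reserve the 26-neighbourhood-dilated voxel set: placed objects
            # are then separated, not merely disjoint, so connected
            # components of the rendered foreground map 1:1 onto objects
            grown = _dilate_voxels(voxels, occupancy.shape, int(np.ceil(margin_px)))
            occupancy[grown[:, 0], grown[:, 1], grown[:, 2]] = True
            return center, voxels
    raise PlacementError(
        f"could not place object of radius {radius_px} px after "
        f"{MAX_PLACEMENT_RETRIES} retries (stack overcrowded)"
    )


def _render_scene(
    params: OrganoidSimParams,
    rng: np.random.Generator,
    alive_centers: list[tuple[tuple[float, float, float], float]] | None = None,
    dead_sites: list[tuple[float, float, float]] | None = None,
) -> tuple[np.ndarray, GroundTruth]:
    """Render one frame.  If centers/sites are given they are used verbatim
    (time-lapse mode); otherwise objects are placed randomly."""
    nx, ny, nz = params.stack_shape
    shape_zyx = (nz, ny, nx)
    z_scale = params.pixel_size_um / params.z_step_um
    occupancy = np.zeros(shape_zyx, dtype=bool)
    fg_level = params.snr * params.background_level

    h2b = np.zeros(shape_zyx, dtype=np.float64)
    pi = np.zeros(shape_zyx, dtype=np.float64) if params.pi_channel else None

    records: list[dict] = []
    voxel_map: dict[int, np.ndarray] = {}
    next_id = 0

    def add_blob(center, radius, class_label, parent_id, channel_pi):
        nonlocal next_id
        voxels = _ellipsoid_voxels(center, radius, z_scale, shape_zyx)
        profile = fg_level * _blob_profile(voxels, center, radius, z_scale)
        h2b[voxels[:, 0], voxels[:, 1], voxels[:, 2]] = profile
        if channel_pi and pi is not None:
            pi[voxels[:, 0], voxels[:, 1], voxels[:, 2]] = profile
        records.append(
            dict(
                object_id=next_id,
                class_label=class_label,
                parent_id=parent_id,
                x=center[2],
                y=center[1],
                z=center[0],
                n_voxels=len(voxels),
            )
        )
        voxel_map[next_id] = voxels
        next_id += 1

    # live nuclei
    if alive_centers is None:
        alive_centers = []
        for _ in range(params.n_alive):
            r = params.alive_radius_px * (
                1 + rng.uniform(-params.alive_radius_spread, params.alive_radius_spread)
            )
            center, _vox = _place_object(rng, occupancy, r, z_scale)
            alive_centers.append((center, r))
    else:
        for center, r in alive_centers:
            vox = _dilate_voxels(
                _ellipsoid_voxels(center, r, z_scale, shape_zyx), shape_zyx, 1
            )
            occupancy[vox[:, 0], vox[:, 1], vox[:, 2]] = True
    for center, r in alive_centers:
        add_blob(center, r, "alive", parent_id=None, channel_pi=False)

    # dead cells shatter into fragments scattered within one nucleus diameter
    if dead_sites is None:
        dead_sites = []
        for _ in range(params.n_dead):
            site, site_vox = _place_object(rng, occupancy, params.alive_radius_px, z_scale)
            # the site reservation only prevents other nuclei landing there
            occupancy[site_vox[:, 0], site_vox[:, 1], site_vox[:, 2]] = False
            dead_sites.append(site)
    for site in dead_sites:
        parent = next_id
        for _ in range(params.fragments_per_dead):
            center, _vox = _place_object(
                rng,
                occupancy,
                params.fragment_radius_px,
                z_scale,
                center_hint=site,
                hint_spread_px=2 * params.alive_radius_px,
            )
            add_blob(center, params.fragment_radius_px, "dead-fragment",
                     parent_id=parent, channel_pi=True)

    columns = ["object_id", "class_label", "parent_id", "x", "y", "z", "n_voxels"]
    objects = pd.DataFrame(records, columns=columns)
    truth = GroundTruth(objects=objects, voxels=voxel_map)

    # additive Gaussian background; blobs sit on top of the background level
    channels = [h2b] + ([pi] if pi is not None else [])
    rendered = []
    for ch in channels:
        img = ch + params.background_level
        if params.noise_sd > 0:
            img = img + rng.normal(0.0, params.noise_sd, size=ch.shape)
        rendered.append(np.clip(img, 0, 65535))
    data = np.stack(rendered, axis=1)  # (z, c, y, x)
    return data, truth


def make_organoid_stack(params: OrganoidSimParams) -> tuple[ImageStack, GroundTruth]:
    """Render a single synthetic organoid stack plus its ground truth.

    Returns an :class:`~organoidquant.imaging.ImageStack` with axes ZCYX
    (channels 'H2B' and, if requested, 'PI') in uint16, and the per-object
    :class:`GroundTruth`.
    """
    params.validate()
    rng = np.random.default_rng(params.seed)
    data, truth = _render_scene(params, rng)
    names = ["H2B", "PI"] if params.pi_channel else ["H2B"]
    stack = ImageStack(
        data=data.astype(np.uint16),
        axes="ZCYX",
        pixel_size_um=params.pixel_size_um,
        z_step_um=params.z_step_um,
        channel_names=tuple(names),
    )
    return stack, truth


# ---------------------------------------------------------------------------
# time-lapse


def make_timelapse(
    params: OrganoidSimParams,
    schedule: EventSchedule,
    frame_interval_min: float = 15.0,
    duration_min: float = 120.0,
) -> tuple[ImageStack, pd.DataFrame, pd.DataFrame]:
    """Simulate an XYZT acquisition driven by a mitosis/apoptosis schedule.

    The initial frame holds ``params.n_alive`` live nuclei (ids 0..n-1) and no
    dead cells.  At a mitosis the parent blob is replaced by two daughters
    placed beside it; at an apoptosis the blob shatters into
    ``params.fragments_per_dead`` fragments at the death site.  An event takes
    effect at the first frame whose time is >= the event time.

    Returns ``(stack, event_log, frame_truth)`` where ``event_log`` is the
    realized schedule (columns organoid_id, time_min, event_type) and
    ``frame_truth`` records the true alive/dead-fragment counts per frame.
    """
    params.validate()
    if duration_min < schedule.latest_time:
        raise ValueError("duration_min must cover the latest scheduled event")
    rng = np.random.default_rng(params.seed)
    z_scale = params.pixel_size_um / params.z_step_um
    nx, ny, nz = params.stack_shape
    shape_zyx = (nz, ny, nx)

    # initial placement
    occupancy = np.zeros(shape_zyx, dtype=bool)
    alive: dict[int, tuple[tuple[float, float, float], float]] = {}
    next_id = 0
    for _ in range(params.n_alive):
        r = params.alive_radius_px * (
            1 + rng.uniform(-params.alive_radius_spread, params.alive_radius_spread)
        )
        center, _ = _place_object(rng, occupancy, r, z_scale)
        alive[next_id] = (center, r)
        next_id += 1
    dead_sites: list[tuple[float, float, float]] = []

    events = schedule.sorted()
    for _, _, oid in events:
        if oid >= params.n_alive:
            raise KeyError(f"event references unknown object id {oid}")

    times = np.arange(0.0, duration_min + 1e-9, frame_interval_min)
    frames = []
    truth_rows = []
    realized = []
    ei = 0
    for fi, t in enumerate(times):
        while ei < len(events) and events[ei][0] <= t:
            etime, kind, oid = events[ei]
            if oid not in alive:
                raise KeyError(f"event references object id {oid} that is no longer alive")
            center, r = alive.pop(oid)
            vox = _ellipsoid_voxels(center, r, z_scale, shape_zyx)
            occupancy[vox[:, 0], vox[:, 1], vox[:, 2]] = False
            if kind == "mitosis":
                r_d = r / 2 ** (1 / 3)  # daughters conserve combined volume
                for _ in range(2):
                    c_d, _ = _place_object(
                        rng, occupancy, r_d, z_scale,
                        center_hint=center, hint_spread_px=2 * r,
                    )
                    alive[next_id] = (c_d, r_d)
                    next_id += 1
            else:
                dead_sites.append(center)
            realized.append(dict(organoid_id=oid, time_min=etime, event_type=kind))
            ei += 1

        frame_params = replace(params, n_alive=0, n_dead=0, noise_sd=params.noise_sd)
        frame_rng = np.random.default_rng((params.seed, fi))
        data, truth = _render_scene(
            frame_params,
            frame_rng,
            alive_centers=list(alive.values()),
            dead_sites=list(dead_sites),
        )
        frames.append(data)
        truth_rows.append(
            dict(
                frame=fi,
                time_min=float(t),
                n_alive=truth.n_alive,
                n_dead_fragments=truth.n_dead_fragments,
            )
        )

    data = np.stack(frames, axis=0)  # (t, z, c, y, x)
    names = ["H2B", "PI"] if params.pi_channel else ["H2B"]
    stack = ImageStack(
        data=data.astype(np.uint16),
        axes="TZCYX",
        pixel_size_um=params.pixel_size_um,
        z_step_um=params.z_step_um,
        channel_names=tuple(names),
    )
    event_log = pd.DataFrame(realized, columns=["organoid_id", "time_min", "event_type"])
    frame_truth = pd.DataFrame(truth_rows)
    return stack, event_log, frame_truth


def classification_scores(truth: GroundTruth, classified, labels: np.ndarray) -> dict:
    """Per-object precision/recall/F1 of an alive/dead particle classification.

    Each ground-truth object is assigned the label of the particle covering
    the majority of its voxels (no particle -> counted as missed).  'dead'
    (fragment detection) is the positive class.
    """
    table = classified.particles.set_index("particle_id")["label"]
    tp = fp = fn = tn = 0
    for _, row in truth.objects.iterrows():
        vox = truth.voxels[row["object_id"]]
        ids, counts = np.unique(labels[vox[:, 0], vox[:, 1], vox[:, 2]], return_counts=True)
        nonzero = ids > 0
        predicted = None
        if nonzero.any():
            best = ids[nonzero][np.argmax(counts[nonzero])]
            predicted = table.get(best)
        is_dead = row["class_label"] == "dead-fragment"
        if is_dead and predicted == "dead":
            tp += 1
        elif is_dead:
            fn += 1
        elif predicted == "dead":
            fp += 1
        else:
            tn += 1
    precision = tp / (tp + fp) if tp + fp else 1.0
    recall = tp / (tp + fn) if tp + fn else 1.0
    f1 = 2 * precision * recall / (precision + recall) if precision + recall else 0.0
    return dict(precision=precision, recall=recall, f1=f1,
                tp=tp, fp=fp, fn=fn, tn=tn)


# ---------------------------------------------------------------------------
# plates


def four_pl_viability(conc: np.ndarray, log10_ic50: float, hill_slope: float) -> np.ndarray:
    """Fractional viability of the normalized 4PL (top 1, bottom 0).

    v(c) = 1 / (1 + 10**((log10 c - log10_ic50) * hill_slope)); hill_slope > 0
    gives the usual descending dose-response.  conc in the same units as the
    IC50 (molar here); conc = 0 maps to v = 1.
    """
    conc = np.asarray(conc, dtype=float)
    out = np.ones_like(conc)
    pos = conc > 0
    x = np.log10(conc[pos])
    out[pos] = 1.0 / (1.0 + 10 ** ((x - log10_ic50) * hill_slope))
    return out


def make_plate_reads(
    drug_a: tuple[float, float],
    drug_b: tuple[float, float] | None,
    grid_a_nM: np.ndarray,
    grid_b_nM: np.ndarray | None = None,
    bliss_excess: float | np.ndarray = 0.0,
    vehicle_signal: float = 1_000_000.0,
    plateau_signal: float = 20_000.0,
    noise_cv: float = 0.0,
    n_vehicle_wells: int = 8,
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate raw ATP-type plate signals over a (combination) dose grid.

    ``drug_a``/``drug_b`` are (log10_ic50, hill_slope) with the IC50 on the
    molar scale.  Monotherapy wells follow the 4PL; combination wells follow
    Bliss independence (v = vA*vB) minus ``bliss_excess`` (scalar or a grid
    matching len(grid_a) x len(grid_b)), floored at 0.  Raw signal =
    plateau + v*(vehicle - plateau), multiplied by lognormal noise with the
    given coefficient of variation.  Returns a tidy DataFrame with columns
    well, conc_a_nM, conc_b_nM, signal, role.
    """
    if noise_cv < 0:
        raise ValueError("noise_cv must be >= 0")
    if vehicle_signal <= plateau_signal:
        raise ValueError("vehicle_signal must exceed plateau_signal")
    grid_a_nM = np.asarray(grid_a_nM, dtype=float)
    if np.any(grid_a_nM <= 0):
        raise ValueError("concentrations must be > 0")
    if grid_b_nM is not None:
        grid_b_nM = np.asarray(grid_b_nM, dtype=float)
        if np.any(grid_b_nM <= 0):
            raise ValueError("concentrations must be > 0")

    ca = np.concatenate([[0.0], grid_a_nM])
    cb = np.concatenate([[0.0], grid_b_nM]) if grid_b_nM is not None else np.array([0.0])
    va = four_pl_viability(ca * 1e-9, *drug_a)
    vb = four_pl_viability(cb * 1e-9, *drug_b) if drug_b is not None else np.ones_like(cb)
    v = np.outer(va, vb)

    excess = np.zeros_like(v)
    if np.ndim(bliss_excess) == 0:
        excess[1:, 1:] = float(bliss_excess)
    else:
        be = np.asarray(bliss_excess, dtype=float)
        if be.shape != (len(grid_a_nM), len(cb) - 1):
            raise ValueError("bliss_excess grid shape must match (len(grid_a), len(grid_b))")
        excess[1:, 1:] = be
    v = np.clip(v - excess, 0.0, None)

    rows = []
    for i, a in enumerate(ca):
        for j, b in enumerate(cb):
            if a == 0 and b == 0:
                continue  # vehicle wells added separately below
            rows.append((a, b, v[i, j], "treated"))
    for _ in range(max(n_vehicle_wells, 1)):
        rows.append((0.0, 0.0, 1.0, "vehicle"))

    rng = np.random.default_rng(seed)
    records = []
    for widx, (a, b, vi, role) in enumerate(rows):
        signal = plateau_signal + vi * (vehicle_signal - plateau_signal)
        if noise_cv > 0:
            sigma = np.sqrt(np.log1p(noise_cv**2))
            signal *= rng.lognormal(mean=-(sigma**2) / 2, sigma=sigma)
        records.append(
            dict(well=f"W{widx:04d}", conc_a_nM=a, conc_b_nM=b, signal=signal, role=role)
        )
    return pd.DataFrame.from_records(records)


# ---------------------------------------------------------------------------
# alamarBlue kinetics


def make_ab_kinetics(
    true_viability: float,
    background_rfu: float = 100.0,
    slope_rfu_per_h: float = 200.0,
    saturation_t_h: float = 3.0,
    read_times_h: np.ndarray | None = None,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Resazurin-reduction fluorescence kinetics: linear rise, then saturation.

    RFU(t) = background + true_viability * slope * min(t, saturation_t) + noise.
    Default reads every 15 min over 2 h, matching a plate-reader time course.
    Returns a DataFrame with columns time_h, rfu.
    """
    if slope_rfu_per_h < 0:
        raise ValueError("slope must be >= 0")
    if read_times_h is None:
        read_times_h = np.arange(0.0, 2.0 + 1e-9, 0.25)
    t = np.asarray(read_times_h, dtype=float)
    if t[0] != 0 or np.any(np.diff(t) < 0):
        raise ValueError("read times must start at 0 and be non-decreasing")
    rfu = background_rfu + true_viability * slope_rfu_per_h * np.minimum(t, saturation_t_h)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        rfu = rfu + rng.normal(0.0, noise_sd, size=t.shape)
    return pd.DataFrame({"time_h": t, "rfu": rfu})


# ---------------------------------------------------------------------------
# flow-cytometry style cell-cycle sample


def make_cellcycle_sample(
    fractions: tuple[float, float, float] = (0.6, 0.25, 0.15),
    n_cells: int = 5000,
    dna_2n: float = 100.0,
    noise_cv: float = 0.05,
    edu_neg_mean: float = 50.0,
    edu_pos_mean: float = 1000.0,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.Series]:
    """Simulate an EdU x DNA flow sample from known G1/S/G2 fractions.

    G1 cells carry 2N DNA, G2 cells 4N, S cells uniform in between; EdU is
    lognormal around a dim level except in S, where it is bright.  Returns
    the per-cell table (columns dna, edu) and the true phase per cell.
    """
    f = np.asarray(fractions, dtype=float)
    if np.any(f < 0) or not np.isclose(f.sum(), 1.0):
        raise ValueError("fractions must be non-negative and sum to 1")
    rng = np.random.default_rng(seed)
    phases = rng.choice(np.array(["G1", "S", "G2"]), size=n_cells, p=f)
    dna = np.empty(n_cells)
    dna[phases == "G1"] = dna_2n
    dna[phases == "G2"] = 2 * dna_2n
    n_s = int((phases == "S").sum())
    dna[phases == "S"] = rng.uniform(1.15 * dna_2n, 1.85 * dna_2n, size=n_s)
    dna *= rng.lognormal(0.0, np.sqrt(np.log1p(noise_cv**2)), size=n_cells)
    edu = np.where(
        phases == "S",
        rng.lognormal(np.log(edu_pos_mean), 0.3, size=n_cells),
        rng.lognormal(np.log(edu_neg_mean), 0.3, size=n_cells),
    )
    sample = pd.DataFrame({"dna": dna, "edu": edu})
    return sample, pd.Series(phases, name="phase")
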