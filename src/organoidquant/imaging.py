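"""Image quantification for 3D(+T) fluorescence stacks of labelled organoids.

Implements the live/dead nuclear quantification workflow: intensity
thresholding of the H2B channel, per-slice or volumetric particle detection,
size-based alive/dead classification, integration over the lower half of an
organoid's z-extent, hue-by-depth maximum projections, an automatic
ramped-threshold optimum, and the pooled PI/H2B cell-death ratio.

Conventions (fixed for determinism): foreground is intensity >= threshold;
indices are 0-based with z = 0 the bottom plane; a particle exactly at the
size cutoff counts as alive; depth-projection argmax ties resolve to the
lowest z.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import matplotlib
from skimage import measure

__all__ = [
    "ImageStack",
    "BinaryMask",
    "ParticleSet",
    "ViabilityQuant",
    "DeathRatio",
    "ThresholdScan",
    "binarize_channel",
    "find_particles",
    "classify_particles",
    "estimate_size_cutoff",
    "quantify_lower_half",
    "depth_coded_projection",
    "ramp_threshold_optimum",
    "pi_h2b_death_ratio",
]


@dataclass
class ImageStack:
    """Multi-channel voxel grid with physical z spacing.

    ``axes`` names the dimensions of ``data`` using a subset of "TZCYX" in
    that order (e.g. "ZYX", "ZCYX", "TZCYX").  z index 0 is the bottom plane.
    """

    data: np.ndarray
    axes: str = "ZYX"
    pixel_size_um: float = 1.0
    z_step_um: float = 1.0
    channel_names: tuple[str, ...] = ("H2B",)

    def __post_init__(self) -> None:
        if self.data.ndim != len(self.axes):
            raise ValueError(f"data has {self.data.ndim} dims but axes is {self.axes!r}")
        if "".join(a for a in "TZCYX" if a in self.axes) != self.axes:
            raise ValueError(f"axes must be an ordered subset of TZCYX, got {self.axes!r}")
        if "C" in self.axes:
            nc = self.data.shape[self.axes.index("C")]
            if nc != len(self.channel_names):
                raise ValueError("channel_names length must match the C axis")

    @property
    def n_z(self) -> int:
        return self.data.shape[self.axes.index("Z")] if "Z" in self.axes else 1

    @property
    def n_t(self) -> int:
        return self.data.shape[self.axes.index("T")] if "T" in self.axes else 1

    def channel(self, name_or_index: str | int = 0, t: int | None = None) -> np.ndarray:
        """One channel as a (z, y, x) volume (optionally one timepoint)."""
        data = self.data
        axes = self.axes
        if "T" in axes:
            if t is None:
                if self.n_t != 1:
                    raise ValueError("stack has a time axis; specify t")
                t = 0
            data = np.take(data, t, axis=axes.index("T"))
            axes = axes.replace("T", "")
        if "C" in axes:
            if isinstance(name_or_index, str):
                try:
                    idx = self.channel_names.index(name_or_index)
                except ValueError:
                    raise KeyError(f"unknown channel {name_or_index!r}; "
                                   f"have {self.channel_names}") from None
            else:
                idx = int(name_or_index)
            data = np.take(data, idx, axis=axes.index("C"))
        elif isinstance(name_or_index, str) and name_or_index not in self.channel_names:
            raise KeyError(f"unknown channel {name_or_index!r}; have {self.channel_names}")
        if "Z" not in axes:
            data = data[np.newaxis, ...]
        return np.asarray(data)

    def save_tiff(self, path) -> None:
        import tifffile

        tifffile.imwrite(
            path,
            self.data.astype(np.uint16),
            metadata={
                "axes": self.axes,
                "pixel_size_um": self.pixel_size_um,
                "z_step_um": self.z_step_um,
                "channel_names": list(self.channel_names),
            },
        )

    @classmethod
    def load_tiff(cls, path) -> "ImageStack":
        import json

        import tifffile

        with tifffile.TiffFile(path) as tf:
            data = tf.asarray()
            meta = tf.shaped_metadata[0] if tf.shaped_metadata else {}
        if isinstance(meta, str):
            meta = json.loads(meta)
        return cls(
            data=data,
            axes=meta.get("axes", "ZYX"[: data.ndim] if data.ndim <= 3 else "ZCYX"),
            pixel_size_um=float(meta.get("pixel_size_um", 1.0)),
            z_step_um=float(meta.get("z_step_um", 1.0)),
            channel_names=tuple(meta.get("channel_names", ("H2B",))),
        )


@dataclass
class BinaryMask:
    """Boolean (z, y, x) grid plus the threshold that produced it."""

    mask: np.ndarray
    threshold: float
    channel: str = "H2B"

    @property
    def pixel_count(self) -> int:
        return int(self.mask.sum())

    def z_support(self) -> tuple[int, int] | None:
        """(zmin, zmax) of slices containing any foreground, or None if empty."""
        has = np.flatnonzero(self.mask.any(axis=(1, 2)))
        if len(has) == 0:
            return None
        return int(has[0]), int(has[-1])


@dataclass
class ParticleSet:
    """Connected foreground components, per slice (2D mode) or per stack (3D)."""

    particles: pd.DataFrame  # particle_id, slice, n_px, centroid_*, bbox_*, label(opt)
    mode: str  # "slice2d" | "volume3d"
    connectivity: int
    labels: np.ndarray | None = field(default=None, repr=False)

    def __len__(self) -> int:
        return len(self.particles)


@dataclass
class ViabilityQuant:
    """Alive/dead pixel totals of one organoid at one timepoint."""

    organoid_id: int | str
    timepoint: int | float
    alive_px: int
    dead_px: int
    z_range: tuple[int, int]

    @property
    def total_px(self) -> int:
        return self.alive_px + self.dead_px

    @property
    def dead_fraction(self) -> float:
        return self.dead_px / self.total_px if self.total_px else float("nan")


@dataclass
class DeathRatio:
    """Pooled PI/H2B pixel-surface ratio — the cell-death readout."""

    pi_px: int
    h2b_px: int
    threshold_h2b: float
    threshold_pi: float

    @property
    def ratio(self) -> float:
        return self.pi_px / self.h2b_px


@dataclass
class ThresholdScan:
    """Diagnostic curves of a ramped threshold scan plus the chosen optimum."""

    thresholds: np.ndarray
    area: np.ndarray
    mean_intensity: np.ndarray
    score: np.ndarray
    optimum: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "threshold": self.thresholds,
                "area_px": self.area,
                "mean_intensity": self.mean_intensity,
                "score": self.score,
            }
        )


# ---------------------------------------------------------------------------


def binarize_channel(
    stack: ImageStack, channel: str | int = "H2B", threshold: float = 0.0,
    t: int | None = None,
) -> BinaryMask:
    """Threshold one channel: a voxel is foreground iff intensity >= threshold."""
    volume = stack.channel(channel, t=t)
    name = channel if isinstance(channel, str) else stack.channel_names[channel]
    return BinaryMask(mask=volume >= threshold, threshold=float(threshold), channel=name)


_VALID_CONN = {"slice2d": {1: 4, 2: 8}, "volume3d": {1: 6, 3: 26}}


def find_particles(
    mask: BinaryMask | np.ndarray,
    mode: str = "slice2d",
    connectivity: int | None = None,
) -> ParticleSet:
    """Label connected components of a binary mask.

    ``mode='slice2d'`` labels every z-slice independently (connectivity 4 or
    8, default 8), mirroring per-slice macro analysis; ``mode='volume3d'``
    labels the full volume (connectivity 6 or 26, default 26).
    """
    arr = mask.mask if isinstance(mask, BinaryMask) else np.asarray(mask, dtype=bool)
    if arr.ndim == 2:
        arr = arr[np.newaxis, ...]
    if mode not in ("slice2d", "volume3d"):
        raise ValueError(f"unknown mode {mode!r}")
    if connectivity is None:
        connectivity = 8 if mode == "slice2d" else 26
    conn_map = {"slice2d": {4: 1, 8: 2}, "volume3d": {6: 1, 26: 3}}[mode]
    if connectivity not in conn_map:
        raise ValueError(f"connectivity {connectivity} invalid for mode {mode!r}")
    skconn = conn_map[connectivity]

    rows = []
    labels = np.zeros(arr.shape, dtype=np.int32)
    pid = 0
    if mode == "slice2d":
        for zi in range(arr.shape[0]):
            lab = measure.label(arr[zi], connectivity=skconn)
            for rp in measure.regionprops(lab):
                pid += 1
                labels[zi][lab == rp.label] = pid
                rows.append(
                    dict(
                        particle_id=pid,
                        slice=zi,
                        n_px=int(rp.area),
                        centroid_y=rp.centroid[0],
                        centroid_x=rp.centroid[1],
                        bbox=rp.bbox,
                    )
                )
    else:
        lab = measure.label(arr, connectivity=skconn)
        for rp in measure.regionprops(lab):
            pid += 1
            labels[lab == rp.label] = pid
            rows.append(
                dict(
                    particle_id=pid,
                    slice=None,
                    n_px=int(rp.area),
                    centroid_z=rp.centroid[0],
                    centroid_y=rp.centroid[1],
                    centroid_x=rp.centroid[2],
                    bbox=rp.bbox,
                )
            )
    cols = ["particle_id", "slice", "n_px"]
    particles = pd.DataFrame(rows) if rows else pd.DataFrame(columns=cols)
    return ParticleSet(particles=particles, mode=mode,
                       connectivity=connectivity, labels=labels)


def classify_particles(particles: ParticleSet, size_cutoff_px: float) -> ParticleSet:
    """Label each particle alive or dead by size: dead iff n_px < cutoff.

    A particle exactly at the cutoff is alive (boundary convention).  Returns
    a new ParticleSet whose table carries a ``label`` column.
    """
    if size_cutoff_px <= 0:
        raise ValueError("size_cutoff_px must be > 0")
    table = particles.particles.copy()
    table["label"] = np.where(table["n_px"] < size_cutoff_px, "dead", "alive")
    return ParticleSet(
        particles=table,
        mode=particles.mode,
        connectivity=particles.connectivity,
        labels=particles.labels,
    )


def estimate_size_cutoff(particles: ParticleSet) -> float:
    """Default dead/alive cutoff: half the median particle area.

    Intended to be calibrated on a vehicle (healthy) condition, where nearly
    all particles are intact nuclei; apoptotic fragments are far smaller than
    half a nucleus cross-section.
    """
    if len(particles) == 0:
        raise ValueError("cannot estimate a cutoff from an empty particle set")
    return float(np.median(particles.particles["n_px"])) / 2.0


def masks_from_labels(classified: ParticleSet, shape: tuple[int, ...]) -> tuple[np.ndarray, np.ndarray]:
    """Alive and dead boolean masks rebuilt from a classified ParticleSet."""
    if classified.labels is None or "label" not in classified.particles:
        raise ValueError("need a classified ParticleSet with labels array")
    table = classified.particles
    alive_ids = set(table.loc[table["label"] == "alive", "particle_id"])
    alive = np.isin(classified.labels, list(alive_ids)) & (classified.labels > 0)
    dead = (classified.labels > 0) & ~alive
    return alive.reshape(shape), dead.reshape(shape)


def quantify_lower_half(
    mask_alive: np.ndarray,
    mask_dead: np.ndarray,
    z_extent: tuple[int, int],
    organoid_id: int | str = 0,
    timepoint: int | float = 0,
) -> ViabilityQuant:
    """Integrate alive/dead pixel areas over the lower half of an organoid.

    ``z_extent`` is the inclusive (zmin, zmax) slice range the organoid spans;
    the analyzed window is the bottom floor(n/2) slices of that range (at
    least one).  Restricting to the lower half avoids the depth-degraded
    upper half of the volume.
    """
    mask_alive = np.asarray(mask_alive, dtype=bool)
    mask_dead = np.asarray(mask_dead, dtype=bool)
    if mask_alive.shape != mask_dead.shape:
        raise ValueError("alive and dead masks must be congruent")
    if (mask_alive & mask_dead).any():
        raise ValueError("alive and dead masks overlap")
    zmin, zmax = z_extent
    nz = mask_alive.shape[0]
    if not (0 <= zmin <= zmax < nz):
        raise ValueError(f"z_extent {z_extent} outside stack of {nz} slices")
    n_slices = zmax - zmin + 1
    n_lower = max(n_slices // 2, 1)
    sl = slice(zmin, zmin + n_lower)
    return ViabilityQuant(
        organoid_id=organoid_id,
        timepoint=timepoint,
        alive_px=int(mask_alive[sl].sum()),
        dead_px=int(mask_dead[sl].sum()),
        z_range=(zmin, zmin + n_lower - 1),
    )


def depth_coded_projection(
    stack: ImageStack | np.ndarray,
    channel: str | int = "H2B",
    lut: str = "turbo",
    transmitted: np.ndarray | None = None,
    t: int | None = None,
) -> np.ndarray:
    """Maximum-intensity z-projection with hue encoding the depth of the max.

    Per xy pixel: intensity = max over z; hue = colormap(z of the argmax),
    ties resolved to the lowest z.  Returns an (y, x, 3) float RGB frame in
    [0, 1].  If a transmitted-light image is supplied, a four-quadrant
    layout is returned instead: depth-coded, transmitted, merge, and the
    grey projection.
    """
    volume = stack.channel(channel, t=t) if isinstance(stack, ImageStack) else np.asarray(stack)
    if volume.ndim == 2:
        volume = volume[np.newaxis, ...]
    nz = volume.shape[0]
    proj = volume.max(axis=0)
    arg = volume.argmax(axis=0)  # numpy argmax returns the first (lowest z) maximum
    cmap = matplotlib.colormaps[lut] if isinstance(lut, str) else lut
    hue = cmap(arg / max(nz - 1, 1))[..., :3]
    lo, hi = float(proj.min()), float(proj.max())
    norm = (proj - lo) / (hi - lo) if hi > lo else np.zeros_like(proj, dtype=float)
    rgb = hue * norm[..., np.newaxis]
    if transmitted is None:
        return rgb
    tl = np.asarray(transmitted, dtype=float)
    tlo, thi = tl.min(), tl.max()
    tl = (tl - tlo) / (thi - tlo) if thi > tlo else np.zeros_like(tl)
    tl_rgb = np.repeat(tl[..., np.newaxis], 3, axis=2)
    grey = np.repeat(norm[..., np.newaxis], 3, axis=2)
    merge = np.clip(0.5 * rgb + 0.5 * tl_rgb, 0, 1)
    top = np.concatenate([rgb, tl_rgb], axis=1)
    bottom = np.concatenate([merge, grey], axis=1)
    return np.concatenate([top, bottom], axis=0)


def ramp_threshold_optimum(
    image: np.ndarray, t_grid: np.ndarray | None = None, n_steps: int = 64
) -> ThresholdScan:
    """Automatic threshold by a ramped scan of surface area vs mean signal.

    For each candidate T: area(T) = number of pixels >= T and mean(T) = mean
    intensity of those pixels.  Both curves are min-max normalized over the
    grid and the optimum maximizes score(T) = norm_mean(T) - norm_area(T) —
    the threshold combining the highest mean signal with the most confined
    surface area.  Ties resolve to the lowest T; thresholds selecting an
    empty surface are never eligible (their score is set to -inf).

    Raises ValueError on a constant image (the scan is degenerate).
    """
    img = np.asarray(image, dtype=float)
    lo, hi = float(img.min()), float(img.max())
    if hi <= lo:
        raise ValueError("constant image: ramped threshold scan is degenerate")
    if t_grid is None:
        t_grid = np.linspace(lo, hi, n_steps)
    t_grid = np.asarray(t_grid, dtype=float)
    if len(np.unique(t_grid)) < 3:
        raise ValueError("t_grid needs at least 3 distinct thresholds")

    flat = img.ravel()
    area = np.array([(flat >= T).sum() for T in t_grid], dtype=float)
    mean = np.array(
        [flat[flat >= T].mean() if (flat >= T).any() else np.nan for T in t_grid]
    )
    # thresholds above the data max select nothing; carry the last valid mean
    if np.isnan(mean).any():
        last = np.flatnonzero(~np.isnan(mean))[-1]
        mean[np.isnan(mean)] = mean[last]

    def _norm(v: np.ndarray) -> np.ndarray:
        vmin, vmax = v.min(), v.max()
        if vmax <= vmin:
            return np.zeros_like(v)
        return (v - vmin) / (vmax - vmin)

    score = _norm(mean) - _norm(area)
    score[area == 0] = -np.inf  # an empty surface is not a usable threshold
    best = int(np.argmax(score))  # argmax takes the first (lowest T) on ties
    return ThresholdScan(
        thresholds=t_grid, area=area, mean_intensity=mean,
        score=score, optimum=float(t_grid[best]),
    )


def pi_h2b_death_ratio(
    stack: ImageStack,
    t_h2b: float | str = "auto",
    t_pi: float | str = "auto",
    h2b_channel: str = "H2B",
    pi_channel: str = "PI",
) -> DeathRatio:
    """Cell-death ratio: PI-positive surface over H2B-positive surface.

    Pixel counts are pooled over the whole stack (all organoids in the field)
    before the division; "auto" thresholds run the ramped-threshold optimum
    per channel.  The PI mask is deliberately not intersected with the H2B
    mask.  Raises if the H2B surface is empty (undefined ratio).
    """
    h2b = stack.channel(h2b_channel)
    pi = stack.channel(pi_channel)
    thr_h = ramp_threshold_optimum(h2b).optimum if t_h2b == "auto" else float(t_h2b)
    thr_p = ramp_threshold_optimum(pi).optimum if t_pi == "auto" else float(t_pi)
    h2b_px = int((h2b >= thr_h).sum())
    pi_px = int((pi >= thr_p).sum())
    if h2b_px == 0:
        raise ValueError("no H2B-positive pixels: death ratio undefined")
    return DeathRatio(pi_px=pi_px, h2b_px=h2b_px, threshold_h2b=thr_h, threshold_pi=thr_p)
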