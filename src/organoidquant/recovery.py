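"""Recovery and ancillary quantifications.

Three independent readouts used around the core drug screens:

* alamarBlue (resazurin) kinetic viability: the assay's linear range is
  detected from the fluorescence time course, and viability is the maximal
  background-corrected RFU within that range, normalized to vehicle;
* xenograft tumor volume series from caliper pairs via V = D*d^2/2 (D the
  major, d the minor axis) with percent change relative to baseline;
* EdU x DNA-content cell-cycle classification into G1/S/G2 with a
  chi-square comparison of phase distributions against a reference sample.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "LinearRange",
    "CellCycleResult",
    "detect_linear_range",
    "ab_viability",
    "tumor_series",
    "cellcycle_gates_from_reference",
    "cellcycle_classify",
]


@dataclass
class LinearRange:
    """Contiguous read window of an RFU time course judged linear."""

    start_index: int
    end_index: int  # inclusive
    slope_rfu_per_h: float
    r_squared: float


def _r_squared(t: np.ndarray, y: np.ndarray) -> float:
    sst = float(np.sum((y - y.mean()) ** 2))
    if sst == 0:
        return 1.0  # perfectly flat: a line fits exactly
    res = stats.linregress(t, y)
    sse = float(np.sum((res.intercept + res.slope * t - y) ** 2))
    return 1.0 - sse / sst


def detect_linear_range(
    series: pd.DataFrame, r2_min: float = 0.99, min_reads: int = 3
) -> LinearRange:
    """Longest read window starting at t = 0 whose OLS fit has R² >= r2_min.

    The window is grown from the first ``min_reads`` reads until adding the
    next read breaks linearity; this anchors the range at the background
    read and stops it at the onset of assay saturation.  If even the
    smallest window fails (noisy flat series), that smallest window is
    returned as a fallback.
    """
    t = series["time_h"].to_numpy(dtype=float)
    y = series["rfu"].to_numpy(dtype=float)
    if len(t) < min_reads:
        raise ValueError(f"need at least {min_reads} reads")
    end = min_reads - 1
    best = end if _r_squared(t[: end + 1], y[: end + 1]) >= r2_min else None
    while end + 1 < len(t):
        if _r_squared(t[: end + 2], y[: end + 2]) >= r2_min:
            end += 1
            best = end
        else:
            break
    if best is None:
        best = min_reads - 1
    res = stats.linregress(t[: best + 1], y[: best + 1])
    return LinearRange(
        start_index=0,
        end_index=best,
        slope_rfu_per_h=float(res.slope),
        r_squared=_r_squared(t[: best + 1], y[: best + 1]),
    )


def _rfu_max_corrected(series: pd.DataFrame, r2_min: float) -> float:
    rng = detect_linear_range(series, r2_min=r2_min)
    y = series["rfu"].to_numpy(dtype=float)
    return float(y[rng.end_index] - y[0])


def ab_viability(
    series: pd.DataFrame, vehicle_series: pd.DataFrame, r2_min: float = 0.99
) -> float:
    """Normalized viability (%) from alamarBlue kinetics.

    Per well: viability signal = RFUmax within the detected linear range
    minus the background read RFU(0); result = 100 * treated / vehicle.
    """
    for s in (series, vehicle_series):
        tt = s["time_h"].to_numpy(dtype=float)
        if len(tt) < 4:
            raise ValueError("need at least 4 reads per series")
        if tt[0] != 0 or np.any(np.diff(tt) <= 0):
            raise ValueError("read times must start at 0 and be strictly increasing")
    treated_signal = _rfu_max_corrected(series, r2_min)
    vehicle_signal = _rfu_max_corrected(vehicle_series, r2_min)
    if vehicle_signal <= 0:
        raise ValueError("vehicle series shows no signal increase: cannot normalize")
    return 100.0 * treated_signal / vehicle_signal


# ---------------------------------------------------------------------------


def tumor_series(measurements: pd.DataFrame) -> pd.DataFrame:
    """Caliper pairs -> ellipsoid-approximation volumes and percent change.

    ``measurements`` columns: animal, day, d1_mm, d2_mm (and optionally
    group).  Volume = D*d²/2 with D the larger and d the smaller caliper
    axis (the pair is canonicalized by swapping, so entry order does not
    matter).  Percent change at day t is 100*(V(t) - V(0))/V(0) against each
    animal's day-0 baseline; per-day group mean and standard deviation are
    attached.
    """
    df = measurements.copy()
    d_major = np.maximum(df["d1_mm"], df["d2_mm"])
    d_minor = np.minimum(df["d1_mm"], df["d2_mm"])
    if (d_minor <= 0).any():
        raise ValueError("caliper measurements must be positive")
    df["d_major_mm"] = d_major
    df["d_minor_mm"] = d_minor
    df["volume_mm3"] = d_major * d_minor**2 / 2.0

    out = []
    for animal, sub in df.groupby("animal", sort=False):
        sub = sub.sort_values("day")
        if 0 not in set(sub["day"]):
            raise ValueError(f"animal {animal!r} lacks a day-0 baseline measurement")
        v0 = float(sub.loc[sub["day"] == 0, "volume_mm3"].iloc[0])
        sub = sub.assign(
            baseline_mm3=v0,
            pct_change=100.0 * (sub["volume_mm3"] - v0) / v0,
        )
        out.append(sub)
    result = pd.concat(out, ignore_index=True)
    keys = ["group", "day"] if "group" in result.columns else ["day"]
    summary = result.groupby(keys)["pct_change"].agg(["mean", "std"]).reset_index()
    result.attrs["group_summary"] = summary
    return result


# ---------------------------------------------------------------------------


@dataclass
class CellCycleResult:
    """Phase fractions from EdU x DNA gating plus an optional chi-square test."""

    counts: dict  # phase -> cell count (G1, S, G2, unassigned)
    fractions: dict
    gates: dict
    chi2: float | None = None
    p_value: float | None = None

    def summary(self) -> pd.DataFrame:
        rows = [
            dict(phase=k, count=self.counts[k], fraction=self.fractions[k])
            for k in ("G1", "S", "G2", "unassigned")
        ]
        return pd.DataFrame(rows)


def cellcycle_gates_from_reference(reference: pd.DataFrame) -> dict:
    """Derive gates from an untreated reference sample.

    The EdU threshold is the Otsu split of log EdU signal (dim vs bright
    populations).  The 2N DNA peak is the mode of the DNA histogram of
    EdU-dim cells; the G1 gate closes at 1.4x that peak and the G2 gate
    opens at 1.7x (4N sits at 2x).
    """
    from skimage.filters import threshold_otsu

    edu = reference["edu"].to_numpy(dtype=float)
    edu_threshold = float(np.exp(threshold_otsu(np.log(edu + 1e-9))))
    dim = reference.loc[reference["edu"] < edu_threshold, "dna"].to_numpy(dtype=float)
    if len(dim) < 10:
        dim = reference["dna"].to_numpy(dtype=float)
    hist, edges = np.histogram(dim, bins=100)
    peak_2n = float((edges[np.argmax(hist)] + edges[np.argmax(hist) + 1]) / 2)
    return dict(
        edu_threshold=edu_threshold,
        dna_2n_upper=1.4 * peak_2n,
        dna_4n_lower=1.7 * peak_2n,
    )


def cellcycle_classify(
    sample: pd.DataFrame,
    gates: dict | None = None,
    reference: pd.DataFrame | None = None,
) -> CellCycleResult:
    """Assign cells to G1/S/G2 from EdU incorporation and DNA content.

    Gate precedence: EdU >= threshold -> S regardless of DNA content; else
    DNA <= 2N gate -> G1; DNA >= 4N gate -> G2; cells between the DNA gates
    stay unassigned (reported, never forced).  If a reference sample is
    given, a chi-square test (no continuity correction) compares the two
    2x3 phase-count tables.
    """
    if len(sample) == 0:
        raise ValueError("empty sample")
    if gates is None:
        gates = cellcycle_gates_from_reference(
            reference if reference is not None else sample
        )
    if not gates["dna_2n_upper"] < gates["dna_4n_lower"]:
        raise ValueError("gates must satisfy 2N upper < 4N lower")

    def phases_of(df: pd.DataFrame) -> pd.Series:
        dna = df["dna"].to_numpy(dtype=float)
        edu = df["edu"].to_numpy(dtype=float)
        out = np.full(len(df), "unassigned", dtype=object)
        s = edu >= gates["edu_threshold"]
        out[s] = "S"
        out[~s & (dna <= gates["dna_2n_upper"])] = "G1"
        out[~s & (dna >= gates["dna_4n_lower"])] = "G2"
        return pd.Series(out)

    phases = phases_of(sample)
    counts = {k: int((phases == k).sum()) for k in ("G1", "S", "G2", "unassigned")}
    if counts["unassigned"] == len(sample):
        raise ValueError("all cells unassigned: check gates")
    n = len(sample)
    fractions = {k: c / n for k, c in counts.items()}

    chi2 = p = None
    if reference is not None:
        ref_phases = phases_of(reference)
        table = np.array(
            [
                [(phases == k).sum() for k in ("G1", "S", "G2")],
                [(ref_phases == k).sum() for k in ("G1", "S", "G2")],
            ]
        )
        chi2, p, _, _ = stats.chi2_contingency(table, correction=False)
        chi2, p = float(chi2), float(p)
    return CellCycleResult(counts=counts, fractions=fractions, gates=dict(gates),
                           chi2=chi2, p_value=p)
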