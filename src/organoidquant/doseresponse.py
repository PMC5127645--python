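"""Dose-response and drug-combination analytics for organoid viability screens.

Raw ATP-type plate signals are normalized to vehicle (100%) and to the
multi-drug plateau (0%), assembled into a dose matrix, and analysed with:

* the normalized four-parameter logistic ("log(inhibitor) vs. normalized
  response, variable slope"): y(x) = 100 / (1 + 10**((x - log10 IC50) * h)),
  x = log10 molar concentration, asymptotes fixed at 100 and 0, Hill slope
  h > 0 for a descending curve;
* ΔIC50 between two lines on the log10 scale (positive = more resistant);
* Bliss-independence excess: observed fractional inhibition minus
  fA + fB - fA*fB computed from the monotherapy rows;
* moving-average smoothing of heat-map matrices;
* monotherapy and fixed-ratio diagonal curve extraction from full matrices.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

__all__ = [
    "DoseMatrix",
    "DoseResponseFit",
    "BlissMatrix",
    "normalize_viability",
    "fit_dose_response",
    "delta_ic50",
    "bliss_excess",
    "smooth_matrix",
    "extract_curve",
    "fit_curve_from_matrix",
    "PRESET_GRIDS",
    "four_pl",
]

# Concentration presets (nM): the 14-point grid spans 5 nM-5 uM; the 22-point
# grid spans 5 nM-20 uM, both log-spaced.
PRESET_GRIDS: dict[str, np.ndarray] = {
    "matrix14": np.logspace(np.log10(5.0), np.log10(5000.0), 14),
    "range22": np.logspace(np.log10(5.0), np.log10(20000.0), 22),
    "matrix9": np.logspace(np.log10(5.0), np.log10(20000.0), 9),
}


def four_pl(x: np.ndarray, log10_ic50: float, hill_slope: float) -> np.ndarray:
    """Normalized variable-slope logistic in percent; x = log10 molar conc."""
    return 100.0 / (1.0 + 10 ** ((np.asarray(x, dtype=float) - log10_ic50) * hill_slope))


@dataclass
class DoseMatrix:
    """Normalized viability (%) on a (conc_a x conc_b) grid.

    Axes are stored in nM, strictly increasing, and include the
    zero-concentration monotherapy row/column when present in the reads.
    ``provenance`` records the normalization constants used.
    """

    values: np.ndarray  # shape (len(conc_a), len(conc_b))
    conc_a_nM: np.ndarray
    conc_b_nM: np.ndarray
    drug_a: str = "drug_a"
    drug_b: str = "drug_b"
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.conc_a_nM = np.asarray(self.conc_a_nM, dtype=float)
        self.conc_b_nM = np.asarray(self.conc_b_nM, dtype=float)
        if self.values.shape != (len(self.conc_a_nM), len(self.conc_b_nM)):
            raise ValueError("values shape must match concentration axes")
        for ax in (self.conc_a_nM, self.conc_b_nM):
            if np.any(np.diff(ax) <= 0):
                raise ValueError("concentration axes must be strictly increasing")

    def has_monotherapy_axes(self) -> bool:
        return self.conc_a_nM[0] == 0.0 and self.conc_b_nM[0] == 0.0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.conc_a_nM, columns=self.conc_b_nM)


@dataclass
class BlissMatrix:
    """Bliss excess (observed - expected independent inhibition) per grid cell."""

    scores: np.ndarray
    conc_a_nM: np.ndarray
    conc_b_nM: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.scores, index=self.conc_a_nM, columns=self.conc_b_nM)


@dataclass
class DoseResponseFit:
    """Fitted normalized 4PL: log10 IC50 (molar) and Hill slope.

    Results-style container: parameters, standard errors, residual sum of
    squares, and a ``summary()`` table.
    """

    log10_ic50: float
    hill_slope: float
    se_log10_ic50: float
    se_hill_slope: float
    rss: float
    n_points: int
    converged: bool

    @property
    def ic50_molar(self) -> float:
        return 10 ** self.log10_ic50

    @property
    def ic50_nM(self) -> float:
        return self.ic50_molar * 1e9

    def predict(self, conc_molar: np.ndarray) -> np.ndarray:
        return four_pl(np.log10(np.asarray(conc_molar, dtype=float)),
                       self.log10_ic50, self.hill_slope)

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "estimate": [self.log10_ic50, self.hill_slope, self.ic50_nM],
                "stderr": [self.se_log10_ic50, self.se_hill_slope, np.nan],
            },
            index=["log10_ic50_M", "hill_slope", "ic50_nM"],
        )


# ---------------------------------------------------------------------------


def normalize_viability(
    reads: pd.DataFrame,
    baseline_rule: str | float = "top_k",
    k_baseline: int = 3,
) -> DoseMatrix:
    """Normalize raw plate signals to vehicle = 100% and plateau = 0%.

    ``reads`` is the tidy plate table (conc_a_nM, conc_b_nM, signal, role).
    V is the mean of vehicle wells.  The baseline plateau B follows
    ``baseline_rule``: ``"top_k"`` averages the k wells with the highest
    total concentration (the multi-drug plateau), or pass a number to supply
    a separately determined plateau signal.  Replicate wells at identical
    (conc_a, conc_b) are averaged after normalization.  Values are not
    clipped.
    """
    vehicle = reads[reads["role"] == "vehicle"]
    if len(vehicle) == 0:
        raise ValueError("no vehicle wells: cannot normalize")
    V = float(vehicle["signal"].mean())
    treated = reads[reads["role"] == "treated"].copy()
    if isinstance(baseline_rule, str):
        if baseline_rule != "top_k":
            raise ValueError(f"unknown baseline_rule {baseline_rule!r}")
        total = treated["conc_a_nM"] + treated["conc_b_nM"]
        top = treated.loc[total.sort_values(ascending=False).index[:k_baseline]]
        B = float(top["signal"].mean())
    else:
        B = float(baseline_rule)
    if V <= B:
        raise ValueError(f"vehicle mean {V} not above baseline {B}: assay failed")

    treated["viability_pct"] = 100.0 * (treated["signal"] - B) / (V - B)
    grid = (
        treated.groupby(["conc_a_nM", "conc_b_nM"])["viability_pct"].mean().reset_index()
    )
    conc_a = np.array(sorted(grid["conc_a_nM"].unique()))
    conc_b = np.array(sorted(grid["conc_b_nM"].unique()))
    values = np.full((len(conc_a), len(conc_b)), np.nan)
    ia = {c: i for i, c in enumerate(conc_a)}
    ib = {c: i for i, c in enumerate(conc_b)}
    for _, row in grid.iterrows():
        values[ia[row["conc_a_nM"]], ib[row["conc_b_nM"]]] = row["viability_pct"]
    # vehicle wells define the (0, 0) monotherapy corner at exactly 100%
    if 0.0 in ia and 0.0 in ib and np.isnan(values[ia[0.0], ib[0.0]]):
        values[ia[0.0], ib[0.0]] = 100.0
    return DoseMatrix(
        values=values,
        conc_a_nM=conc_a,
        conc_b_nM=conc_b,
        provenance=dict(vehicle_mean=V, baseline=B, rule=str(baseline_rule),
                        k_baseline=k_baseline),
    )


def fit_dose_response(
    conc_molar: np.ndarray, response_pct: np.ndarray
) -> DoseResponseFit:
    """Least-squares fit of the normalized 4PL to (concentration, response %).

    Requires >= 4 distinct non-zero concentrations.  Multi-start
    initialization over candidate midpoints and slopes guards against local
    minima; the converged flag reports whether any start succeeded.
    """
    conc = np.asarray(conc_molar, dtype=float)
    y = np.asarray(response_pct, dtype=float)
    keep = conc > 0
    conc, y = conc[keep], y[keep]
    if len(np.unique(conc)) < 4:
        raise ValueError("need at least 4 distinct concentrations to fit")
    if np.allclose(y, y[0]):
        raise ValueError("all responses identical: dose-response fit undefined")
    x = np.log10(conc)

    best = None
    starts = [
        (x0, s0)
        for x0 in np.linspace(x.min(), x.max(), 5)
        for s0 in (0.5, 1.0, 2.0)
    ]
    for x0, s0 in starts:
        try:
            popt, pcov = curve_fit(
                four_pl, x, y, p0=[x0, s0],
                bounds=([x.min() - 6, 1e-3], [x.max() + 6, 20.0]),
                maxfev=20000,
            )
        except (RuntimeError, ValueError):
            continue
        rss = float(np.sum((four_pl(x, *popt) - y) ** 2))
        if best is None or rss < best[2]:
            best = (popt, pcov, rss)
    if best is None:
        return DoseResponseFit(np.nan, np.nan, np.nan, np.nan, np.nan,
                               n_points=len(y), converged=False)
    popt, pcov, rss = best
    se = np.sqrt(np.diag(pcov)) if np.all(np.isfinite(pcov)) else [np.nan, np.nan]
    return DoseResponseFit(
        log10_ic50=float(popt[0]),
        hill_slope=float(popt[1]),
        se_log10_ic50=float(se[0]),
        se_hill_slope=float(se[1]),
        rss=rss,
        n_points=len(y),
        converged=True,
    )


def delta_ic50(fit_mut: DoseResponseFit, fit_wt: DoseResponseFit) -> float:
    """Δlog10 IC50 between two lines; positive = the first is more resistant."""
    if not (fit_mut.converged and fit_wt.converged):
        raise ValueError("both fits must have converged")
    return fit_mut.log10_ic50 - fit_wt.log10_ic50


def bliss_excess(matrix: DoseMatrix) -> BlissMatrix:
    """Bliss-independence excess of a normalized combination matrix.

    For each cell: fA and fB are the monotherapy fractional inhibitions
    (1 - v/100 along the zero-concentration row/column, clamped to [0, 1]),
    expected = fA + fB - fA*fB, observed = the cell's fractional inhibition
    (clamped); score = observed - expected.  Monotherapy cells score 0 by
    construction.
    """
    if not matrix.has_monotherapy_axes():
        raise ValueError("matrix must contain the zero-concentration row and column")
    v = matrix.values
    fA = np.clip(1.0 - v[:, 0] / 100.0, 0.0, 1.0)  # drug A alone (b = 0)
    fB = np.clip(1.0 - v[0, :] / 100.0, 0.0, 1.0)  # drug B alone (a = 0)
    expected = fA[:, None] + fB[None, :] - fA[:, None] * fB[None, :]
    observed = np.clip(1.0 - v / 100.0, 0.0, 1.0)
    scores = observed - expected
    scores[0, :] = 0.0
    scores[:, 0] = 0.0
    return BlissMatrix(scores=scores, conc_a_nM=matrix.conc_a_nM,
                       conc_b_nM=matrix.conc_b_nM)


def smooth_matrix(matrix, window: int = 3):
    """Moving-average smoothing of a heat-map matrix.

    Each cell becomes the mean of its window x window neighbourhood; the
    window shrinks at the matrix edges.  window must be odd; window = 1 is
    the identity.  Accepts and returns DoseMatrix or BlissMatrix.
    """
    if window < 1 or window % 2 == 0:
        raise ValueError("window must be an odd integer >= 1")
    values = matrix.values if isinstance(matrix, DoseMatrix) else matrix.scores
    h = window // 2
    out = np.empty_like(values, dtype=float)
    n, m = values.shape
    for i in range(n):
        for j in range(m):
            block = values[max(i - h, 0): i + h + 1, max(j - h, 0): j + h + 1]
            out[i, j] = block.mean()
    if isinstance(matrix, DoseMatrix):
        return DoseMatrix(out, matrix.conc_a_nM, matrix.conc_b_nM,
                          matrix.drug_a, matrix.drug_b,
                          {**matrix.provenance, "smoothed_window": window})
    return BlissMatrix(out, matrix.conc_a_nM, matrix.conc_b_nM)


def extract_curve(
    matrix: DoseMatrix,
    mode: str,
    ratio_offset_logdecades: float = 0.0,
    log_tol: float = 1e-6,
) -> pd.DataFrame:
    """Extract a dose-response curve from a full combination matrix.

    ``mode='row_a_mono'`` returns drug A alone (the conc_b = 0 column);
    ``'col_b_mono'`` drug B alone; ``'fixed_ratio_diagonal'`` the cells where
    log10(conc_b) = log10(conc_a) + offset (offset 0 = equimolar).  Diagonal
    curves are reported on the drug-A (reference) concentration axis, the
    offset recorded in the output.  Returns columns conc_nM, viability_pct.
    """
    if mode == "row_a_mono":
        if matrix.conc_b_nM[0] != 0.0:
            raise ValueError("matrix lacks the conc_b = 0 monotherapy column")
        sel = matrix.conc_a_nM > 0
        return pd.DataFrame(
            {"conc_nM": matrix.conc_a_nM[sel], "viability_pct": matrix.values[sel, 0]}
        )
    if mode == "col_b_mono":
        if matrix.conc_a_nM[0] != 0.0:
            raise ValueError("matrix lacks the conc_a = 0 monotherapy row")
        sel = matrix.conc_b_nM > 0
        return pd.DataFrame(
            {"conc_nM": matrix.conc_b_nM[sel], "viability_pct": matrix.values[0, sel]}
        )
    if mode != "fixed_ratio_diagonal":
        raise ValueError(f"unknown mode {mode!r}")

    ca = matrix.conc_a_nM[matrix.conc_a_nM > 0]
    cb = matrix.conc_b_nM[matrix.conc_b_nM > 0]
    rows = []
    for a in ca:
        target = np.log10(a) + ratio_offset_logdecades
        j = np.argmin(np.abs(np.log10(cb) - target))
        if abs(np.log10(cb[j]) - target) <= log_tol:
            ia = int(np.where(matrix.conc_a_nM == a)[0][0])
            ib = int(np.where(matrix.conc_b_nM == cb[j])[0][0])
            rows.append(dict(conc_nM=a, conc_b_nM=cb[j],
                             viability_pct=matrix.values[ia, ib]))
    if not rows:
        raise ValueError(
            f"offset {ratio_offset_logdecades} log decades is not representable "
            "on this concentration grid"
        )
    out = pd.DataFrame(rows)
    out.attrs["ratio_offset_logdecades"] = ratio_offset_logdecades
    return out


def fit_curve_from_matrix(
    matrix: DoseMatrix, mode: str, ratio_offset_logdecades: float = 0.0
) -> DoseResponseFit:
    """Extract a curve from a matrix and fit the normalized 4PL to it.

    For diagonal (combination) curves the IC50 is reported on the reference
    drug-A axis; both drugs are present at the stated offset.
    """
    curve = extract_curve(matrix, mode, ratio_offset_logdecades)
    return fit_dose_response(curve["conc_nM"].to_numpy() * 1e-9,
                             curve["viability_pct"].to_numpy())


def plot_heatmap(matrix, path=None, ax=None, title: str = ""):
    """Viability heat map with the red (0%) to green (100%) convention;
    Bliss maps use a diverging blue-white-red scale centred at 0."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    if ax is None:
        fig, ax = plt.subplots(figsize=(5, 4))
    else:
        fig = ax.figure
    if isinstance(matrix, DoseMatrix):
        im = ax.imshow(matrix.values, origin="lower", cmap="RdYlGn",
                       vmin=0, vmax=100, aspect="auto")
        label = "viability (%)"
    else:
        lim = max(np.abs(matrix.scores).max(), 0.1)
        im = ax.imshow(matrix.scores, origin="lower", cmap="bwr",
                       vmin=-lim, vmax=lim, aspect="auto")
        label = "Bliss excess"
    ax.set_xlabel("drug B (nM)")
    ax.set_ylabel("drug A (nM)")
    ax.set_xticks(range(len(matrix.conc_b_nM)))
    ax.set_xticklabels([f"{c:g}" for c in matrix.conc_b_nM], rotation=90, fontsize=6)
    ax.set_yticks(range(len(matrix.conc_a_nM)))
    ax.set_yticklabels([f"{c:g}" for c in matrix.conc_a_nM], fontsize=6)
    ax.set_title(title)
    fig.colorbar(im, ax=ax, label=label)
    if path is not None:
        fig.tight_layout()
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return ax
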