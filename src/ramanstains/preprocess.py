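"""Preprocessing chain for Raman spectra.

Three steps, in fixed order: fluorescence-background subtraction (quantile
anchors + shape-preserving piecewise-cubic interpolation), Savitzky–Golay
denoising, and normalization by the area under the curve. An optional
isolation-forest outlier screen and the r-criterion filter-parameter tuner
complete the module.

The background estimate works on non-overlapping windows of the configured
width: within each window the intensity sample closest to the requested
quantile (default 10%) becomes an anchor node, and a monotonicity-preserving
cubic (PCHIP) through the anchors is evaluated on the full axis and
subtracted. Anchoring on actual spectrum samples means a pure linear ramp is
reproduced exactly and removed.

The Savitzky–Golay tuner scores each (window, order) pair by the mean
relative deviation between each filtered spectrum and the set average

    r = (1/2N) Σ_j (1/K_j) Σ_k |S_SG,j(k) − S̄(k)| / |S_SG,j(k) + S̄(k)|,

where S̄ is the pointwise mean of the raw set (the replicate average is the
best available proxy for the noiseless spectrum) and K_j counts the points
where the denominator is non-negligible. Lower r means the filtered spectrum
tracks the replicate average more closely; the grid argmin gives the tuned
window and polynomial order.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import PchipInterpolator
from scipy.signal import savgol_filter
from sklearn.decomposition import PCA
from sklearn.ensemble import IsolationForest

from .errors import (
    DegenerateSpectrumError,
    InsufficientReplicatesError,
    ParameterError,
    TooShortError,
)
from .spectra import Spectrum, SpectrumSet, cm1_to_points

#: Relative denominator guard for the tuning functional.
_TUNE_EPS = 1e-9


@dataclass(frozen=True)
class PreprocessConfig:
    """Parameters of the three-step preprocessing chain.

    Defaults follow common practice for fingerprint-region Raman spectra:
    a 182.2 cm⁻¹ baseline window at the 10% quantile, a 41 cm⁻¹
    Savitzky–Golay window with a first-order polynomial, and area
    normalization. Outlier removal is opt-in (``remove_outliers=True``).
    """

    baseline_window: float = 182.2   # cm⁻¹
    baseline_quantile: float = 0.10
    sg_window: float = 41.0          # cm⁻¹
    sg_order: int = 1
    normalize: str = "area"          # {"area", "none"}
    outlier_fraction: float = 0.05
    remove_outliers: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.baseline_quantile < 0.5):
            raise ParameterError("baseline_quantile must be in (0, 0.5)")
        if self.sg_order < 1:
            raise ParameterError("sg_order must be >= 1")
        if self.normalize not in ("area", "none"):
            raise ParameterError("normalize must be 'area' or 'none'")
        if not (0.0 <= self.outlier_fraction < 0.5):
            raise ParameterError("outlier_fraction must be in [0, 0.5)")


@dataclass
class SGTuningResult:
    """Grid of r values from :func:`tune_sg` plus the argmin cell."""

    windows: list        # cm⁻¹, grid axis 1
    orders: list         # grid axis 2
    r_grid: np.ndarray   # shape (len(windows), len(orders)); NaN = invalid combo
    best_window: float
    best_order: int
    best_r: float


# ---------------------------------------------------------------------------
# baseline
# ---------------------------------------------------------------------------

def _baseline_anchors(axis: np.ndarray, y: np.ndarray, w: int,
                      quantile: float) -> tuple[np.ndarray, np.ndarray]:
    n = axis.size
    starts = list(range(0, n, w))
    ax_pts: list[float] = []
    y_pts: list[float] = []
    for s0 in starts:
        block = slice(s0, min(s0 + w, n))
        size = block.stop - block.start
        if size < max(w // 2, 2) and len(starts) > 1 and s0 > 0:
            continue  # short trailing window: points covered by extrapolation
        yb = y[block]
        q = np.quantile(yb, quantile)
        idx = block.start + int(np.argmin(np.abs(yb - q)))
        ax_pts.append(axis[idx])
        y_pts.append(y[idx])
    return np.asarray(ax_pts), np.asarray(y_pts)


def subtract_baseline(s: Spectrum, window: float = 182.2,
                      quantile: float = 0.10) -> Spectrum:
    """Subtract a smooth quantile baseline (fluorescence stand-in).

    Parameters
    ----------
    s : Spectrum
    window : float
        Anchor-window width in cm⁻¹ (non-overlapping consecutive windows).
    quantile : float
        Intensity quantile within each window defining the anchor, in
        (0, 0.5).

    Returns
    -------
    Spectrum
        Input minus the PCHIP curve through the anchors. Residuals may dip
        below zero.
    """
    if not (0.0 < quantile < 0.5):
        raise ParameterError("quantile must be in (0, 0.5)")
    w = cm1_to_points(window, s.axis)
    ax_pts, y_pts = _baseline_anchors(s.axis, s.intensity, w, quantile)
    if ax_pts.size < 2:
        raise TooShortError(
            f"spectrum {s.label!r} yields {ax_pts.size} baseline anchor window(s); need >= 2"
        )
    curve = PchipInterpolator(ax_pts, y_pts, extrapolate=True)(s.axis)
    return s.with_intensity(s.intensity - curve)


# ---------------------------------------------------------------------------
# Savitzky–Golay smoothing and tuning
# ---------------------------------------------------------------------------

def smooth_sg(s: Spectrum, window: float = 41.0, order: int = 1) -> Spectrum:
    """Savitzky–Golay least-squares smoothing.

    ``window`` is in cm⁻¹ and converted to an odd point count on the
    spectrum's axis; edges use a polynomial fit on the truncated one-sided
    window (no reflection padding).
    """
    w = cm1_to_points(window, s.axis, odd=True)
    if w <= order + 1:
        raise ParameterError(
            f"SG window of {w} points must exceed order+1 = {order + 1}"
        )
    return s.with_intensity(savgol_filter(s.intensity, w, order, mode="interp"))


def _r_functional(filtered: np.ndarray, mean_spec: np.ndarray) -> float:
    """Mean relative deviation with a denominator guard; one spectrum's term."""
    num = np.abs(filtered - mean_spec)
    den = np.abs(filtered + mean_spec)
    guard = _TUNE_EPS * max(np.max(np.abs(mean_spec)), np.finfo(float).tiny)
    mask = den >= guard
    k = int(mask.sum())
    if k == 0:
        return np.nan
    return float(np.sum(num[mask] / den[mask]) / k)


def tune_sg(ss: SpectrumSet, windows: list[float] | np.ndarray,
            orders: list[int] | np.ndarray) -> SGTuningResult:
    """Grid-search Savitzky–Golay parameters against the set average.

    Requires at least two replicate spectra; returns the full r grid and the
    argmin (best window in cm⁻¹, best polynomial order).
    """
    if len(ss) < 2:
        raise InsufficientReplicatesError("tune_sg needs >= 2 replicate spectra")
    windows = list(windows)
    orders = [int(o) for o in orders]
    if not windows or not orders:
        raise ParameterError("window and order grids must be non-empty")
    mean_spec = ss.matrix().mean(axis=0)
    n = len(ss)
    r_grid = np.full((len(windows), len(orders)), np.nan)
    for i, w_cm1 in enumerate(windows):
        try:
            w_pts = cm1_to_points(w_cm1, ss.axis, odd=True)
        except ParameterError:
            continue
        for j, order in enumerate(orders):
            if w_pts <= order + 1:
                continue
            total = 0.0
            valid = True
            for s in ss:
                filt = savgol_filter(s.intensity, w_pts, order, mode="interp")
                term = _r_functional(filt, mean_spec)
                if np.isnan(term):
                    valid = False
                    break
                total += term
            if valid:
                r_grid[i, j] = total / (2.0 * n)
    if np.all(np.isnan(r_grid)):
        raise ParameterError("no valid (window, order) combination on the grid")
    flat = np.nanargmin(r_grid)
    bi, bj = np.unravel_index(flat, r_grid.shape)
    return SGTuningResult(
        windows=windows,
        orders=orders,
        r_grid=r_grid,
        best_window=float(windows[bi]),
        best_order=int(orders[bj]),
        best_r=float(r_grid[bi, bj]),
    )


# ---------------------------------------------------------------------------
# normalization and outliers
# ---------------------------------------------------------------------------

def normalize_area(s: Spectrum) -> Spectrum:
    """Divide the intensity by its trapezoidal integral over the axis.

    The output integrates to exactly 1; a zero or negative total area raises
    :class:`DegenerateSpectrumError`.
    """
    a = s.area()
    if not np.isfinite(a) or a <= 0:
        raise DegenerateSpectrumError(
            f"spectrum {s.label!r} has non-positive area {a}; cannot normalize"
        )
    return s.with_intensity(s.intensity / a)


def remove_outliers(ss: SpectrumSet, fraction: float = 0.05,
                    seed: int = 0) -> tuple[SpectrumSet, list[Spectrum]]:
    """Drop the stated fraction of spectra with the worst anomaly scores.

    Scoring uses an isolation forest (unsupervised tree-ensemble anomaly
    detection) on the leading principal-component scores of the intensity
    vectors — the projection concentrates localized spectral anomalies that
    random axis-aligned splits would dilute across hundreds of wavelength
    channels. Deterministic for a fixed seed. Returns ``(kept, removed)``;
    kept and removed partition the input, and ``fraction=0`` removes
    nothing.
    """
    if not (0.0 <= fraction < 0.5):
        raise ParameterError("outlier fraction must be in [0, 0.5)")
    if len(ss) < 5:
        raise InsufficientReplicatesError("outlier screening needs >= 5 spectra")
    n_remove = int(round(fraction * len(ss)))
    if n_remove == 0:
        return ss, []
    x = ss.matrix()
    n_comp = min(len(ss) - 1, 10)
    pca = PCA(n_components=n_comp, svd_solver="full").fit(x - x.mean(axis=0))
    # keep only the components carrying real set variance (>= 95% cumulative):
    # trailing noise dimensions would dilute the isolation splits
    k = int(np.searchsorted(np.cumsum(pca.explained_variance_ratio_), 0.95)) + 1
    proj = pca.transform(x - x.mean(axis=0))[:, :k]
    forest = IsolationForest(n_estimators=200, random_state=seed)
    forest.fit(proj)
    scores = forest.score_samples(proj)  # lower = more anomalous
    worst = np.argsort(scores, kind="stable")[:n_remove]
    removed_idx = set(int(i) for i in worst)
    kept = [s for i, s in enumerate(ss) if i not in removed_idx]
    removed = [s for i, s in enumerate(ss) if i in removed_idx]
    kept_set = SpectrumSet(kept, ss.group, dict(ss.metadata))
    kept_set.metadata["outliers_removed"] = [s.label for s in removed]
    return kept_set, removed


# ---------------------------------------------------------------------------
# full chain
# ---------------------------------------------------------------------------

def preprocess_spectrum(s: Spectrum, cfg: PreprocessConfig = PreprocessConfig()) -> Spectrum:
    """Baseline subtraction → SG smoothing → (optional) area normalization."""
    try:
        out = subtract_baseline(s, cfg.baseline_window, cfg.baseline_quantile)
        out = smooth_sg(out, cfg.sg_window, cfg.sg_order)
        if cfg.normalize == "area":
            out = normalize_area(out)
    except Exception as exc:
        raise type(exc)(f"[spectrum {s.label!r}] {exc}") from exc
    return out


def preprocess_set(ss: SpectrumSet, cfg: PreprocessConfig = PreprocessConfig()) -> SpectrumSet:
    """Apply the preprocessing chain to every spectrum in the set.

    Outlier screening, if enabled in the config, runs after the chain so it
    scores comparable (normalized) spectra. The effective configuration is
    recorded in the returned set's metadata.
    """
    out = ss.map(lambda s: preprocess_spectrum(s, cfg))
    out.metadata["preprocess"] = {
        "baseline_window_cm1": cfg.baseline_window,
        "baseline_quantile": cfg.baseline_quantile,
        "sg_window_cm1": cfg.sg_window,
        "sg_order": cfg.sg_order,
        "normalize": cfg.normalize,
        "remove_outliers": cfg.remove_outliers,
        "outlier_fraction": cfg.outlier_fraction if cfg.remove_outliers else 0.0,
        "seed": cfg.seed,
    }
    if cfg.remove_outliers and cfg.outlier_fraction > 0:
        out, _removed = remove_outliers(out, cfg.outlier_fraction, cfg.seed)
    return out
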