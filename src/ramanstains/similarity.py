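"""Spectral-similarity diagnostics: Soergel distance and proximity factor.

The Soergel distance between two non-negative vectors,

    S = Σ|xᵢ − zᵢ| / Σ max(xᵢ, zᵢ),

is a normalized dissimilarity in [0, 1]: 0 for identical curves, 1 for
disjoint support. Its block-averaged profile S_l replaces both spectra by
averages over sequential (non-overlapping) intervals of l points before
evaluating S; because averaging ever-larger blocks drives both
area-normalized spectra toward the same constant, S_l → 0 as l → N for any
pair, so the shape of S_l(l) carries information about how similar two
spectra are at each spectral scale. Block values are integral means
(trapezoidal integral over the block divided by the block width), which
makes the l = N limit exact for area-normalized inputs.

The proximity factor between a residual spectrum S_R and a library spectrum
S_0,

    r = ½ Σᵢ |S_R,i − S_0,i| / |S_R,i + S_0,i|,

is used to classify an extracted residual against a spectral library: the
class of the member with the smallest r wins.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import DegenerateSpectrumError, ParameterError
from .spectra import Spectrum

#: Relative denominator guard for the proximity factor.
_PROX_EPS = 1e-9


@dataclass
class SoergelProfile:
    """S_l over block lengths plus per-window distances at a fixed length."""

    l_values: np.ndarray
    s_values: np.ndarray
    pair: tuple[str, str] = ("", "")


@dataclass
class WindowedSoergel:
    """Per-window Soergel distances at one block length.

    ``distances`` holds NaN for windows whose denominator vanished; the
    ``undefined`` mask flags them.
    """

    l: int
    centers: np.ndarray     # window-center Raman shifts
    distances: np.ndarray
    undefined: np.ndarray


@dataclass
class ProximityResult:
    """Raw and per-point proximity factor between two spectra."""

    raw: float
    per_point: float
    n_points: int


def _clip_pair(x: Spectrum, z: Spectrum) -> tuple[np.ndarray, np.ndarray]:
    x.require_same_axis(z)
    return np.clip(x.intensity, 0.0, None), np.clip(z.intensity, 0.0, None)


def soergel(x: Spectrum, z: Spectrum) -> float:
    """Soergel distance between two spectra on one axis.

    Inputs are expected area-normalized; negative values (possible after
    baseline subtraction) are clipped at zero, since the max() in the
    denominator assumes non-negative intensities.
    """
    a, b = _clip_pair(x, z)
    den = float(np.sum(np.maximum(a, b)))
    if den == 0.0:
        raise DegenerateSpectrumError("Soergel distance undefined for an all-zero pair")
    return float(np.sum(np.abs(a - b)) / den)


def block_average(s: Spectrum, l: int) -> Spectrum:
    """Average a spectrum over sequential non-overlapping blocks of l points.

    Each block is replaced by one point at the block-center shift carrying
    the block's integral mean (trapezoidal integral / width); a 2-point
    block's integral mean equals its arithmetic mean. The trailing partial
    block is averaged as-is. ``l = 1`` returns the input; ``l = N`` returns
    the single global mean. The total integral (block value × block width,
    summed) is conserved exactly.
    """
    n = s.n_points
    if not (1 <= l <= n):
        raise ParameterError(f"block length {l} out of range [1, {n}]")
    if l == 1:
        return s
    xs: list[float] = []
    ys: list[float] = []
    for start in range(0, n, l):
        stop = min(start + l, n)
        ax = s.axis[start:stop]
        yv = s.intensity[start:stop]
        xs.append(float(ax.mean()))
        if ax.size == 1:
            ys.append(float(yv[0]))
        else:
            ys.append(float(np.trapezoid(yv, ax) / (ax[-1] - ax[0])))
    return Spectrum._unchecked(np.asarray(xs), np.asarray(ys), s.label)


def soergel_profile(x: Spectrum, z: Spectrum,
                    l_values=None) -> SoergelProfile:
    """S_l = Soergel(block_average(x, l), block_average(z, l)) over l.

    With both inputs area-normalized, S at l = N is 0 to within 1e−9 (both
    global integral means equal 1/range).
    """
    x.require_same_axis(z)
    n = x.n_points
    if l_values is None:
        l_values = np.unique(np.round(np.geomspace(1, n, 40)).astype(int))
    ls = np.asarray([int(l) for l in l_values])
    vals = np.array([soergel(block_average(x, l), block_average(z, l)) for l in ls])
    return SoergelProfile(ls, vals, (x.label, z.label))


def windowed_soergel(x: Spectrum, z: Spectrum, l: int) -> WindowedSoergel:
    """Soergel distance evaluated independently inside each window of l points."""
    a, b = _clip_pair(x, z)
    n = x.n_points
    if not (1 <= l <= n):
        raise ParameterError(f"window length {l} out of range [1, {n}]")
    centers: list[float] = []
    dists: list[float] = []
    for start in range(0, n, l):
        stop = min(start + l, n)
        aw, bw = a[start:stop], b[start:stop]
        centers.append(float(x.axis[start:stop].mean()))
        den = float(np.sum(np.maximum(aw, bw)))
        dists.append(float(np.sum(np.abs(aw - bw)) / den) if den > 0 else np.nan)
    d = np.asarray(dists)
    return WindowedSoergel(l, np.asarray(centers), d, np.isnan(d))


def proximity_factor(residual: Spectrum, library_member: Spectrum,
                     full: bool = False):
    """Proximity factor r = ½ Σ |S_R − S_0| / |S_R + S_0|.

    Points where |S_R + S_0| falls below 1e−9 of the pair's maximum are
    skipped. Returns the raw sum by default; with ``full=True`` a
    :class:`ProximityResult` also reporting the per-contributing-point
    variant (classification by argmin is invariant to that constant).
    """
    residual.require_same_axis(library_member)
    a = residual.intensity
    b = library_member.intensity
    num = np.abs(a - b)
    den = np.abs(a + b)
    guard = _PROX_EPS * max(np.max(np.abs(a)), np.max(np.abs(b)), np.finfo(float).tiny)
    mask = den >= guard
    k = int(mask.sum())
    if k == 0:
        raise DegenerateSpectrumError("proximity factor: no contributing points")
    raw = float(0.5 * np.sum(num[mask] / den[mask]))
    if full:
        return ProximityResult(raw, raw / k, k)
    return raw
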