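"""MCRAD: multivariate curve resolution with virtual standard additions.

The comparison method. A measured spectrum S_org is "titrated" numerically
with known multiples of the reference,

    Ŝ_j = S_org + ĉ_j · S_ref,   ĉ_0 = 0 < ĉ_1 < ...,

the augmented matrix is factorized by two-component non-negative alternating
least squares (bilinear model W = C·Sᵗ, target + lumped blank), and the
target component's concentration scores are regressed against the added
levels. Classical standard-addition extrapolation then gives the unknown
weight as intercept/slope.

The ALS variant is concrete and testable: component 1 is initialized to the
reference and softly re-anchored to it each cycle (re-blended at a
configurable weight, default 0.5 — a hard constraint would make the
additions trivially identifiable, full freedom would let the target drift);
component 2 starts from the non-negative residual of the sample after
projecting out the reference. Both half-steps are exact two-variable
non-negative least squares. A monotone safeguard repeats a cycle without the
re-blend if the blend would raise the reconstruction residual, so the
recorded residual history never increases.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .errors import ParameterError, RamanStainsError
from .rsc import RestoredVF
from .spectra import Spectrum, SpectrumSet

log = logging.getLogger(__name__)

DEFAULT_LEVELS = (0.0, 0.5, 1.0, 1.5, 2.0)


@dataclass
class AdditionSeries:
    """The virtual standard-addition series: levels ĉ_j and spectra Ŝ_j."""

    levels: np.ndarray
    augmented: SpectrumSet


@dataclass
class MCRSolution:
    """Two-component non-negative bilinear factorization of the series."""

    concentrations: np.ndarray       # (n_levels, 2); column 0 = target
    components: np.ndarray           # (2, n_points); row 0 anchored to reference
    residuals: list = field(default_factory=list)  # Frobenius norm per cycle
    iterations: int = 0
    converged: bool = True

    @property
    def residual_norm(self) -> float:
        return self.residuals[-1] if self.residuals else np.inf


@dataclass
class MCRADResult:
    """Standard-addition extrapolation of the target weight."""

    c_hat: float
    slope: float
    intercept: float
    r_squared: float
    solution: MCRSolution
    pair: tuple[str, str] = ("", "")
    unreliable: bool = False
    #: Relative change of the blank component's score across the addition
    #: series. Virtual additions leave the blank untouched, so a healthy
    #: factorization keeps this near zero; a large value means the blank
    #: component absorbed part of the target (rotational ambiguity) and the
    #: extrapolation cannot be trusted.
    blank_score_trend: float = 0.0


# ---------------------------------------------------------------------------
# additions
# ---------------------------------------------------------------------------

def make_additions(sample: Spectrum, reference: Spectrum,
                   levels=DEFAULT_LEVELS) -> AdditionSeries:
    """Build Ŝ_j = S_org + ĉ_j·S_ref exactly (no renormalization inside the
    series — the additions must stay linear in ĉ_j)."""
    sample.require_same_axis(reference)
    lv = np.asarray(list(levels), dtype=float)
    if lv.size < 2:
        raise ParameterError("need at least two addition levels")
    if lv[0] != 0.0:
        raise ParameterError("the first addition level must be 0")
    if np.any(np.diff(lv) <= 0):
        raise ParameterError("addition levels must be strictly ascending (no duplicates)")
    spectra = [Spectrum(sample.axis, sample.intensity + c * reference.intensity,
                        f"{sample.label}+{c:g}x{reference.label}")
               for c in lv]
    return AdditionSeries(lv, SpectrumSet(spectra, "addition-series"))


# ---------------------------------------------------------------------------
# two-variable NNLS (exact, vectorized)
# ---------------------------------------------------------------------------

def _nnls2(g: np.ndarray, h: np.ndarray) -> np.ndarray:
    """Solve min_{x>=0} ||A x - b||² for many right-hand sides at once.

    ``g`` is the 2×2 Gram matrix AᵀA (shared); ``h`` is AᵀB with shape
    (2, m). Enumerates the four KKT-active sets (both free, one clamped,
    both zero) and picks the feasible candidate with the smallest quadratic
    form q(x) = xᵀGx − 2xᵀh per column. Exact for this problem size.
    """
    m = h.shape[1]
    cands = np.zeros((4, 2, m))
    det = g[0, 0] * g[1, 1] - g[0, 1] * g[1, 0]
    if det > 1e-300:
        cands[0, 0] = (g[1, 1] * h[0] - g[0, 1] * h[1]) / det
        cands[0, 1] = (g[0, 0] * h[1] - g[1, 0] * h[0]) / det
    else:
        cands[0] = -1.0  # infeasible marker
    if g[0, 0] > 0:
        cands[1, 0] = np.maximum(h[0] / g[0, 0], 0.0)
    if g[1, 1] > 0:
        cands[2, 1] = np.maximum(h[1] / g[1, 1], 0.0)
    # cands[3] = both zero

    q = np.full((4, m), np.inf)
    for i in range(4):
        x = cands[i]
        feasible = (x[0] >= 0) & (x[1] >= 0)
        gx0 = g[0, 0] * x[0] + g[0, 1] * x[1]
        gx1 = g[1, 0] * x[0] + g[1, 1] * x[1]
        qi = x[0] * gx0 + x[1] * gx1 - 2.0 * (x[0] * h[0] + x[1] * h[1])
        q[i] = np.where(feasible, qi, np.inf)
    best = np.argmin(q, axis=0)
    return cands[best, :, np.arange(m)].T  # (2, m)


def _als_cycle(w: np.ndarray, s: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """One pure ALS cycle: C-step then S-step, both non-negative."""
    c = _nnls2(s @ s.T, s @ w.T).T            # (n, 2)
    s_new = _nnls2(c.T @ c, c.T @ w)          # (2, p)
    return c, s_new


# ---------------------------------------------------------------------------
# MCR-ALS
# ---------------------------------------------------------------------------

def mcr_als(series: AdditionSeries, reference: Spectrum, tol: float = 1e-8,
            max_iter: int = 500, blend: float = 0.5) -> MCRSolution:
    """Two-component non-negative ALS on the augmented matrix.

    Component 1 starts at the (clipped) reference spectrum and is re-blended
    toward it at weight ``blend`` each cycle; component 2 starts at the
    non-negative residual of the unaugmented sample after projecting out the
    reference. Stops when the relative residual change falls below ``tol``
    or after ``max_iter`` cycles (then flagged ``converged=False``).
    """
    if tol <= 0:
        raise ParameterError("tol must be > 0")
    if not (0.0 <= blend <= 1.0):
        raise ParameterError("blend must be in [0, 1]")
    w = series.augmented.matrix()
    ref = np.clip(reference.intensity, 0.0, None)
    sample = series.augmented[0].intensity
    rr = float(ref @ ref)
    proj = (sample @ ref) / rr if rr > 0 else 0.0
    s2 = np.clip(sample - proj * ref, 0.0, None)
    s = np.vstack([ref, s2])

    c, s = _als_cycle(w, s)
    residuals = [float(np.linalg.norm(w - c @ s))]
    w_norm = float(np.linalg.norm(w))
    floor = 1e-13 * max(w_norm, np.finfo(float).tiny)
    converged = residuals[0] <= floor
    it = 1
    for it in range(2, max_iter + 1):
        if converged:
            break
        s_blend = s.copy()
        s_blend[0] = (1.0 - blend) * s[0] + blend * ref
        c_new, s_new = _als_cycle(w, s_blend)
        r_new = float(np.linalg.norm(w - c_new @ s_new))
        if r_new > residuals[-1] * (1.0 + 1e-12):
            # blend would raise the residual: fall back to a pure ALS cycle
            c_new, s_new = _als_cycle(w, s)
            r_new = float(np.linalg.norm(w - c_new @ s_new))
        c, s = c_new, s_new
        prev = residuals[-1]
        residuals.append(r_new)
        scale = max(residuals[0], np.finfo(float).tiny)
        if r_new <= floor or abs(prev - r_new) < tol * scale:
            converged = True
            break
    if not converged:
        log.warning("MCR-ALS did not converge in %d iterations", max_iter)
    return MCRSolution(c, s, residuals, it, converged)


def mcrad_estimate(sample: Spectrum, reference: Spectrum,
                   levels=DEFAULT_LEVELS, tol: float = 1e-8,
                   max_iter: int = 500, blend: float = 0.5) -> MCRADResult:
    """Estimate the target weight by virtual standard additions.

    Runs :func:`make_additions` → :func:`mcr_als`, regresses the target
    component's concentration scores on the added levels (ordinary least
    squares) and extrapolates ``c_hat = intercept / slope``. The
    ``unreliable`` flag is set by a non-positive slope, a fit with
    R² < 0.9, or a blank component whose score drifts by more than 5%
    across the addition series (the additions contain no blank, so drift
    means the factorization leaked the target into the blank). The estimate
    is still reported (negative extrapolations are meaningful for the
    absence test).
    """
    series = make_additions(sample, reference, levels)
    sol = mcr_als(series, reference, tol=tol, max_iter=max_iter, blend=blend)
    scores = sol.concentrations[:, 0]
    lv = series.levels
    slope, intercept = np.polyfit(lv, scores, 1)
    fitted = slope * lv + intercept
    ss_res = float(np.sum((scores - fitted) ** 2))
    ss_tot = float(np.sum((scores - scores.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else (1.0 if ss_res == 0 else 0.0)
    if slope > 0:
        c_hat = float(intercept / slope)
    else:
        c_hat = np.nan

    blank_scores = sol.concentrations[:, 1]
    mean_blank = float(blank_scores.mean())
    if mean_blank > np.finfo(float).tiny:
        blank_slope = float(np.polyfit(lv, blank_scores, 1)[0])
        trend = abs(blank_slope) * (lv[-1] - lv[0]) / mean_blank
    else:
        trend = 0.0

    unreliable = (slope <= 0) or (r2 < 0.9) or (trend > 0.05)
    if unreliable:
        log.warning("MCRAD extrapolation unreliable for pair (%s, %s): "
                    "slope=%.3g R²=%.3g blank-trend=%.3g",
                    sample.label, reference.label, slope, r2, trend)
    return MCRADResult(c_hat, float(slope), float(intercept), float(r2), sol,
                       (sample.label, reference.label), unreliable, trend)


def mcrad_pairwise(samples: SpectrumSet, references: SpectrumSet,
                   levels=DEFAULT_LEVELS, tol: float = 1e-8,
                   max_iter: int = 500, blend: float = 0.5) -> RestoredVF:
    """One MCRAD weight per (sample, reference) pair; NaN extrapolations
    (non-positive slope) are dropped as failures."""
    values: list[float] = []
    failed = 0
    for s in samples:
        for r in references:
            try:
                res = mcrad_estimate(s, r, levels, tol, max_iter, blend)
            except RamanStainsError as exc:
                failed += 1
                log.warning("MCRAD pair (%s, %s) failed: %s", s.label, r.label, exc)
                continue
            if np.isnan(res.c_hat):
                failed += 1
                continue
            values.append(res.c_hat)
    if not values:
        raise RamanStainsError("mcrad_pairwise: all pairs failed")
    return RestoredVF.from_values(np.asarray(values), "mcrad", failed)
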