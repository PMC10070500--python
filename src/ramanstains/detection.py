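"""Decision layer: absence testing, residual extraction and screening.

The absence test asks whether a target (e.g. dried blood) is present in a
set of measured spectra. All (sample, reference) pairs yield restored
weights C̃ whose distribution f(C) has mean μ and standard deviation σ; the
standard score

    Z = (0 − μ)/σ

measures how far the restored weight sits from zero, and the two-sided
normal confidence probability of absence is P = 2·(1 − Φ(|Z|)). Large P
supports "target absent"; at the 95% confidence level absence is rejected
when |Z| exceeds 1.96.

For the hierarchical false-positive screen the toolkit also provides:
reverse-RSC residual extraction (estimate and subtract the *substrate*
contribution from a stain spectrum, leaving the biofluid residual),
proximity-factor classification of that residual against a spectral
library, and a PCA screen checking whether apparent-stain and pure-substrate
spectra separate in the first two principal components (mean silhouette on
the 2-D scores as the separation statistic).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.stats import norm
from sklearn.decomposition import PCA
from sklearn.metrics import silhouette_score

from .errors import DegenerateSpectrumError, EmptyInputError, ParameterError
from .preprocess import normalize_area
from .rsc import DEFAULT_SEARCH, RestoredVF, rsc_estimate, rsc_pairwise
from .mcrad import DEFAULT_LEVELS, mcrad_pairwise
from .similarity import proximity_factor
from .spectra import Spectrum, SpectrumSet

log = logging.getLogger(__name__)


@dataclass
class AbsenceTestReport:
    """Z score and confidence probability of target absence."""

    method: str
    mu: float
    sigma: float
    z: float
    p: float
    level: float
    critical_value: float
    absence_rejected: bool
    n_pairs: int


@dataclass
class ResidualReport:
    """Reverse-RSC extraction of the biofluid residual from a stain."""

    residual: Spectrum            # stain − ĉ·substrate, un-normalized
    #: Clipped at 0 and area-normalized for shape-based library comparison;
    #: None when the residual vanishes (nothing left to classify).
    normalized: Spectrum | None
    substrate_weight: float
    boundary_warning: bool


@dataclass
class ProximityReport:
    """Per-class proximity factors of a residual against a library."""

    r_by_class: dict              # class -> list of r values
    best_class: str
    best_r: float


@dataclass
class ScreenReport:
    """PCA false-positive screen of stains vs. pure substrate."""

    scores: np.ndarray            # (n, 2) first two PC scores, stains first
    groups: list                  # group label per row
    separation: float             # mean silhouette on the 2-D scores
    separated: bool
    threshold: float


# ---------------------------------------------------------------------------
# absence test
# ---------------------------------------------------------------------------

def z_score(vf: RestoredVF) -> tuple[float, float]:
    """Standard score and two-sided confidence probability of absence.

    z = (0 − μ)/σ and p = 2·(1 − Φ(|z|)); e.g. z = 0.03 → p = 0.976 and
    z = 2.7 → p = 0.007. p is exact here and rounded only at reporting.
    """
    if vf.sigma <= 0:
        raise DegenerateSpectrumError(
            f"restored-weight distribution is degenerate (σ = {vf.sigma}; "
            f"n = {vf.values.size}, μ = {vf.mu}); Z undefined"
        )
    z = (0.0 - vf.mu) / vf.sigma
    p = float(2.0 * norm.sf(abs(z)))
    return float(z), p


def critical_value(level: float) -> float:
    """Two-sided standard-normal critical value (1.96 at the 95% level)."""
    if not (0.0 < level < 1.0):
        raise ParameterError("confidence level must be in (0, 1)")
    return float(norm.ppf(1.0 - (1.0 - level) / 2.0))


def absence_test(samples: SpectrumSet, references: SpectrumSet,
                 method: str = "rsc", level: float = 0.95,
                 search=DEFAULT_SEARCH, levels=DEFAULT_LEVELS) -> AbsenceTestReport:
    """Run the chosen pairwise estimator and test "target absent".

    Absence is *not* rejected iff |Z| ≤ the two-sided critical value at the
    stated confidence level (default 0.95 → 1.96).
    """
    if method == "rsc":
        vf = rsc_pairwise(samples, references, search)
    elif method == "mcrad":
        vf = mcrad_pairwise(samples, references, levels)
    else:
        raise ParameterError(f"unknown method {method!r}; use 'rsc' or 'mcrad'")
    z, p = z_score(vf)
    crit = critical_value(level)
    return AbsenceTestReport(method, vf.mu, vf.sigma, z, p, level, crit,
                             absence_rejected=abs(z) > crit,
                             n_pairs=int(vf.values.size))


# ---------------------------------------------------------------------------
# reverse RSC + classification
# ---------------------------------------------------------------------------

def reverse_rsc_residual(stain: Spectrum, pure_substrate: Spectrum,
                         search=DEFAULT_SEARCH) -> ResidualReport:
    """Extract the biofluid residual by removing the substrate contribution.

    RSC estimates the *substrate* weight inside the stain spectrum (the
    substrate plays the reference role), subtracts it, and returns the raw
    residual plus a clipped, area-normalized copy for shape-based library
    classification.
    """
    res = rsc_estimate(stain, pure_substrate, search)
    residual = stain.with_intensity(
        stain.intensity - res.c_hat * pure_substrate.intensity,
        f"{stain.label}-residual",
    )
    clipped = residual.with_intensity(np.clip(residual.intensity, 0.0, None))
    try:
        normalized = normalize_area(clipped)
    except DegenerateSpectrumError:
        normalized = None  # residual vanished: nothing to classify
    return ResidualReport(residual, normalized, res.c_hat, res.boundary_warning)


def classify_residual(residual: Spectrum, library: SpectrumSet) -> ProximityReport:
    """Classify a residual by the proximity factor against a grouped library.

    Library members must carry class labels of the form ``"class/whatever"``
    or set-level groups; here the member label's prefix before the first
    ``"/"`` (or the whole label) is the class. The class of the member with
    the globally smallest r wins.
    """
    if len(library) == 0:
        raise EmptyInputError("empty spectral library")
    r_by_class: dict[str, list[float]] = {}
    best_class, best_r = "", np.inf
    for member in library:
        cls = member.label.split("/")[0]
        r = proximity_factor(residual, member)
        r_by_class.setdefault(cls, []).append(r)
        if r < best_r:
            best_class, best_r = cls, r
    return ProximityReport(r_by_class, best_class, float(best_r))


# ---------------------------------------------------------------------------
# PCA screen
# ---------------------------------------------------------------------------

def pca_screen(stains: SpectrumSet, pures: SpectrumSet,
               threshold: float = 0.25) -> ScreenReport:
    """PCA-based check that apparent stains differ from the pure substrate.

    Mean-centered PCA on the pooled preprocessed spectra; the separation
    statistic is the mean silhouette of the two group labels on the first
    two component scores, flagged "separated" above ``threshold``.
    """
    if len(stains) < 3 or len(pures) < 3:
        raise ParameterError("PCA screen needs >= 3 spectra per group")
    x = np.vstack([stains.matrix(), pures.matrix()])
    if np.all(x == x[0]):
        raise DegenerateSpectrumError("PCA screen needs at least 2 distinct spectra")
    groups = ["stain"] * len(stains) + ["pure"] * len(pures)
    scores = PCA(n_components=2, svd_solver="full").fit_transform(x - x.mean(axis=0))
    sep = float(silhouette_score(scores, groups))
    return ScreenReport(scores, groups, sep, sep > threshold, threshold)
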