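"""Synthetic Raman spectra: references, substrates, mixtures and noise.

This module is the test bed for the whole toolkit. It builds peak-structured
reference spectra (dried blood, seminal fluid, and common fabric substrates)
from published band positions, composes two-component mixtures

    S_org(k) = S_blank(k) + C · S_ref(k)  (+ baseline + noise),

and adds zero-mean uniform noise whose amplitude ν is a fraction of the mean
reference intensity, each draw uniform on [−0.5, 0.5].

Band positions for blood and the fabrics follow standard Raman assignments
(amide I at 1658 cm⁻¹, phenylalanine at 1003 cm⁻¹ and the 826/856 cm⁻¹
tyrosine doublet for blood; indigo at 1573 cm⁻¹ for denim; PET bands for
blue polyester; nylon bands for white polyester; cellulose bands for
cotton). Relative band amplitudes are a fixed deterministic ladder that
respects the qualitative prominence of the listed bands — the most intense
band is listed first — since absolute intensities are instrument-dependent.
The semen-like class is a synthetic stand-in built from commonly reported
dried-semen bands; it exists to exercise residual classification, not to
calibrate against any measured spectrum.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import AxisError, ParameterError
from .preprocess import normalize_area
from .spectra import AxisSpec, Spectrum, SpectrumSet

#: Default full width at half maximum of a synthetic band, cm⁻¹. Narrow
#: enough that neighbouring listed bands stay resolved on a 1 cm⁻¹ axis.
DEFAULT_FWHM = 12.0


@dataclass(frozen=True)
class PeakModel:
    """One synthetic Raman band."""

    center: float                 # cm⁻¹
    fwhm: float = DEFAULT_FWHM    # cm⁻¹
    amplitude: float = 1.0        # relative height
    shape: str = "lorentzian"     # {"lorentzian", "gaussian"}

    def __post_init__(self) -> None:
        if self.fwhm <= 0:
            raise ParameterError("peak width must be positive")
        if self.amplitude <= 0:
            raise ParameterError("peak amplitude must be positive")
        if self.shape not in ("lorentzian", "gaussian"):
            raise ParameterError(f"unknown peak shape {self.shape!r}")

    def profile(self, axis: np.ndarray) -> np.ndarray:
        d = axis - self.center
        if self.shape == "lorentzian":
            g = self.fwhm / 2.0
            return self.amplitude * g * g / (d * d + g * g)
        return self.amplitude * np.exp(-4.0 * np.log(2.0) * d * d / (self.fwhm ** 2))


@dataclass(frozen=True)
class NoiseModel:
    """Additive uniform noise: amplitude ν (relative to a reference mean),
    draws iid uniform on [−0.5, 0.5], seeded."""

    nu: float
    seed: int = 0

    def __post_init__(self) -> None:
        if self.nu < 0:
            raise ParameterError("noise amplitude nu must be >= 0")


@dataclass(frozen=True)
class MixtureSpec:
    """How to compose one stain spectrum: target weight C, an optional
    polynomial fluorescence stand-in, and an optional noise model.

    ``baseline`` holds polynomial coefficients (c0, c1, c2, ...) evaluated in
    the normalized axis coordinate t = (k − k_min)/(k_max − k_min) ∈ [0, 1],
    so magnitudes are axis-independent.
    """

    target_vf: float
    baseline: tuple = ()
    noise: NoiseModel | None = None

    def __post_init__(self) -> None:
        if self.target_vf < 0:
            raise ParameterError("target volume fraction must be >= 0 for generation")


# ---------------------------------------------------------------------------
# built-in band tables
# ---------------------------------------------------------------------------

def _ladder(rank: int) -> float:
    """Deterministic amplitude ladder 1.0, 0.8, 0.65, ... with floor 0.2."""
    if rank == 0:
        return 1.0
    if rank == 1:
        return 0.8
    return max(0.2, 0.65 * 0.85 ** (rank - 2))


# Entries are (center, fwhm) with None = DEFAULT_FWHM; a tuple of entries at
# one position shares a single ladder rank (e.g. the blood 826/856 doublet).
_BAND_TABLES: dict[str, list] = {
    "blood": [
        (1658, None), (1003, None), ((826, None), (856, None)), (754, None),
        (960, None), (1032, None), (1127, None), (1208, None), (1449, None),
        (1340, None), (623, None), (644, None),
    ],
    "denim": [
        (1573, None), (1380, None), (1340, None), (1090, None), (460, None),
        (1090, 120.0),  # broad 1030–1150 cellulose envelope
    ],
    "blue_polyester": [
        (1725, None), (1612, None), (702, None), (859, None), (998, None),
        (1096, None), (1179, None), (1291, None), (1416, None), (1463, None),
    ],
    "white_polyester": [
        (1637, None), (1440, None), (1080, None), (1280, None), (1300, None),
        (1094, 68.0),  # broad 1060–1128 envelope
        (1235, None),
    ],
    "cotton": [
        (1380, None), (1340, None), (1090, None), (460, None),
        (1090, 120.0),  # broad 1030–1150 cellulose envelope
    ],
    # Synthetic stand-in class from commonly reported dried-semen bands.
    "semen": [
        (1002, None), (1666, None), (1449, None), (1245, None), (1320, None),
        (888, None), (830, None), (620, None),
    ],
    # Synthetic control substrate: every band sits > 40 cm⁻¹ from any blood
    # band, so target and substrate share no peak support (tails only).
    "disjoint_control": [
        (460, None), (520, None), (700, None), (1500, None), (1550, None),
        (1720, None), (1760, None),
    ],
}

REFERENCE_KINDS = tuple(_BAND_TABLES) + ("custom",)


def _jittered_reference(kind: str, axis: AxisSpec, rng: np.random.Generator,
                        amp_jitter: float = 0.0, pos_jitter: float = 0.0,
                        width_jitter: float = 0.0) -> "Spectrum":
    """A replicate of a built-in reference with jittered band parameters
    (spot-to-spot heterogeneity), re-normalized to unit area."""
    peaks = _table_peaks(kind)
    if amp_jitter > 0 or pos_jitter > 0 or width_jitter > 0:
        peaks = [PeakModel(p.center + (rng.normal(0.0, pos_jitter) if pos_jitter else 0.0),
                           p.fwhm * (float(np.exp(rng.normal(0.0, width_jitter)))
                                     if width_jitter else 1.0),
                           p.amplitude * (float(np.exp(rng.normal(0.0, amp_jitter)))
                                          if amp_jitter else 1.0),
                           p.shape) for p in peaks]
    return make_reference("custom", axis, peaks)


def _table_peaks(kind: str) -> list[PeakModel]:
    peaks: list[PeakModel] = []
    for rank, entry in enumerate(_BAND_TABLES[kind]):
        amp = _ladder(rank)
        sub = entry if isinstance(entry[0], tuple) else (entry,)
        for center, fwhm in sub:
            peaks.append(PeakModel(center, DEFAULT_FWHM if fwhm is None else fwhm, amp))
    return peaks


def make_reference(kind: str, axis: AxisSpec = AxisSpec(),
                   peaks: list[PeakModel] | None = None) -> Spectrum:
    """Build an area-normalized, noiseless reference spectrum.

    Parameters
    ----------
    kind : str
        One of ``blood``, ``semen``, ``blue_polyester``, ``denim``,
        ``cotton``, ``white_polyester`` (built-in band tables) or ``custom``
        (requires ``peaks``).
    axis : AxisSpec
        Target axis; all peak centers must lie within it.
    peaks : list of PeakModel, optional
        Explicit bands for ``kind="custom"``.

    Returns
    -------
    Spectrum
        Sum of the band profiles, normalized to unit trapezoidal area;
        deterministic.
    """
    if kind == "custom":
        if not peaks:
            raise ParameterError("kind='custom' requires an explicit peak list")
        use = peaks
    else:
        if kind not in _BAND_TABLES:
            raise ParameterError(
                f"unknown reference kind {kind!r}; choose from {REFERENCE_KINDS}"
            )
        use = _table_peaks(kind)
    grid = axis.grid()
    for p in use:
        if not (grid[0] <= p.center <= grid[-1]):
            raise ParameterError(
                f"peak center {p.center} cm⁻¹ outside axis [{grid[0]}, {grid[-1]}]"
            )
    y = np.zeros_like(grid)
    for p in use:
        y += p.profile(grid)
    return normalize_area(Spectrum(grid, y, kind))


# ---------------------------------------------------------------------------
# noise and mixtures
# ---------------------------------------------------------------------------

def add_noise(s: Spectrum, nm: NoiseModel, scale_reference: float,
              rng: np.random.Generator | None = None) -> Spectrum:
    """Add zero-mean uniform noise: out(k) = s(k) + ν·scale·u(k), u ~ U[−0.5, 0.5].

    ``scale_reference`` is the mean intensity of the reference set the noise
    amplitude is quoted against. Pass ``rng`` to draw from an external
    stream; otherwise the model's own seed is used (repeatable).
    """
    if nm.nu == 0:
        return s
    gen = rng if rng is not None else np.random.default_rng(nm.seed)
    u = gen.uniform(-0.5, 0.5, size=s.n_points)
    return s.with_intensity(s.intensity + nm.nu * scale_reference * u)


def make_mixture(blank: Spectrum, ref: Spectrum, spec: MixtureSpec,
                 rng: np.random.Generator | None = None,
                 label: str = "") -> Spectrum:
    """Compose S_org = S_blank + C·S_ref (+ baseline + noise) on a shared axis."""
    blank.require_same_axis(ref)
    y = blank.intensity + spec.target_vf * ref.intensity
    if spec.baseline:
        t = (blank.axis - blank.axis[0]) / (blank.axis[-1] - blank.axis[0])
        y = y + np.polynomial.polynomial.polyval(t, np.asarray(spec.baseline, dtype=float))
    out = Spectrum(blank.axis, y, label or f"mix_C{spec.target_vf:g}")
    if spec.noise is not None and spec.noise.nu > 0:
        out = add_noise(out, spec.noise, float(np.mean(ref.intensity)), rng=rng)
    return out


# ---------------------------------------------------------------------------
# full dataset
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DatasetConfig:
    """Study conditions for a synthetic three-group experiment.

    ``n`` spectra per group; per-stain target weights drawn from a normal
    distribution (``c_mean``, ``c_sd``) clipped at zero; noise amplitude
    ``nu`` relative to the mean reference intensity; one seed drives all
    randomness via independent substreams.
    """

    substrate: str = "denim"
    target: str = "blood"
    n: int = 10
    c_mean: float = 0.4
    c_sd: float = 0.05
    nu: float = 0.02
    seed: int = 0
    axis: AxisSpec = field(default_factory=AxisSpec)
    baseline: tuple = ()
    #: Per-replicate log-normal jitter of band amplitudes (SD of log height).
    #: Emulates spot-to-spot heterogeneity of mapped stains; 0 disables.
    band_jitter: float = 0.05
    #: Per-replicate Gaussian jitter of band centers, cm⁻¹ (calibration and
    #: microenvironment shifts).
    position_jitter: float = 1.0
    #: Per-replicate log-normal jitter of band widths (defocus, local
    #: disorder); SD of log FWHM.
    width_jitter: float = 0.10
    #: Per-replicate random quadratic fluorescence, shifted non-negative:
    #: coefficients drawn N(0, baseline_sd²) on the unit-interval polynomial
    #: basis, on top of any fixed ``baseline``. Fluorescence in biological
    #: Raman measurements typically dwarfs the Raman signal; the default is
    #: ≈ 15× the mean intensity of an area-normalized spectrum on the
    #: default axis.
    baseline_sd: float = 0.01

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ParameterError("need at least 2 spectra per group")
        if self.nu < 0:
            raise ParameterError("nu must be >= 0")
        if self.c_sd < 0:
            raise ParameterError("c_sd must be >= 0")
        if min(self.band_jitter, self.position_jitter, self.width_jitter,
               self.baseline_sd) < 0:
            raise ParameterError("jitter and baseline_sd parameters must be >= 0")


def make_dataset(cfg: DatasetConfig) -> tuple[SpectrumSet, SpectrumSet, SpectrumSet]:
    """Generate the three measured groups of a stain-mapping experiment.

    Returns ``(stains, pures, refs)``:

    - ``refs`` — noisy replicates of the target reference (the role of a
      stain on a non-interfering aluminium-foil substrate);
    - ``pures`` — noisy replicates of the pure substrate;
    - ``stains`` — mixtures (1 − C_i)·substrate + C_i·target with
      per-spectrum C_i drawn from N(c_mean, c_sd²) clipped at 0, plus
      baseline and noise. The convex combination keeps the stain at unit
      area, so C_i is exactly the relative weight of the area-normalized
      target inside the area-normalized stain — the quantity the estimators
      restore after preprocessing re-normalizes every spectrum.

    The true weights are recorded in ``stains.metadata["true_c"]``
    (label → C), so parameter recovery is checkable. Bit-reproducible from
    the config.
    """
    target = make_reference(cfg.target, cfg.axis)
    root = np.random.SeedSequence(cfg.seed)
    rng_c, rng_stain, rng_pure, rng_ref = (np.random.default_rng(s) for s in root.spawn(4))
    scale = float(np.mean(target.intensity))
    nm = NoiseModel(cfg.nu, cfg.seed)
    grid = cfg.axis.grid()
    t = (grid - grid[0]) / (grid[-1] - grid[0])

    def realization(kind: str, rng: np.random.Generator) -> np.ndarray:
        """One replicate of a reference: jittered bands, unit area."""
        return _jittered_reference(kind, cfg.axis, rng, cfg.band_jitter,
                                   cfg.position_jitter, cfg.width_jitter).intensity

    def fluorescence(rng: np.random.Generator) -> np.ndarray:
        base = np.polynomial.polynomial.polyval(t, np.asarray(cfg.baseline, dtype=float)) \
            if cfg.baseline else np.zeros_like(t)
        if cfg.baseline_sd > 0:
            coef = rng.normal(0.0, cfg.baseline_sd, size=3)
            base = base + coef[0] + coef[1] * t + coef[2] * t * t
        return base - min(base.min(), 0.0)  # fluorescence is non-negative

    true_c = np.clip(rng_c.normal(cfg.c_mean, cfg.c_sd, size=cfg.n), 0.0, None) \
        if cfg.c_sd > 0 else np.full(cfg.n, cfg.c_mean)

    stains = []
    for i, c in enumerate(true_c):
        y = (1.0 - c) * realization(cfg.substrate, rng_stain) \
            + c * realization(cfg.target, rng_stain) + fluorescence(rng_stain)
        s = Spectrum(grid, y, f"stain_{i:03d}")
        stains.append(add_noise(s, nm, scale, rng=rng_stain))
    pures = [add_noise(Spectrum(grid, realization(cfg.substrate, rng_pure)
                                + fluorescence(rng_pure), f"pure_{i:03d}"),
                       nm, scale, rng=rng_pure) for i in range(cfg.n)]
    refs = [add_noise(Spectrum(grid, realization(cfg.target, rng_ref)
                               + fluorescence(rng_ref), f"ref_{i:03d}"),
                      nm, scale, rng=rng_ref) for i in range(cfg.n)]

    stain_set = SpectrumSet(
        stains, "stain-on-substrate",
        {"true_c": {s.label: float(c) for s, c in zip(stains, true_c)},
         "config": dict(cfg.__dict__) | {"axis": (cfg.axis.start, cfg.axis.stop, cfg.axis.step)}})
    pure_set = SpectrumSet(pures, "pure-substrate")
    ref_set = SpectrumSet(refs, "reference")
    return stain_set, pure_set, ref_set


# ---------------------------------------------------------------------------
# canonical study constructions
# ---------------------------------------------------------------------------

def make_disjoint_substrate(axis: AxisSpec = AxisSpec()) -> Spectrum:
    """A substrate whose bands avoid every blood band (absence-test control)."""
    return make_reference("disjoint_control", axis)


def make_tuning_set(n: int = 40, nu: float = 1.0, fwhm: float = 50.0,
                    seed: int = 0, axis: AxisSpec = AxisSpec()) -> SpectrumSet:
    """Replicate set for the Savitzky–Golay tuning study.

    Emulates a mapped stain measurement: one broad-banded spectrum (blood
    band positions, ~50 cm⁻¹ envelopes as in condensed-phase spectra of
    stains on fabric) replicated ``n`` times with additive uniform noise.
    The default amplitude ν = 1.0 relative to the mean intensity puts the
    mean spectral signal-to-noise near 11 dB, of the order reported for
    mapped stain spectra (a few dB mean, tens of dB at band maxima).
    """
    centers = (1658.0, 1449.0, 1340.0, 1090.0, 1003.0, 856.0, 754.0, 623.0)
    base = make_reference("custom", axis, [PeakModel(c, fwhm=fwhm) for c in centers])
    scale = float(np.mean(base.intensity))
    rng = np.random.default_rng(seed)
    nm = NoiseModel(nu)
    reps = [add_noise(base.with_intensity(base.intensity, f"rep_{i:03d}"), nm, scale, rng=rng)
            for i in range(n)]
    return SpectrumSet(reps, "tuning-replicates",
                       {"nu": nu, "fwhm": fwhm, "seed": seed})
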