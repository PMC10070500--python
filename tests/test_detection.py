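"""Absence testing, residual extraction/classification, PCA screen."""

import numpy as np
import pytest

from ramanstains.detection import (
    absence_test,
    classify_residual,
    critical_value,
    pca_screen,
    reverse_rsc_residual,
    z_score,
)
from ramanstains.errors import (
    DegenerateSpectrumError,
    EmptyInputError,
    ParameterError,
)
from ramanstains.preprocess import preprocess_set
from ramanstains.rsc import RestoredVF
from ramanstains.spectra import Spectrum, SpectrumSet
from ramanstains.synthdata import DatasetConfig, make_dataset, make_reference


def vf_with(mu, sigma):
    return RestoredVF(values=np.array([mu]), mu=mu, sigma=sigma,
                      density=(np.array([0.0, 1.0]), np.array([1.0])))


class TestZScore:
    @pytest.mark.parametrize(
        "z,printed,places",
        [(0.03, 0.976, 3), (0.54, 0.59, 2), (2.7, 0.007, 3)],
    )
    def test_two_sided_mapping_reproduces_worked_examples(self, z, printed, places):
        got_z, got_p = z_score(vf_with(-z, 1.0))
        assert got_z == pytest.approx(z)
        assert round(got_p, places) == printed

    def test_extreme_score_gives_negligible_probability(self):
        _, p = z_score(vf_with(-6.6, 1.0))
        assert p < 1e-4

    def test_zero_mean_gives_certainty_of_absence(self):
        z, p = z_score(vf_with(0.0, 0.5))
        assert z == 0.0 and p == 1.0

    def test_p_strictly_decreasing_in_abs_z(self):
        ps = [z_score(vf_with(-z, 1.0))[1] for z in np.linspace(0, 5, 21)]
        assert np.all(np.diff(ps) < 0)

    def test_p_at_1_96_is_five_percent(self):
        _, p = z_score(vf_with(-1.96, 1.0))
        assert p == pytest.approx(0.05, abs=1e-3)

    def test_degenerate_sigma_rejected(self):
        with pytest.raises(DegenerateSpectrumError):
            z_score(vf_with(0.1, 0.0))


class TestCriticalValue:
    def test_95_percent_two_sided(self):
        assert round(critical_value(0.95), 2) == 1.96

    def test_invalid_level_rejected(self):
        with pytest.raises(ParameterError):
            critical_value(1.5)


class TestAbsenceTest:
    def test_stains_with_target_reject_absence(self):
        cfg = DatasetConfig(substrate="disjoint_control", n=5, c_mean=0.5,
                            c_sd=0.02, nu=0.02, seed=2)
        stains, _, refs = make_dataset(cfg)
        rep = absence_test(preprocess_set(stains), preprocess_set(refs), "rsc")
        assert rep.absence_rejected
        assert abs(rep.z) > 1.96

    def test_pure_substrate_does_not_reject_absence(self):
        cfg = DatasetConfig(substrate="disjoint_control", n=5, c_mean=0.5,
                            c_sd=0.02, nu=0.02, seed=2)
        _, pures, refs = make_dataset(cfg)
        rep = absence_test(preprocess_set(pures), preprocess_set(refs), "rsc")
        assert not rep.absence_rejected

    def test_unknown_method_rejected(self, blood):
        ss = SpectrumSet([blood])
        with pytest.raises(ParameterError):
            absence_test(ss, ss, method="pls")


class TestReverseResidual:
    def test_noiseless_stain_residual_is_the_biofluid(self, blood, denim):
        stain = Spectrum(blood.axis,
                         0.7 * denim.intensity + 0.3 * blood.intensity, "stain")
        rep = reverse_rsc_residual(stain, denim)
        corr = np.corrcoef(rep.residual.intensity, blood.intensity)[0, 1]
        assert corr > 0.999
        assert rep.substrate_weight == pytest.approx(0.7, abs=0.01)

    def test_pure_substrate_leaves_negligible_residual(self, denim):
        rep = reverse_rsc_residual(
            denim.with_intensity(denim.intensity, "pure"), denim)
        assert np.linalg.norm(rep.residual.intensity) < 0.01 * np.linalg.norm(
            denim.intensity)

    def test_noisy_stain_residual_classifies_as_blood(self, blood):
        cfg = DatasetConfig(substrate="denim", n=3, c_mean=0.4, c_sd=0.0,
                            nu=0.02, seed=5)
        stains, pures, _ = make_dataset(cfg)
        library = SpectrumSet([
            blood.with_intensity(blood.intensity, "blood/ref"),
            make_reference("semen").with_intensity(
                make_reference("semen").intensity, "semen/ref"),
        ])
        rep = reverse_rsc_residual(stains[0], pures[0])
        cls = classify_residual(rep.normalized, library)
        assert cls.best_class == "blood"


class TestClassifyResidual:
    def test_library_member_identity(self, blood, denim):
        lib = SpectrumSet([blood.with_intensity(blood.intensity, "blood/0"),
                           denim.with_intensity(denim.intensity, "denim/0")])
        rep = classify_residual(blood, lib)
        assert rep.best_class == "blood"
        assert rep.best_r == 0.0

    def test_blood_like_residual_separates_from_semen_class(self, blood):
        semen = make_reference("semen")
        lib = SpectrumSet(
            [blood.with_intensity(blood.intensity, f"blood/{i}") for i in range(3)]
            + [semen.with_intensity(semen.intensity, f"semen/{i}") for i in range(3)]
        )
        noisy = blood.with_intensity(blood.intensity * 1.001, "residual")
        rep = classify_residual(noisy, lib)
        assert max(rep.r_by_class["blood"]) < min(rep.r_by_class["semen"])

    def test_empty_library_rejected(self):
        with pytest.raises(EmptyInputError):
            SpectrumSet([])


class TestPcaScreen:
    def test_distinct_groups_fully_separate(self, blood, denim, grid):
        rng = np.random.default_rng(0)
        stains = SpectrumSet([blood.with_intensity(
            blood.intensity + 1e-9 * rng.normal(size=grid.size), f"s{i}")
            for i in range(4)])
        pures = SpectrumSet([denim.with_intensity(
            denim.intensity + 1e-9 * rng.normal(size=grid.size), f"p{i}")
            for i in range(4)])
        rep = pca_screen(stains, pures)
        assert rep.separation > 0.9
        assert rep.separated

    def test_same_spectra_in_both_groups_do_not_separate(self, denim, grid):
        rng = np.random.default_rng(1)
        def jig(label):
            return denim.with_intensity(
                denim.intensity + 1e-9 * rng.normal(size=grid.size), label)
        stains = SpectrumSet([jig(f"s{i}") for i in range(4)])
        pures = SpectrumSet([jig(f"p{i}") for i in range(4)])
        rep = pca_screen(stains, pures)
        assert abs(rep.separation) < 0.25
        assert not rep.separated

    def test_denim_overlaps_more_than_blue_polyester(self):
        """At a low stain fraction the strongly scattering denim masks the
        target more than blue polyester does (mean over three seeds)."""
        seps = {}
        for sub in ("denim", "blue_polyester"):
            vals = []
            for seed in (0, 1, 2):
                cfg = DatasetConfig(substrate=sub, n=8, c_mean=0.2, c_sd=0.02,
                                    nu=0.05, seed=seed)
                stains, pures, _ = make_dataset(cfg)
                rep = pca_screen(preprocess_set(stains), preprocess_set(pures))
                vals.append(rep.separation)
            seps[sub] = float(np.mean(vals))
        assert seps["denim"] < seps["blue_polyester"]

    def test_too_few_spectra_rejected(self, blood):
        ss = SpectrumSet([blood])
        with pytest.raises(ParameterError):
            pca_screen(ss, ss)
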