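import json

import numpy as np
import pytest

from otnmr import (
    ComponentLibrary,
    DeconvolutionConfig,
    Distortion,
    GridSpec,
    MixtureScenario,
    PeakSpec,
    Spectrum,
    SpectrumError,
    absolute_concentrations,
    deconvolve,
    deconvolve_oracle,
    deconvolve_unpenalized,
    estimation_errors,
    make_mixture,
    parameter_sweep,
    result_to_dict,
    result_to_json,
    signal_to_molar,
    sum_spectra,
)


def lorentz_pair_library(seed=0, n=400):
    """Two disjoint Lorentzian components on a shared grid."""
    grid = GridSpec(0.0, 10.0, n)
    from otnmr import generate_component

    c1 = generate_component([PeakSpec(2.0, 0.05), PeakSpec(2.6, 0.05)], grid)
    c2 = generate_component([PeakSpec(7.0, 0.05), PeakSpec(7.8, 0.05)], grid)
    return ComponentLibrary((c1, c2), names=("a", "b"))


class TestDeconvolve:
    def test_exact_mixture_recovered_with_zero_objective(self):
        lib = lorentz_pair_library()
        mix = sum_spectra(lib, (0.3, 0.7))
        res = deconvolve(mix, lib)
        np.testing.assert_allclose(res.p, [0.3, 0.7], atol=1e-8)
        assert res.p0 == pytest.approx(0.0, abs=1e-8)
        assert res.p0_prime == pytest.approx(0.0, abs=1e-8)
        assert res.objective == pytest.approx(0.0, abs=1e-9)

    def test_far_contaminant_removed_to_omega(self, delta):
        # removal at 0.25/unit beats matching at 4.0/unit
        mix = Spectrum([1.0, 5.0], [0.8, 0.2], normalized=True)
        lib = ComponentLibrary((delta(1.0),))
        res = deconvolve(mix, lib)
        assert res.p[0] == pytest.approx(0.8, abs=1e-9)
        assert res.p0 == pytest.approx(0.2, abs=1e-9)
        assert res.p0_prime == pytest.approx(0.0, abs=1e-9)
        assert res.objective == pytest.approx(0.05, abs=1e-9)
        np.testing.assert_allclose(res.proportions, [1.0])

    def test_library_excess_routed_to_xi(self, delta):
        mix = delta(1.0)
        lib = ComponentLibrary((Spectrum([1.0, 5.0], [0.5, 0.5], normalized=True),))
        res = deconvolve(mix, lib)
        assert res.p[0] == pytest.approx(1.0, abs=1e-9)
        assert res.p0 == pytest.approx(0.0, abs=1e-9)
        assert res.p0_prime == pytest.approx(0.5, abs=1e-9)
        assert res.objective == pytest.approx(0.11, abs=1e-9)

    def test_unnormalized_mixture_rejected(self, delta):
        lib = ComponentLibrary((delta(1.0),))
        with pytest.raises(SpectrumError):
            deconvolve(Spectrum([1.0], [2.0]), lib)

    def test_result_invariants_on_random_instances(self, random_instance):
        rng = np.random.default_rng(11)
        for _ in range(10):
            mixture, library = random_instance(rng)
            res = deconvolve(mixture, library)
            assert (res.p >= -1e-9).all()
            assert 0 - 1e-9 <= res.p0 <= 1 + 1e-9
            assert 0 - 1e-9 <= res.p0_prime <= 1 + 1e-9
            assert res.p.sum() + res.p0 == pytest.approx(1.0, abs=1e-8)
            if res.p.sum() > 0:
                assert res.proportions.sum() == pytest.approx(1.0, abs=1e-8)
            km, kc = res.config.kappa_mixture, res.config.kappa_components
            assert res.plan.cost(km, kc) == pytest.approx(res.objective, abs=1e-7)

    def test_plan_vortex_mass_matches_p0(self, delta):
        mix = Spectrum([1.0, 5.0], [0.8, 0.2], normalized=True)
        res = deconvolve(mix, ComponentLibrary((delta(1.0),)))
        to_omega, from_xi = res.plan.vortex_mass()
        assert to_omega == pytest.approx(res.p0, abs=1e-9)
        assert from_xi == pytest.approx(res.p0_prime, abs=1e-9)

    def test_matches_dense_oracle(self, random_instance):
        rng = np.random.default_rng(12)
        worst = 0.0
        for _ in range(15):
            mixture, library = random_instance(rng, k_max=3, n_max=8)
            obj = deconvolve(mixture, library).objective
            oracle_obj, _ = deconvolve_oracle(mixture, library)
            worst = max(worst, abs(obj - oracle_obj))
        assert worst <= 1e-6

    def test_monotone_p0_in_kappa_mixture(self, random_instance):
        rng = np.random.default_rng(13)
        mixture, library = random_instance(rng, k_max=2, n_max=6)
        p0s = [
            deconvolve(mixture, library, DeconvolutionConfig(kappa_mixture=km)).p0
            for km in (0.05, 0.2, 0.8, 3.0)
        ]
        for lo, hi in zip(p0s, p0s[1:]):
            assert hi <= lo + 1e-8

    def test_monotone_p0prime_in_kappa_components(self, random_instance):
        rng = np.random.default_rng(14)
        mixture, library = random_instance(rng, k_max=2, n_max=6)
        vals = [
            deconvolve(
                mixture, library, DeconvolutionConfig(kappa_components=kc)
            ).p0_prime
            for kc in (0.05, 0.2, 0.8, 3.0)
        ]
        for lo, hi in zip(vals, vals[1:]):
            assert hi <= lo + 1e-8

    def test_max_grid_coarsening_runs(self):
        lib = lorentz_pair_library(n=800)
        mix = sum_spectra(lib, (0.4, 0.6))
        res = deconvolve(mix, lib, DeconvolutionConfig(max_grid=200))
        np.testing.assert_allclose(res.proportions, [0.4, 0.6], atol=0.02)


class TestUnpenalized:
    def test_exact_mixture(self):
        lib = lorentz_pair_library()
        mix = sum_spectra(lib, (0.3, 0.7))
        res = deconvolve_unpenalized(mix, lib)
        np.testing.assert_allclose(res.p, [0.3, 0.7], atol=1e-8)
        assert res.objective == pytest.approx(0.0, abs=1e-9)

    def test_single_component_forced_to_one(self, delta, random_spectrum):
        mix = random_spectrum(np.random.default_rng(15))
        res = deconvolve_unpenalized(mix, ComponentLibrary((delta(3.0),)))
        assert res.p[0] == pytest.approx(1.0, abs=1e-10)

    def test_equals_deconvolve_in_large_kappa_limit(self, random_instance):
        rng = np.random.default_rng(16)
        for _ in range(5):
            mixture, library = random_instance(rng, k_max=3, n_max=7)
            plain = deconvolve_unpenalized(mixture, library)
            capped = deconvolve(
                mixture,
                library,
                DeconvolutionConfig(kappa_mixture=1e6, kappa_components=1e6),
            )
            assert capped.p0 == pytest.approx(0.0, abs=1e-9)
            assert capped.p0_prime == pytest.approx(0.0, abs=1e-9)
            assert capped.objective == pytest.approx(plain.objective, abs=1e-6)


class TestErrorMetrics:
    def test_perfect_estimate(self):
        e = estimation_errors([0.5, 0.5], [0.5, 0.5])
        assert e.l1_error == 0.0
        assert e.avre == 0.0
        np.testing.assert_array_equal(e.re, [0.0, 0.0])

    def test_published_low_resolution_example(self):
        e = estimation_errors([0.11, 0.75, 0.06, 0.08], [0.11, 0.73, 0.09, 0.08])
        assert e.avre == pytest.approx(9.0, abs=0.05)
        assert e.re[2] == pytest.approx(33.3, abs=0.05)

    def test_published_lineshape_example(self):
        e = estimation_errors(
            [0.32, 0.21, 0.13, 0.20, 0.14], [0.30, 0.22, 0.13, 0.20, 0.15]
        )
        assert e.avre == pytest.approx(3.6, abs=0.05)

    def test_zero_truth_rejected(self):
        with pytest.raises(ValueError):
            estimation_errors([0.5, 0.5], [1.0, 0.0])

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            estimation_errors([0.5], [0.5, 0.5])


class TestConversions:
    def test_equal_protons_identity(self):
        np.testing.assert_allclose(signal_to_molar([0.3, 0.7], [5, 5]), [0.3, 0.7])

    @pytest.mark.parametrize(
        "signal,protons,expected",
        [([0.5, 0.5], [1, 4], [0.8, 0.2]), ([0.4, 0.6], [2, 3], [0.5, 0.5])],
    )
    def test_proton_weighting(self, signal, protons, expected):
        np.testing.assert_allclose(signal_to_molar(signal, protons), expected)

    def test_invalid_proton_count(self):
        with pytest.raises(ValueError):
            signal_to_molar([1.0], [0])

    def _result_with_p(self, p):
        from otnmr.transport import TransportPlan
        from otnmr.deconv import DeconvolutionResult

        p = np.asarray(p, dtype=float)
        return DeconvolutionResult(
            p=p, p0=1 - p.sum(), p0_prime=0.0, proportions=p / p.sum(),
            objective=0.0, plan=TransportPlan((), 0.0), status="optimal",
        )

    @pytest.mark.parametrize(
        "p,ref,conc,protons,expected_first",
        [
            ([0.5, 0.5], 1, 10.0, [1, 1], 10.0),
            ([0.25, 0.75], 1, 3.0, [1, 1], 1.0),
            ([0.5, 0.5], 1, 4.0, [2, 1], 2.0),
        ],
    )
    def test_external_standard(self, p, ref, conc, protons, expected_first):
        res = self._result_with_p(p)
        c = absolute_concentrations(res, ref, conc, protons)
        assert c[0] == pytest.approx(expected_first)
        assert c[ref] == pytest.approx(conc)

    def test_undetected_reference_rejected(self):
        res = self._result_with_p([1.0, 0.0])
        with pytest.raises(ValueError):
            absolute_concentrations(res, 1, 1.0, [1, 1])


class TestParameterSweep:
    def test_grid_shape(self):
        lib = lorentz_pair_library(n=200)
        mix = sum_spectra(lib, (0.3, 0.7))
        frame = parameter_sweep(mix, lib, [0.1, 0.25, 0.5], [0.1, 0.22, 0.5])
        assert len(frame) == 9
        assert {"kappa_mixture", "kappa_components", "p0", "p0_prime", "objective"} <= set(
            frame.columns
        )

    def test_noiseless_mixture_zero_error_everywhere(self):
        lib = lorentz_pair_library(n=200)
        mix = sum_spectra(lib, (0.3, 0.7))
        frame = parameter_sweep(
            mix, lib, [0.05, 0.25], [0.05, 0.22], p_true=(0.3, 0.7)
        )
        assert (frame["l1_error"].abs() < 1e-7).all()

    def test_p0_nonincreasing_along_kappa_mixture(self):
        scenario = MixtureScenario(
            component_peaklists=(
                (PeakSpec(2.0, 0.05, shape="gaussian"),),
                (PeakSpec(7.0, 0.05, shape="gaussian"),),
            ),
            proportions=(0.5, 0.5),
            grid=GridSpec(0.0, 10.0, 400),
            distortions=(
                Distortion(
                    "contaminant",
                    peaks=(PeakSpec(4.5, 0.05, shape="gaussian"),),
                    fraction=0.2,
                ),
            ),
        )
        mix, lib, _, _ = make_mixture(scenario)
        frame = parameter_sweep(mix, lib, [0.05, 0.25, 1.0, 5.0], [0.22])
        p0 = frame.sort_values("kappa_mixture")["p0"].to_numpy()
        assert (np.diff(p0) <= 1e-8).all()

    def test_empty_grid_rejected(self):
        lib = lorentz_pair_library(n=100)
        mix = sum_spectra(lib, (0.5, 0.5))
        with pytest.raises(ValueError):
            parameter_sweep(mix, lib, [], [0.22])


class TestSerialization:
    def test_json_round_trip_fields(self, tmp_path, delta):
        mix = Spectrum([1.0, 5.0], [0.8, 0.2], normalized=True)
        res = deconvolve(mix, ComponentLibrary((delta(1.0),), names=("ref",)))
        path = tmp_path / "result.json"
        result_to_json(res, path, names=("ref",))
        data = json.loads(path.read_text())
        assert data["names"] == ["ref"]
        assert data["p0"] == pytest.approx(0.2, abs=1e-9)
        assert data["kappa_mixture"] == 0.25
        assert data["kappa_components"] == 0.22
        assert data["proportions"] == pytest.approx([1.0])

    def test_dict_contains_objective_and_status(self, delta):
        mix = delta(1.0)
        res = deconvolve(mix, ComponentLibrary((delta(1.0),)))
        d = result_to_dict(res)
        assert d["objective"] == pytest.approx(0.0, abs=1e-9)
        assert isinstance(d["status"], str)
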