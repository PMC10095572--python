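"""Synthetic cohort generator: determinism, validation, analytic oracles."""

import dataclasses

import numpy as np
import pytest

from alphaerd.cohort import (
    AgeLinearFactor,
    CohortSpec,
    SpecValidationError,
    SubjectProfile,
    expected_band_components,
    expected_band_power,
    expected_erd,
    generate_cohort,
    generate_profiles,
    sample_erd_table,
    subject_effects,
    synth_recording,
    synth_signal,
)
from alphaerd.eeg_io import EEGRecording
from alphaerd.spectral import ALPHA1, ALPHA2, band_power, mean_spectrum, segment


class TestProfiles:
    def test_study_group_sizes(self):
        profiles = generate_profiles(CohortSpec(seed=1))
        assert len(profiles) == 94
        groups = [p.clu_group for p in profiles]
        assert groups.count("CC") == 34 and groups.count("CT&TT") == 60

    def test_inclusion_criteria(self):
        for p in generate_profiles(CohortSpec(seed=3)):
            assert 19 <= p.age <= 80
            assert p.mmse >= 28 and p.cdr == 0
            assert p.sex in {"m", "f"} and p.apoe_group in {"E4+", "E4-"}

    def test_minimal_cohort(self):
        spec = CohortSpec(n_per_genotype_group=(1, 0), artifact_epoch_rate=0.0,
                          duration_per_condition=8.0, seed=5)
        profiles, pairs = generate_cohort(spec)
        assert len(profiles) == 1 and len(pairs) == 1
        rest, task = pairs[0]
        assert rest.condition == "rest" and task.condition == "task"
        assert rest.samples.shape == (16, 8 * 256)


class TestValidation:
    @pytest.mark.parametrize(
        "kwargs, field",
        [
            ({"artifact_epoch_rate": 0.5}, "artifact_epoch_rate"),
            ({"age_range": (10, 80)}, "age_range"),
            ({"n_per_genotype_group": (0, 0)}, "n_per_genotype_group"),
            ({"task_attenuation_alpha2_ct_tt": 1.4}, "task_attenuation_alpha2_ct_tt"),
            ({"task_attenuation_alpha2_cc": AgeLinearFactor(0.5, -0.01)},
             "task_attenuation_alpha2_cc"),
            ({"left_bias": 0.0}, "left_bias"),
            ({"white_noise_sd": -1.0}, "white_noise_sd"),
        ],
    )
    def test_invalid_spec_names_field(self, kwargs, field):
        with pytest.raises(SpecValidationError, match=field):
            CohortSpec(**kwargs).validate()

    def test_unknown_channel(self, tiny_spec):
        profile = generate_profiles(tiny_spec)[0]
        with pytest.raises(ValueError, match="Cz"):
            synth_signal(profile, "rest", tiny_spec, "Cz")

    def test_yaml_round_trip(self, tmp_path, tiny_spec):
        path = tmp_path / "spec.yaml"
        tiny_spec.to_yaml(path)
        assert CohortSpec.from_yaml(path) == tiny_spec


class TestDeterminism:
    def test_bit_identical_regeneration(self, tiny_spec):
        p1, r1 = generate_cohort(tiny_spec)
        p2, r2 = generate_cohort(tiny_spec)
        assert p1 == p2
        for (a_rest, a_task), (b_rest, b_task) in zip(r1, r2):
            assert np.array_equal(a_rest.samples, b_rest.samples)
            assert np.array_equal(a_task.samples, b_task.samples)

    def test_seed_changes_output(self, tiny_spec):
        other = dataclasses.replace(tiny_spec, seed=tiny_spec.seed + 1)
        a = generate_cohort(tiny_spec)[1][0][0].samples
        b = generate_cohort(other)[1][0][0].samples
        assert not np.array_equal(a, b)

    def test_recording_is_stack_of_channel_signals(self, tiny_spec):
        profile = generate_profiles(tiny_spec)[0]
        rec = synth_recording(profile, "task", tiny_spec)
        one = synth_signal(profile, "task", tiny_spec, "F3")
        assert np.array_equal(rec.channel("F3"), one)


class TestOracle:
    """Closed-form expected band power against empirical spectra."""

    def test_pure_oscillator_ratio(self):
        # single oscillator, background and noise off:
        # task/rest expected power ratio is exactly a²
        spec = CohortSpec(
            n_per_genotype_group=(0, 1), background_1f_scale=0.0, white_noise_sd=0.0,
            alpha1_amp=0.0, amp_jitter_sigma=0.0, attenuation_jitter_sd=0.0,
            left_bias=1.0, seed=2,
        )
        p = generate_profiles(spec)[0]
        a = spec.task_attenuation_alpha2_ct_tt
        rest = expected_band_power(spec, p, "rest", ALPHA2)
        task = expected_band_power(spec, p, "task", ALPHA2)
        assert task / rest == pytest.approx(a**2, rel=1e-12)

    # right-hemisphere/non-frontal channels share the F4 expectation (no left bias);
    # averaging across them shrinks the Monte Carlo error of a fixed-seed check
    _IID_CHANNELS = ("O2", "P4", "C4", "F4", "T6", "FP2", "T4", "F8")

    def _mean_band_power(self, spec, profile, cond, band, channels):
        emp = []
        for ch in channels:
            x = synth_signal(profile, cond, spec, ch)
            rec = EEGRecording(profile.subject_id, cond, (ch,), 256.0, x[None, :])
            freqs, ms = mean_spectrum(segment(rec))
            emp.append(band_power(freqs, ms[0], band))
        return float(np.mean(emp))

    def test_convergence_600s(self, clean_spec):
        profile = generate_profiles(clean_spec)[0]
        for cond in ("rest", "task"):
            for band in (ALPHA1, ALPHA2):
                emp = self._mean_band_power(clean_spec, profile, cond, band,
                                            self._IID_CHANNELS)
                exp = expected_band_power(clean_spec, profile, cond, band, "F4")
                assert emp == pytest.approx(exp, rel=0.05)

    def test_convergence_3600s(self, clean_spec):
        spec = dataclasses.replace(clean_spec, duration_per_condition=3600.0)
        profile = generate_profiles(spec)[0]
        for band in (ALPHA1, ALPHA2):
            emp = self._mean_band_power(spec, profile, "rest", band,
                                        self._IID_CHANNELS[:4])
            exp = expected_band_power(spec, profile, "rest", band, "F4")
            assert emp == pytest.approx(exp, rel=0.02)

    def test_erd_closed_form(self, clean_spec):
        # single oscillator: ERD% = 100(a²−1)(1−b), b = in-band background share at rest
        spec = dataclasses.replace(clean_spec, alpha1_amp=0.0, left_bias=1.0)
        p = generate_profiles(spec)[0]
        parts = expected_band_components(spec, p, "rest", ALPHA2, "F4")
        b = parts["background"] / sum(parts.values())
        a = subject_effects(spec, p).att_alpha2
        assert expected_erd(spec, p, ALPHA2, "Fd") == pytest.approx(
            100.0 * (a**2 - 1.0) * (1.0 - b), rel=1e-9
        )

    def test_cc_erd_declines_with_age(self):
        # ground-truth upper-alpha ERD is strictly monotone in age for CC carriers
        spec = CohortSpec(n_per_genotype_group=(10, 0), amp_jitter_sigma=0.0,
                          attenuation_jitter_sd=0.0, seed=4)
        erds = []
        for i, age in enumerate(range(20, 80, 6)):
            profile = SubjectProfile(subject_id=f"S{i:03d}", clu_genotype="CC",
                                     apoe_group="E4-", age=age, sex="f", lft_words=45)
            erds.append(expected_erd(spec, profile, ALPHA2, "Fd"))
        assert np.all(np.diff(erds) < 0)


class TestFastPath:
    def test_shape_and_determinism(self):
        spec = CohortSpec(n_per_genotype_group=(5, 7), seed=9)
        meta1, erd1 = sample_erd_table(spec)
        meta2, erd2 = sample_erd_table(spec)
        assert len(meta1) == 12 and len(erd1) == 48
        assert erd1.equals(erd2) and meta1.equals(meta2)

    def test_group_means_track_ground_truth(self):
        # large fast cohort: group-mean sampled ERD within 3 SE of the analytic mean
        spec = CohortSpec(n_per_genotype_group=(0, 120), amp_jitter_sigma=0.0,
                          attenuation_jitter_sd=0.0, artifact_epoch_rate=0.0, seed=12)
        meta, erd = sample_erd_table(spec)
        profiles = generate_profiles(spec)
        truth = np.mean([expected_erd(spec, p, ALPHA2, "Fd") for p in profiles])
        sub = erd[(erd.band == "alpha2") & (erd.region == "Fd")]["erd_percent"]
        se = sub.std(ddof=1) / np.sqrt(len(sub))
        assert abs(sub.mean() - truth) < 3 * se
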