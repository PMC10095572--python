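"""Synthetic EEG cohort generator with analytic ground truth.

The generator emulates a two-condition (rest / covert verbal-fluency task)
quantitative-EEG study of nondemented adults stratified by *CLU* rs11136000
genotype.  Each channel of each recording is the sum of four independent
Gaussian processes:

* white measurement noise of standard deviation ``white_noise_sd``;
* a 1/f ("pink") background synthesized in the frequency domain with one-sided
  PSD ``background_1f_scale / f`` above ``background_f_min`` — its expected
  power in any band [lo, hi) is exactly ``scale·ln(hi/lo)``;
* two narrow-band alpha oscillators (lower alpha 8-11 Hz, upper alpha
  11-13 Hz) built by zero-phase band-pass filtering white noise with a
  4th-order Butterworth filter and scaling to a target RMS amplitude — their
  expected power in any band follows from the filter's squared magnitude
  response, so every downstream band-power and desynchronization estimate has
  a closed-form target.

Under the task condition the oscillator amplitudes are multiplied by
genotype- and age-dependent attenuation factors (with an extra left-hemisphere
bias on F3/FP1), producing event-related desynchronization
ERD% = 100·(a²−1)·(1−b) in expectation, where ``a`` is the amplitude factor
and ``b`` the in-band background power share.  High-amplitude artifact
transients are injected into random 4-s epochs to exercise artifact rejection.

Determinism: the same (spec, seed) always yields bit-identical cohorts, and
per-subject seeding makes streaming generation equal to materialized
generation.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Iterator

import numpy as np
import pandas as pd
import yaml
from scipy import signal as sps
from scipy.integrate import cumulative_trapezoid

from .eeg_io import EEGRecording
from .montage import CHANNELS_16, LEFT_FRONTAL
from .spectral import ALPHA1, ALPHA2, Band

__all__ = [
    "AgeLinearFactor",
    "CohortSpec",
    "SubjectProfile",
    "SubjectEffects",
    "SpecValidationError",
    "generate_profiles",
    "generate_cohort",
    "iter_cohort",
    "subject_effects",
    "synth_recording",
    "synth_signal",
    "expected_band_power",
    "expected_region_power",
    "expected_erd",
    "sample_erd_table",
    "profiles_to_frame",
]

CONDITIONS = ("rest", "task")
EPOCH_LEN_S = 4.0


class SpecValidationError(ValueError):
    """A CohortSpec field violates its contract; the message names the field."""


@dataclass(frozen=True)
class AgeLinearFactor:
    """Amplitude attenuation factor linear in age: a(age) = intercept + slope·age."""

    intercept: float
    slope_per_year: float

    def __call__(self, age: float) -> float:
        return self.intercept + self.slope_per_year * age


@dataclass(frozen=True)
class SubjectProfile:
    """Demographics and covariates of one generated subject."""

    subject_id: str
    clu_genotype: str  # CC / CT / TT
    apoe_group: str  # E4+ / E4-
    age: int
    sex: str  # m / f
    lft_words: int
    mmse: int = 29
    cdr: int = 0

    @property
    def clu_group(self) -> str:
        return "CC" if self.clu_genotype == "CC" else "CT&TT"


@dataclass(frozen=True)
class CohortSpec:
    """All simulation parameters; the defaults are the stated study conditions."""

    n_per_genotype_group: tuple[int, int] = (34, 60)  # (CC, CT&TT)
    age_range: tuple[int, int] = (19, 80)
    seed: int = 0
    sampling_rate: float = 256.0
    duration_per_condition: float = 180.0
    channel_set: tuple[str, ...] = CHANNELS_16
    # background + noise (µV / µV² scale)
    background_1f_scale: float = 8.0  # one-sided PSD = scale/f µV²/Hz
    background_f_min: float = 0.5
    white_noise_sd: float = 1.5
    # rest oscillator RMS amplitudes (µV) with per-subject lognormal jitter
    alpha1_amp: float = 5.0
    alpha2_amp: float = 3.5
    amp_jitter_sigma: float = 0.2
    # task attenuation (amplitude factors); CC upper-alpha factor declines with age
    task_attenuation_alpha2_cc: AgeLinearFactor = AgeLinearFactor(1.02, -0.004)
    task_attenuation_alpha2_ct_tt: float = 0.99
    task_attenuation_alpha1: dict = field(
        default_factory=lambda: {"CC": 0.98, "CT&TT": 0.92}
    )
    attenuation_jitter_sd: float = 0.1
    left_bias: float = 0.95  # extra attenuation on F3/FP1 during task
    # artifacts
    artifact_epoch_rate: float = 0.1
    artifact_amplitude: float = 300.0
    # demographics
    apoe_e4_prob: float = 0.37
    lft_mean: float = 47.3
    lft_sd: float = 14.0

    # -- validation ---------------------------------------------------------

    def validate(self) -> None:
        def fail(name: str, why: str) -> None:
            raise SpecValidationError(f"{name}: {why}")

        n_cc, n_ct = self.n_per_genotype_group
        if n_cc < 0 or n_ct < 0 or n_cc + n_ct < 1:
            fail("n_per_genotype_group", "needs at least one subject in total")
        lo, hi = self.age_range
        if not (19 <= lo <= hi <= 80):
            fail("age_range", "must lie within [19, 80]")
        if self.sampling_rate <= 0:
            fail("sampling_rate", "must be positive")
        if self.duration_per_condition < EPOCH_LEN_S:
            fail("duration_per_condition", "shorter than one epoch")
        if not 0.0 <= self.artifact_epoch_rate <= 0.2:
            fail("artifact_epoch_rate", "must be in [0, 0.2]")
        n_epochs = int(self.duration_per_condition // EPOCH_LEN_S)
        if n_epochs * (1.0 - self.artifact_epoch_rate) < 30 and n_epochs >= 30:
            fail("artifact_epoch_rate", "expected retained epochs per condition < 30")
        for name in ("background_1f_scale", "white_noise_sd", "alpha1_amp", "alpha2_amp"):
            if getattr(self, name) < 0:
                fail(name, "must be nonnegative")
        for age in self.age_range:
            a = self.task_attenuation_alpha2_cc(age)
            if not 0.0 < a <= 1.0:
                fail("task_attenuation_alpha2_cc", f"factor {a:.3f} at age {age} outside (0, 1]")
        if not 0.0 < self.task_attenuation_alpha2_ct_tt <= 1.0:
            fail("task_attenuation_alpha2_ct_tt", "must be in (0, 1]")
        for grp, a in self.task_attenuation_alpha1.items():
            if not 0.0 < a <= 1.0:
                fail("task_attenuation_alpha1", f"factor for {grp} outside (0, 1]")
        if not 0.0 < self.left_bias <= 1.0:
            fail("left_bias", "must be in (0, 1]")

    # -- YAML round trip ----------------------------------------------------

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["task_attenuation_alpha2_cc"] = dataclasses.asdict(self.task_attenuation_alpha2_cc)
        d["n_per_genotype_group"] = list(self.n_per_genotype_group)
        d["age_range"] = list(self.age_range)
        d["channel_set"] = list(self.channel_set)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "CohortSpec":
        d = dict(d)
        if "task_attenuation_alpha2_cc" in d and isinstance(
            d["task_attenuation_alpha2_cc"], dict
        ):
            d["task_attenuation_alpha2_cc"] = AgeLinearFactor(**d["task_attenuation_alpha2_cc"])
        for key in ("n_per_genotype_group", "age_range", "channel_set"):
            if key in d:
                d[key] = tuple(d[key])
        unknown = set(d) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise SpecValidationError(f"unknown field(s): {', '.join(sorted(unknown))}")
        return cls(**d)

    def to_yaml(self, path) -> None:
        from pathlib import Path

        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def from_yaml(cls, path) -> "CohortSpec":
        from pathlib import Path

        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


@dataclass(frozen=True)
class SubjectEffects:
    """Realized per-subject generator parameters (rest amplitudes, attenuations)."""

    alpha1_amp: float
    alpha2_amp: float
    att_alpha1: float
    att_alpha2: float

    def attenuation(self, band_name: str, left: bool, left_bias: float) -> float:
        a = self.att_alpha1 if band_name == "alpha1" else self.att_alpha2
        if left:
            a = max(a * left_bias, 0.05)
        return a


# ---------------------------------------------------------------------------
# filter machinery (cached per band/rate)
# ---------------------------------------------------------------------------

_OSC_ORDER = 4
_GRID_N = 16385


@lru_cache(maxsize=16)
def _oscillator_filter(f_lo: float, f_hi: float, fs: float):
    """SOS band-pass plus the power-gain profile of forward-backward filtering.

    Returns (sos, unit_variance, band_integral) where ``unit_variance`` is the
    variance of filtfilt-filtered unit white noise and ``band_integral(a, b)``
    gives the fraction-weight integral of the power gain over [a, b).
    """
    sos = sps.butter(_OSC_ORDER, [f_lo, f_hi], btype="bandpass", output="sos", fs=fs)
    f = np.linspace(0.0, fs / 2.0, _GRID_N)
    _, h = sps.sosfreqz(sos, worN=f, fs=fs)
    gain = np.abs(h) ** 4  # filtfilt applies the filter twice
    cum = cumulative_trapezoid(gain, f, initial=0.0)
    total = float(cum[-1])
    unit_var = total * 2.0 / fs  # white noise PSD is 2/fs one-sided per unit variance

    def band_integral(a: float, b: float) -> float:
        lo, hi = np.interp([a, b], f, cum)
        return float(hi - lo) / total

    return sos, unit_var, band_integral


_PSD_GRID_M = 1 << 16  # fine PSD grid for the expected-periodogram computation


def _expected_epoch_spectrum(psd: np.ndarray, fs: float, n_epoch: int) -> np.ndarray:
    """Expected one-sided rectangular-window periodogram of a stationary process.

    ``psd`` is the one-sided model PSD sampled on ``rfftfreq(_PSD_GRID_M, 1/fs)``.
    The finite epoch convolves the true spectrum with the Fejér kernel; this is
    computed exactly through the autocovariance with the triangular (Bartlett)
    lag window, so the oracle carries the same spectral leakage as the
    estimator.  Normalization matches :func:`alphaerd.spectral.epoch_spectrum`
    (bins sum to the mean squared signal).
    """
    # autocovariance r(τ) = ∫ S(f) cos(2πfτΔt) df  (one-sided S)
    r = fs * np.fft.irfft(psd, _PSD_GRID_M)[:n_epoch] / 2.0
    tau = np.arange(n_epoch)
    c = (1.0 - tau / n_epoch) * r
    folded = c.copy()
    folded[1:] += c[1:][::-1]  # negative lags alias onto N−τ
    spec_two = np.fft.rfft(folded).real / n_epoch
    spec_one = spec_two.copy()
    if n_epoch % 2 == 0:
        spec_one[1:-1] *= 2.0
    else:
        spec_one[1:] *= 2.0
    return np.maximum(spec_one, 0.0)


@lru_cache(maxsize=64)
def _component_band_weights(
    component: str, f_lo: float, f_hi: float, fs: float, n_epoch: int,
    band_lo: float, band_hi: float,
) -> float:
    """Expected band power per unit component strength, leakage included.

    ``component`` is 'oscillator' (per unit amp², band-pass [f_lo, f_hi)),
    'background' (per unit 1/f scale, cutoff f_lo) or 'white' (per unit σ²).
    """
    f = np.fft.rfftfreq(_PSD_GRID_M, 1.0 / fs)
    if component == "oscillator":
        sos, unit_var, _ = _oscillator_filter(f_lo, f_hi, fs)
        _, h = sps.sosfreqz(sos, worN=f, fs=fs)
        psd = np.abs(h) ** 4 * (2.0 / fs) / unit_var  # integrates to 1
    elif component == "background":
        psd = np.zeros_like(f)
        mask = f >= f_lo
        psd[mask] = 1.0 / f[mask]
    elif component == "white":
        psd = np.full_like(f, 2.0 / fs)
    else:  # pragma: no cover
        raise ValueError(component)
    spec_one = _expected_epoch_spectrum(psd, fs, n_epoch)
    freqs = np.fft.rfftfreq(n_epoch, 1.0 / fs)
    return float(spec_one[(freqs >= band_lo) & (freqs < band_hi)].sum())


def _oscillator_band_fraction(
    osc_band: Band, target: Band, fs: float, n_epoch: int
) -> float:
    """Fraction of an oscillator's power the band-power estimator collects."""
    return _component_band_weights(
        "oscillator", osc_band.f_lo, osc_band.f_hi, fs, n_epoch, target.f_lo, target.f_hi
    )


def _background_band_power(spec: CohortSpec, target: Band, n_epoch: int) -> float:
    w = _component_band_weights(
        "background", spec.background_f_min, 0.0, spec.sampling_rate, n_epoch,
        target.f_lo, target.f_hi,
    )
    return spec.background_1f_scale * w


def _white_band_power(spec: CohortSpec, target: Band, n_epoch: int) -> float:
    w = _component_band_weights(
        "white", 0.0, 0.0, spec.sampling_rate, n_epoch, target.f_lo, target.f_hi
    )
    return spec.white_noise_sd**2 * w


# ---------------------------------------------------------------------------
# seeding
# ---------------------------------------------------------------------------

_PROFILE_STREAM, _EFFECT_STREAM, _SIGNAL_STREAM, _ARTIFACT_STREAM, _FAST_STREAM = range(5)


def _rng(spec_seed: int, *key: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(spec_seed), *map(int, key)]))


def _subject_index(profile: SubjectProfile) -> int:
    try:
        return int(profile.subject_id.lstrip("S"))
    except ValueError as exc:
        raise ValueError(
            f"subject_id {profile.subject_id!r} is not generator-issued (S<number>)"
        ) from exc


# ---------------------------------------------------------------------------
# generation
# ---------------------------------------------------------------------------

def generate_profiles(spec: CohortSpec) -> list[SubjectProfile]:
    """Draw the subject metadata table (deterministic in spec.seed)."""
    spec.validate()
    rng = _rng(spec.seed, _PROFILE_STREAM)
    n_cc, n_ct = spec.n_per_genotype_group
    genotypes = ["CC"] * n_cc + list(rng.choice(["CT", "TT"], size=n_ct, p=[2 / 3, 1 / 3]))
    profiles = []
    lo, hi = spec.age_range
    for i, gt in enumerate(genotypes):
        age = int(rng.integers(lo, hi + 1))
        profiles.append(
            SubjectProfile(
                subject_id=f"S{i:03d}",
                clu_genotype=gt,
                apoe_group="E4+" if rng.random() < spec.apoe_e4_prob else "E4-",
                age=age,
                sex="m" if rng.random() < 0.5 else "f",
                lft_words=int(max(5, round(rng.normal(spec.lft_mean, spec.lft_sd)))),
                mmse=int(rng.integers(28, 31)),
                cdr=0,
            )
        )
    return profiles


def subject_effects(spec: CohortSpec, profile: SubjectProfile) -> SubjectEffects:
    """Realized amplitudes and attenuation factors for one subject.

    Deterministic in (spec.seed, subject index), so signal synthesis and the
    analytic oracle always agree.  Attenuation jitter is clipped to
    [0.05, 1.25]: individual subjects may show mild synchronization.
    """
    rng = _rng(spec.seed, _EFFECT_STREAM, _subject_index(profile))
    a1_amp = spec.alpha1_amp * float(np.exp(rng.normal(0.0, spec.amp_jitter_sigma)))
    a2_amp = spec.alpha2_amp * float(np.exp(rng.normal(0.0, spec.amp_jitter_sigma)))
    if profile.clu_group == "CC":
        mean_a2 = spec.task_attenuation_alpha2_cc(profile.age)
    else:
        mean_a2 = spec.task_attenuation_alpha2_ct_tt
    mean_a1 = spec.task_attenuation_alpha1[profile.clu_group]
    jit = rng.normal(0.0, spec.attenuation_jitter_sd, size=2)
    att1 = float(np.clip(mean_a1 + jit[0], 0.05, 1.25))
    att2 = float(np.clip(mean_a2 + jit[1], 0.05, 1.25))
    return SubjectEffects(alpha1_amp=a1_amp, alpha2_amp=a2_amp, att_alpha1=att1, att_alpha2=att2)


def _one_over_f(spec: CohortSpec, rng: np.random.Generator, n: int) -> np.ndarray:
    freqs = np.fft.rfftfreq(n, d=1.0 / spec.sampling_rate)
    psd = np.zeros_like(freqs)
    mask = freqs >= spec.background_f_min
    psd[mask] = spec.background_1f_scale / freqs[mask]
    amp = np.sqrt(psd * spec.sampling_rate * n / 4.0)
    coefs = amp * (rng.standard_normal(freqs.size) + 1j * rng.standard_normal(freqs.size))
    coefs[0] = 0.0
    return np.fft.irfft(coefs, n)


def _oscillator(
    band: Band, amp: float, spec: CohortSpec, rng: np.random.Generator, n: int
) -> np.ndarray:
    sos, unit_var, _ = _oscillator_filter(band.f_lo, band.f_hi, spec.sampling_rate)
    w = rng.standard_normal(n)
    return sps.sosfiltfilt(sos, w) * (amp / np.sqrt(unit_var))


def _artifact_mask(spec: CohortSpec, subject_idx: int, condition: str) -> np.ndarray:
    n_epochs = int(spec.duration_per_condition // EPOCH_LEN_S)
    rng = _rng(spec.seed, _ARTIFACT_STREAM, subject_idx, CONDITIONS.index(condition))
    return rng.random(n_epochs) < spec.artifact_epoch_rate


def _artifact_waveform(spec: CohortSpec) -> np.ndarray:
    """One high-amplitude transient: a 1-s Hann bump centered in a 4-s epoch."""
    n_ep = int(EPOCH_LEN_S * spec.sampling_rate)
    n_bump = int(spec.sampling_rate)
    wave = np.zeros(n_ep)
    start = (n_ep - n_bump) // 2
    wave[start : start + n_bump] = spec.artifact_amplitude * np.hanning(n_bump)
    return wave


def synth_signal(
    profile: SubjectProfile, condition: str, spec: CohortSpec, channel: str
) -> np.ndarray:
    """Synthesize one channel's time series (µV) for one subject and condition."""
    spec.validate()
    if channel not in spec.channel_set:
        raise ValueError(f"unknown channel label {channel!r}")
    if condition not in CONDITIONS:
        raise ValueError(f"condition must be one of {CONDITIONS}")
    eff = subject_effects(spec, profile)
    idx = _subject_index(profile)
    ch_idx = spec.channel_set.index(channel)
    rng = _rng(spec.seed, _SIGNAL_STREAM, idx, CONDITIONS.index(condition), ch_idx)
    n = int(round(spec.duration_per_condition * spec.sampling_rate))
    left = channel in LEFT_FRONTAL

    x = rng.normal(0.0, spec.white_noise_sd, n)
    x += _one_over_f(spec, rng, n)
    for band, amp in ((ALPHA1, eff.alpha1_amp), (ALPHA2, eff.alpha2_amp)):
        if condition == "task":
            amp = amp * eff.attenuation(band.name, left, spec.left_bias)
        x += _oscillator(band, amp, spec, rng, n)

    mask = _artifact_mask(spec, idx, condition)
    if mask.any():
        wave = _artifact_waveform(spec)
        n_ep_samp = wave.size
        for ei in np.nonzero(mask)[0]:
            x[ei * n_ep_samp : (ei + 1) * n_ep_samp] += wave
    return x


def synth_recording(profile: SubjectProfile, condition: str, spec: CohortSpec) -> EEGRecording:
    """Full 16-channel recording for one subject and condition."""
    samples = np.stack(
        [synth_signal(profile, condition, spec, ch) for ch in spec.channel_set]
    )
    return EEGRecording(
        subject_id=profile.subject_id,
        condition=condition,
        channel_labels=spec.channel_set,
        sampling_rate=spec.sampling_rate,
        samples=samples,
    )


def iter_cohort(spec: CohortSpec) -> Iterator[tuple[SubjectProfile, EEGRecording, EEGRecording]]:
    """Stream (profile, rest recording, task recording) one subject at a time."""
    for profile in generate_profiles(spec):
        yield profile, synth_recording(profile, "rest", spec), synth_recording(
            profile, "task", spec
        )


def generate_cohort(
    spec: CohortSpec,
) -> tuple[list[SubjectProfile], list[tuple[EEGRecording, EEGRecording]]]:
    """Materialize the whole cohort: profiles plus (rest, task) recording pairs."""
    profiles, pairs = [], []
    for profile, rest, task in iter_cohort(spec):
        profiles.append(profile)
        pairs.append((rest, task))
    return profiles, pairs


def profiles_to_frame(profiles: list[SubjectProfile]) -> pd.DataFrame:
    return pd.DataFrame([dataclasses.asdict(p) for p in profiles])


# ---------------------------------------------------------------------------
# analytic oracle
# ---------------------------------------------------------------------------

def expected_band_components(
    spec: CohortSpec,
    profile: SubjectProfile,
    condition: str,
    band: Band | str,
    channel: str = "F4",
    epoch_len_s: float = EPOCH_LEN_S,
) -> dict[str, float]:
    """Expected in-band power split into oscillator and background parts (µV²).

    The values are what the default band-power estimator measures in
    expectation, spectral leakage of the finite epoch included, so that e.g.
    the desynchronization closed form ERD% = 100·(a²−1)·(1−b) holds exactly
    with b = background share = (background + white) / total at rest.
    """
    if isinstance(band, str):
        band = {"alpha1": ALPHA1, "alpha2": ALPHA2}[band]
    if condition not in CONDITIONS:
        raise ValueError(f"condition must be one of {CONDITIONS}")
    n_epoch = int(round(epoch_len_s * spec.sampling_rate))
    eff = subject_effects(spec, profile)
    left = channel in LEFT_FRONTAL
    parts = {
        "background": _background_band_power(spec, band, n_epoch)
        + _white_band_power(spec, band, n_epoch)
    }
    for osc_band, amp in ((ALPHA1, eff.alpha1_amp), (ALPHA2, eff.alpha2_amp)):
        if condition == "task":
            amp = amp * eff.attenuation(osc_band.name, left, spec.left_bias)
        frac = _oscillator_band_fraction(osc_band, band, spec.sampling_rate, n_epoch)
        parts[osc_band.name] = amp**2 * frac
    return parts


def expected_band_power(
    spec: CohortSpec,
    profile: SubjectProfile,
    condition: str,
    band: Band | str,
    channel: str = "F4",
    epoch_len_s: float = EPOCH_LEN_S,
) -> float:
    """Closed-form expected absolute band power (µV²) of the generative model."""
    return float(
        sum(
            expected_band_components(
                spec, profile, condition, band, channel, epoch_len_s
            ).values()
        )
    )


def expected_region_power(
    spec: CohortSpec,
    profile: SubjectProfile,
    condition: str,
    band: Band | str,
    region: str,
) -> float:
    """Expected regional power: mean over the region's two channels."""
    channels = ("F3", "FP1") if region == "Fs" else ("F4", "FP2")
    return float(
        np.mean(
            [expected_band_power(spec, profile, condition, band, ch) for ch in channels]
        )
    )


def expected_erd(
    spec: CohortSpec, profile: SubjectProfile, band: Band | str, region: str
) -> float:
    """Ground-truth ERD% for one subject/band/region: 100·(E−R)/R on expected powers."""
    r = expected_region_power(spec, profile, "rest", band, region)
    e = expected_region_power(spec, profile, "task", band, region)
    return 100.0 * (e - r) / r


# ---------------------------------------------------------------------------
# fast subject-level sampling (for calibration/power studies)
# ---------------------------------------------------------------------------

def sample_erd_table(
    spec: CohortSpec, rng: np.random.Generator | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Draw a cohort's ERD table directly from the generative model.

    Skips signal synthesis: per subject × band × region, rest and task region
    powers take their closed-form expected values and estimation noise is
    modeled as scaled chi-square with 2·(bins per band)·(retained epochs)·
    (2 channels) degrees of freedom — the sampling distribution of a
    Bartlett-averaged band power over independent periodogram bins.  Retained
    epoch counts are Binomial(n_epochs, 1−artifact_epoch_rate).

    Returns (metadata frame, ERD frame).  Used for replicate-heavy calibration
    and power studies where full synthesis would be wasteful; the signal-level
    path is validated against the same closed forms elsewhere.
    """
    spec.validate()
    if rng is None:
        rng = _rng(spec.seed, _FAST_STREAM)
    profiles = generate_profiles(spec)
    n_epochs = int(spec.duration_per_condition // EPOCH_LEN_S)
    bin_res = 0.25  # 4-s epochs
    rows = []
    for profile in profiles:
        retained = {
            cond: max(int(rng.binomial(n_epochs, 1.0 - spec.artifact_epoch_rate)), 1)
            for cond in CONDITIONS
        }
        for band in (ALPHA1, ALPHA2):
            n_bins = int(round((band.f_hi - band.f_lo) / bin_res))
            for region in ("Fd", "Fs"):
                power_hat = {}
                for cond in CONDITIONS:
                    mean_p = expected_region_power(spec, profile, cond, band, region)
                    dof = 2 * n_bins * retained[cond] * 2  # ×2 channels per region
                    power_hat[cond] = mean_p * rng.chisquare(dof) / dof
                rows.append(
                    {
                        "subject_id": profile.subject_id,
                        "band": band.name,
                        "region": region,
                        "erd_percent": 100.0
                        * (power_hat["task"] - power_hat["rest"])
                        / power_hat["rest"],
                    }
                )
    erd = pd.DataFrame(rows).sort_values(["subject_id", "band", "region"], ignore_index=True)
    return profiles_to_frame(profiles), erd
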