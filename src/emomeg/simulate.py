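"""Synthetic case-control cohort generator.

Produces cleaned multichannel epochs and ordinal picture-rating tables that
mimic the structure of a sensor-level MEG emotion study: two groups (healthy
controls, label 1, and facial-palsy patients, label 0), three stimulus
categories (pleasant / neutral / unpleasant), 45-55 clean trials per subject
and category, epochs spanning -1000..+1500 ms around stimulus onset at
250 Hz, and 7-point valence/arousal ratings for 60 pictures per category.

Each simulated trial is the sum of

* spectrally shaped background noise with a ~1/f power slope,
* a stimulus-locked evoked component (Gaussian-windowed sinusoid, latency
  drawn once per category from 100-400 ms, strictly post-stimulus) whose
  spatial topography is shared within the cohort up to a subject-level
  amplitude jitter (coefficient of variation 20%), and
* band-limited oscillatory activity in each of the five default bands.

Group differences are planted via :class:`EffectSpec`: on the affected
channels, patients' evoked amplitude is divided by ``erf_amplitude_ratio``
and their per-band oscillation amplitude by ``sqrt(band_power_ratio)``, so
the ratios read as control:patient ratios and all ratios equal to one
reproduce the exact null.  Rating effects are planted as a signed shift of
the patients' latent valence (and arousal) for the pleasant category.

All randomness flows through explicit seeds; identical ``(spec, effect,
seed)`` triples yield bit-identical cohorts.
"""

from __future__ import annotations

import math
from collections.abc import Iterator, Mapping
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .bands import DEFAULT_BANDS

CATEGORIES: tuple[str, ...] = ("pleasant", "neutral", "unpleasant")
GROUP_CONTROL = 1
GROUP_PATIENT = 0

# Signal model constants (arbitrary consistent field units).
NOISE_SD = 1.0
EVOKED_AMPLITUDE = 2.0
EVOKED_FREQ_HZ = 5.0
EVOKED_WIDTH_S = 0.08
EVOKED_LATENCY_RANGE_S = (0.100, 0.400)
SUBJECT_AMPLITUDE_CV = 0.20
BAND_OSC_AMPLITUDE = 0.5

# Rating model constants (1-7 scale, valence 1 = most pleasant).
VALENCE_MEANS = {"pleasant": 2.2, "neutral": 4.0, "unpleasant": 5.8}
AROUSAL_MEANS = {"pleasant": 4.8, "neutral": 2.6, "unpleasant": 5.2}
PICTURE_LATENT_SD = 0.15
RATING_NOISE_SCALE = 0.8


def _check_finite_positive(name: str, value: float) -> None:
    if not (math.isfinite(value) and value > 0):
        raise ValueError(f"{name} must be finite and positive, got {value!r}")


@dataclass(frozen=True)
class CohortSpec:
    """Cohort geometry: group sizes, montage, sampling and trial counts."""

    n_controls: int = 17
    n_patients: int = 16
    n_channels: int = 102
    fs: float = 250.0
    epoch_window_ms: tuple[float, float] = (-1000.0, 1500.0)
    trials_per_category: tuple[int, int] = (45, 55)
    categories: tuple[str, ...] = CATEGORIES
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_controls", "n_patients", "n_channels"):
            v = getattr(self, name)
            if not (isinstance(v, (int, np.integer)) and v >= 1):
                raise ValueError(f"{name} must be an integer >= 1, got {v!r}")
        _check_finite_positive("fs", self.fs)
        lo, hi = self.epoch_window_ms
        if not (math.isfinite(lo) and math.isfinite(hi) and lo < 0.0 < hi):
            raise ValueError(
                f"epoch_window_ms must span stimulus onset at 0, got ({lo}, {hi})"
            )
        tlo, thi = self.trials_per_category
        if not (1 <= tlo <= thi):
            raise ValueError(
                f"trials_per_category must satisfy 1 <= lo <= hi, got ({tlo}, {thi})"
            )
        if len(self.categories) == 0 or len(set(self.categories)) != len(self.categories):
            raise ValueError("categories must be a non-empty set of unique labels")

    @property
    def n_subjects(self) -> int:
        return self.n_controls + self.n_patients

    @property
    def n_samples(self) -> int:
        # Half-open window [t_lo, t_hi): avoids a duplicated boundary sample.
        lo, hi = self.epoch_window_ms
        return int(round((hi - lo) * self.fs / 1000.0))

    @property
    def t0_index(self) -> int:
        return int(round(-self.epoch_window_ms[0] * self.fs / 1000.0))

    def subject_ids(self) -> list[str]:
        return [f"C{i + 1:02d}" for i in range(self.n_controls)] + [
            f"P{i + 1:02d}" for i in range(self.n_patients)
        ]

    def groups(self) -> np.ndarray:
        return np.array(
            [GROUP_CONTROL] * self.n_controls + [GROUP_PATIENT] * self.n_patients
        )


@dataclass(frozen=True)
class EffectSpec:
    """Plantable group differences; the all-defaults instance is the exact null."""

    affected_channels: tuple[int, ...] = ()
    affected_categories: tuple[str, ...] | None = None  # None = every category
    erf_amplitude_ratio: float = 1.0
    band_power_ratio: float | Mapping[str, float] = 1.0
    valence_shift_pleasant: float = 0.0
    arousal_shift: float = 0.0

    def __post_init__(self) -> None:
        _check_finite_positive("erf_amplitude_ratio", self.erf_amplitude_ratio)
        for name in self._band_ratio_values():
            _check_finite_positive("band_power_ratio", name)
        for name in ("valence_shift_pleasant", "arousal_shift"):
            if not math.isfinite(getattr(self, name)):
                raise ValueError(f"{name} must be finite")
        for ch in self.affected_channels:
            if not (isinstance(ch, (int, np.integer)) and ch >= 0):
                raise ValueError(f"affected channel indices must be ints >= 0, got {ch!r}")

    def _band_ratio_values(self) -> list[float]:
        if isinstance(self.band_power_ratio, Mapping):
            return list(self.band_power_ratio.values())
        return [self.band_power_ratio]

    def band_ratio(self, band_name: str) -> float:
        if isinstance(self.band_power_ratio, Mapping):
            return float(self.band_power_ratio.get(band_name, 1.0))
        return float(self.band_power_ratio)

    def applies_to(self, category: str) -> bool:
        return self.affected_categories is None or category in self.affected_categories

    def is_null(self) -> bool:
        return (
            self.erf_amplitude_ratio == 1.0
            and all(v == 1.0 for v in self._band_ratio_values())
            and self.valence_shift_pleasant == 0.0
            and self.arousal_shift == 0.0
        )


@dataclass
class EpochSet:
    """One subject x one category block of cleaned trials."""

    subject_id: str
    group: int
    category: str
    data: np.ndarray  # (n_trials, n_channels, n_samples)
    fs: float
    t0_index: int

    def __post_init__(self) -> None:
        if self.data.ndim != 3:
            raise ValueError("EpochSet.data must be (trials, channels, samples)")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("EpochSet.data must be finite")
        if not (0 < self.t0_index < self.data.shape[2]):
            raise ValueError("t0_index must lie strictly inside the epoch")

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def n_samples(self) -> int:
        return self.data.shape[2]


def _spectrum_scales(
    spec: CohortSpec, effect: EffectSpec, patient: bool
) -> np.ndarray:
    """Per-channel rFFT bin standard deviations for background + oscillations.

    Background and band oscillations are independent Gaussian processes, so
    they are drawn jointly as one complex spectrum whose per-bin variance is
    the sum of the component variances.  For a complex bin draw with
    per-component sd ``s`` the time-domain variance contribution of that bin
    is ``4 s^2 / n^2`` (conjugate-symmetric rFFT convention), which fixes the
    normalization below.
    """
    n = spec.n_samples
    freqs = np.fft.rfftfreq(n, 1.0 / spec.fs)
    nf = freqs.size

    # 1/f background: amplitude ~ f^(-1/2) above 1 Hz, flat below, zero DC.
    w = np.zeros(nf)
    nz = freqs > 0
    w[nz] = np.maximum(freqs[nz], 1.0) ** -0.5
    c = NOISE_SD * n / (2.0 * math.sqrt(float(np.sum(w**2))))
    var = np.broadcast_to((c * w) ** 2, (spec.n_channels, nf)).copy()

    affected = np.asarray(effect.affected_channels, dtype=int)
    for band in DEFAULT_BANDS:
        bins = (freqs >= band.f_lo) & (freqs <= band.f_hi)
        nb = int(np.count_nonzero(bins))
        if nb == 0:
            continue
        amp = np.full(spec.n_channels, BAND_OSC_AMPLITUDE)
        if patient and affected.size:
            amp[affected] /= math.sqrt(effect.band_ratio(band.name))
        s_band = amp * n / (2.0 * math.sqrt(nb))
        var[:, bins] += s_band[:, None] ** 2

    return np.sqrt(var)


def _evoked_waveform(spec: CohortSpec, latency_s: float) -> np.ndarray:
    t = (np.arange(spec.n_samples) - spec.t0_index) / spec.fs
    wave = np.exp(-0.5 * ((t - latency_s) / EVOKED_WIDTH_S) ** 2) * np.sin(
        2.0 * math.pi * EVOKED_FREQ_HZ * (t - latency_s)
    )
    wave[t < 0] = 0.0
    return wave


def iter_epochs(
    spec: CohortSpec, effect: EffectSpec | None = None, seed: int | None = None
) -> Iterator[EpochSet]:
    """Yield one :class:`EpochSet` per subject x category, streaming.

    Memory-lean companion of :func:`generate_epochs`; iteration order is
    controls then patients, categories in ``spec.categories`` order.
    """
    effect = effect if effect is not None else EffectSpec()
    seed = spec.seed if seed is None else seed
    affected = np.asarray(effect.affected_channels, dtype=int)
    if affected.size and affected.max() >= spec.n_channels:
        raise ValueError(
            f"affected_channels {tuple(affected)} exceed montage of "
            f"{spec.n_channels} channels"
        )
    for band in DEFAULT_BANDS:
        band.validate_against(spec.fs)

    n_cat = len(spec.categories)
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(1 + spec.n_subjects * n_cat)
    root = np.random.default_rng(children[0])

    # Cohort-level structure, drawn once in a fixed order.
    topo = {c: root.uniform(0.2, 1.0, spec.n_channels) for c in spec.categories}
    latency = {c: root.uniform(*EVOKED_LATENCY_RANGE_S) for c in spec.categories}
    amp_jitter = np.clip(
        root.normal(1.0, SUBJECT_AMPLITUDE_CV, (spec.n_subjects, n_cat)), 0.2, None
    )
    lo, hi = spec.trials_per_category
    n_trials = root.integers(lo, hi + 1, (spec.n_subjects, n_cat))

    scales_control = _spectrum_scales(spec, effect, patient=False)
    scales_patient = _spectrum_scales(spec, effect, patient=True)

    ids = spec.subject_ids()
    groups = spec.groups()
    n = spec.n_samples
    block = 0
    for s in range(spec.n_subjects):
        patient = groups[s] == GROUP_PATIENT
        for ci, cat in enumerate(spec.categories):
            affected_here = patient and effect.applies_to(cat)
            scales = scales_patient if affected_here else scales_control
            rng = np.random.default_rng(children[1 + block])
            block += 1
            nt = int(n_trials[s, ci])
            shape = (nt, spec.n_channels, scales.shape[1])
            z = rng.standard_normal(shape) + 1j * rng.standard_normal(shape)
            z *= scales[None, :, :]
            z[..., 0] = 0.0
            if n % 2 == 0:
                z[..., -1] = z[..., -1].real
            x = np.fft.irfft(z, n=n, axis=-1)

            chan_amp = EVOKED_AMPLITUDE * amp_jitter[s, ci] * topo[cat]
            if affected_here and affected.size:
                chan_amp = chan_amp.copy()
                chan_amp[affected] /= effect.erf_amplitude_ratio
            x += chan_amp[None, :, None] * _evoked_waveform(spec, latency[cat])[None, None, :]

            yield EpochSet(
                subject_id=ids[s],
                group=int(groups[s]),
                category=cat,
                data=x.astype(np.float32),
                fs=spec.fs,
                t0_index=spec.t0_index,
            )


def generate_epochs(
    spec: CohortSpec, effect: EffectSpec | None = None, seed: int | None = None
) -> list[EpochSet]:
    """Generate the full cohort as a list of subject x category epoch blocks."""
    return list(iter_epochs(spec, effect, seed))


def generate_ratings(
    spec: CohortSpec,
    effect: EffectSpec | None = None,
    n_pictures_per_category: int = 60,
    seed: int | None = None,
    n_incomplete_patients: int = 2,
) -> pd.DataFrame:
    """Generate a long-form 7-point SAM rating table.

    Each picture carries a latent valence/arousal value drawn around its
    category mean; each rating adds logistic subject noise (scale
    ``RATING_NOISE_SCALE``) and is rounded and clipped to the integer 1-7
    scale.  Patients' pleasant-category latents are shifted by
    ``effect.valence_shift_pleasant`` / ``effect.arousal_shift``.

    ``n_incomplete_patients`` patients are left incomplete (a random fifth of
    their rows is dropped), emulating partial participation; downstream
    analyses exclude them.

    Returns a DataFrame with columns
    ``subject_id, group, picture_id, category, valence, arousal``.
    """
    effect = effect if effect is not None else EffectSpec()
    seed = spec.seed if seed is None else seed
    if n_pictures_per_category < 1:
        raise ValueError("n_pictures_per_category must be >= 1")
    if not (0 <= n_incomplete_patients <= spec.n_patients):
        raise ValueError("n_incomplete_patients must be within the patient group")
    rng = np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(1,)))

    ids = spec.subject_ids()
    groups = spec.groups()
    npic = n_pictures_per_category
    frames = []
    for cat in spec.categories:
        val_latent = rng.normal(VALENCE_MEANS[cat], PICTURE_LATENT_SD, npic)
        aro_latent = rng.normal(AROUSAL_MEANS[cat], PICTURE_LATENT_SD, npic)
        val_noise = rng.logistic(0.0, RATING_NOISE_SCALE, (spec.n_subjects, npic))
        aro_noise = rng.logistic(0.0, RATING_NOISE_SCALE, (spec.n_subjects, npic))
        val = val_latent[None, :] + val_noise
        aro = aro_latent[None, :] + aro_noise
        if cat == "pleasant":
            is_pat = (groups == GROUP_PATIENT)[:, None]
            val = val + is_pat * effect.valence_shift_pleasant
            aro = aro + is_pat * effect.arousal_shift
        val = np.clip(np.rint(val), 1, 7).astype(int)
        aro = np.clip(np.rint(aro), 1, 7).astype(int)
        pic_ids = [f"{cat[:3]}{i + 1:03d}" for i in range(npic)]
        frames.append(
            pd.DataFrame(
                {
                    "subject_id": np.repeat(ids, npic),
                    "group": np.repeat(groups, npic),
                    "picture_id": np.tile(pic_ids, spec.n_subjects),
                    "category": cat,
                    "valence": val.ravel(),
                    "arousal": aro.ravel(),
                }
            )
        )
    table = pd.concat(frames, ignore_index=True)

    if n_incomplete_patients:
        patient_ids = [i for i, g in zip(ids, groups) if g == GROUP_PATIENT]
        incomplete = rng.choice(patient_ids, size=n_incomplete_patients, replace=False)
        drop_mask = np.zeros(len(table), dtype=bool)
        for sid in incomplete:
            rows = np.flatnonzero((table["subject_id"] == sid).to_numpy())
            n_drop = max(1, len(rows) // 5)
            drop_mask[rng.choice(rows, size=n_drop, replace=False)] = True
        table = table.loc[~drop_mask].reset_index(drop=True)

    return table
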