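"""Synthetic resting-state EEG with a band-switching dominant rhythm.

Each subject is simulated as correlated pink-noise background plus one
oscillator whose band membership is re-drawn every 2-second epoch from a
per-subject occupancy distribution. Because the oscillator is constant
within an epoch, the spec'd occupancies map directly onto the
dominant-frequency prevalence (DFP) the extraction pipeline measures,
giving clean recovery targets. Two cohort presets emulate the qualitative
contrast between Lewy body disease with cognitive fluctuations (dominant
rhythm mostly in pre-alpha/theta) and without (mostly alpha), together
with covariates (age, sex, MoCA) in which MoCA is a genuine confounder.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .errors import ParameterError
from .recording_io import CANONICAL_ORDER, Recording

BANDS = ("delta", "theta", "pre_alpha", "alpha", "beta")

#: Per-band oscillator frequency windows such that, after per-epoch jitter,
#: the nearest 0.5 Hz bin still classifies into the intended band.
_BAND_FREQ_CLIP = {
    "delta": (3.2, 4.0),
    "theta": (4.5, 5.5),
    "pre_alpha": (6.0, 7.5),
    "alpha": (8.0, 12.0),
    "beta": (12.5, 13.5),
}


@dataclass
class SubjectSpec:
    """Generative parameters for one synthetic subject."""

    subject_id: str
    group: str
    occupancy: dict[str, float]
    band_freqs: dict[str, float]
    snr_db: float
    age: float
    sex: str
    moca: float
    seed: int

    def __post_init__(self) -> None:
        occ = np.array([self.occupancy.get(b, 0.0) for b in BANDS])
        if (occ < 0).any() or abs(occ.sum() - 1.0) > 1e-9:
            raise ParameterError(
                f"occupancy must be non-negative and sum to 1, got {self.occupancy}")
        if not (0 <= self.moca <= 30):
            raise ParameterError(f"MoCA must be in [0, 30], got {self.moca}")
        for band, f in self.band_freqs.items():
            lo, hi = _BAND_FREQ_CLIP[band]
            if not (lo <= f <= hi):
                raise ParameterError(
                    f"{band} oscillator at {f} Hz outside safe window [{lo}, {hi}]")


def _pink_noise(rng: np.random.Generator, n: int, beta: float) -> np.ndarray:
    """One 1/f^beta noise trace of length n, unit variance."""
    freqs = np.fft.rfftfreq(n)
    amp = np.zeros_like(freqs)
    amp[1:] = freqs[1:] ** (-beta / 2.0)
    phases = rng.uniform(0, 2 * np.pi, len(freqs))
    spec = amp * np.exp(1j * phases)
    x = np.fft.irfft(spec, n)
    return x / x.std()


def _inband_std(x: np.ndarray, fs: float, lo: float = 3.0, hi: float = 14.0) -> np.ndarray:
    from scipy import signal

    sos = signal.butter(4, [lo, hi], btype="bandpass", fs=fs, output="sos")
    return signal.sosfiltfilt(sos, x, axis=-1).std(axis=-1)


def synth_recording(spec: SubjectSpec, duration_s: float = 180.0, fs: float = 256.0,
                    channels: tuple[str, ...] = CANONICAL_ORDER,
                    epoch_len_s: float = 2.0, background_std_uv: float = 10.0,
                    shared_frac: float = 0.6, noise_beta: float = 1.0,
                    jitter_hz: float = 0.2,
                    epoch_locked: bool = True) -> Recording:
    """Simulate one multichannel recording from a subject spec.

    The background of every channel mixes a scalp-shared pink-noise trace
    with a private one (``shared_frac`` amplitude fraction shared), so
    regional averaging is non-trivial. Each epoch draws one band from the
    occupancy distribution (shared across channels, like a global brain
    state); a sinusoid at that band's subject frequency -- jittered by up
    to ``jitter_hz`` per epoch, random phase per channel -- is added at
    ``snr_db`` relative to the in-band (3-14 Hz) background power. With
    ``epoch_locked=False`` the band instead switches at exponentially
    distributed times, desynchronized from epoch boundaries.
    Fully reproducible from ``spec.seed``.
    """
    if duration_s < epoch_len_s:
        raise ParameterError("duration must cover at least one epoch")
    if fs < 64:
        raise ParameterError(f"sampling rate too low: {fs}")
    n_per = epoch_len_s * fs
    if abs(n_per - round(n_per)) > 1e-9 or abs(duration_s * fs - round(duration_s * fs)) > 1e-9:
        raise ParameterError("duration and epoch length must be sample-aligned")
    rng = np.random.default_rng(spec.seed)
    n = int(round(duration_s * fs))
    n_ch = len(channels)

    shared = _pink_noise(rng, n, noise_beta)
    private = np.stack([_pink_noise(rng, n, noise_beta) for _ in range(n_ch)])
    mix = shared_frac * shared[None, :] + np.sqrt(1 - shared_frac ** 2) * private
    background = background_std_uv * mix / mix.std(axis=-1, keepdims=True)
    bg_inband_std = _inband_std(background, fs)

    bands = [b for b in BANDS if spec.occupancy.get(b, 0.0) > 0]
    probs = np.array([spec.occupancy[b] for b in bands])
    probs = probs / probs.sum()
    t = np.arange(n) / fs
    osc = np.zeros((n_ch, n))

    if epoch_locked:
        n_epochs = n // int(round(n_per))
        bounds = [(int(e * n_per), int((e + 1) * n_per)) for e in range(n_epochs)]
        if n_epochs * int(round(n_per)) < n:
            bounds.append((n_epochs * int(round(n_per)), n))
    else:
        bounds = []
        start = 0
        while start < n:
            length = int(round(rng.exponential(epoch_len_s) * fs)) + 1
            bounds.append((start, min(start + length, n)))
            start += length

    amp = np.sqrt(2.0 * 10.0 ** (spec.snr_db / 10.0)) * bg_inband_std
    for lo_i, hi_i in bounds:
        band = bands[rng.choice(len(bands), p=probs)]
        f = spec.band_freqs[band] + rng.uniform(-jitter_hz, jitter_hz)
        phases = rng.uniform(0, 2 * np.pi, n_ch)
        seg_t = t[lo_i:hi_i]
        osc[:, lo_i:hi_i] = amp[:, None] * np.sin(
            2 * np.pi * f * seg_t[None, :] + phases[:, None])

    return Recording(background + osc, fs, list(channels))


# ---------------------------------------------------------------------------
# Cohort generation
# ---------------------------------------------------------------------------

@dataclass
class GroupPreset:
    """Group-level distributions from which subject specs are drawn."""

    occupancy_mean: dict[str, float]
    f_alpha_mean: float
    f_alpha_sd: float
    f_slow_mean: float
    f_slow_sd: float
    male_prob: float
    moca_mean: float
    moca_sd: float
    occupancy_conc: float = 30.0
    snr_db_mean: float = 8.0
    snr_db_sd: float = 2.0
    age_mean: float = 73.0
    age_sd: float = 6.0


#: LB disease without cognitive fluctuations: alpha-dominant rhythm.
PRESET_NON_CF = GroupPreset(
    occupancy_mean={"alpha": 0.55, "pre_alpha": 0.22, "theta": 0.07, "delta": 0.16},
    f_alpha_mean=9.5, f_alpha_sd=0.6, f_slow_mean=6.5, f_slow_sd=0.5,
    male_prob=0.54, moca_mean=24.0, moca_sd=2.5)

#: LB disease with cognitive fluctuations: pre-alpha/theta-dominant rhythm,
#: residual alpha sitting low in the band, lower MoCA.
PRESET_CF = GroupPreset(
    occupancy_mean={"alpha": 0.10, "pre_alpha": 0.45, "theta": 0.17, "delta": 0.28},
    f_alpha_mean=8.8, f_alpha_sd=0.5, f_slow_mean=6.2, f_slow_sd=0.5,
    male_prob=0.79, moca_mean=19.5, moca_sd=4.0)

PRESETS: dict[str, dict[str, GroupPreset]] = {
    "paperlike": {"cf": PRESET_CF, "non_cf": PRESET_NON_CF},
}


@dataclass
class CohortSpec:
    """Sizes, presets and the master seed for a two-group synthetic cohort."""

    n_cf: int = 29
    n_non_cf: int = 24
    seed: int = 1
    duration_s: float = 180.0
    fs: float = 256.0
    channels: tuple[str, ...] = CANONICAL_ORDER
    cf_preset: GroupPreset = field(default_factory=lambda: PRESET_CF)
    non_cf_preset: GroupPreset = field(default_factory=lambda: PRESET_NON_CF)

    def __post_init__(self) -> None:
        if self.n_cf < 2 or self.n_non_cf < 2:
            raise ParameterError("need n >= 2 per group")


def _clip(x: float, lo: float, hi: float) -> float:
    return float(min(max(x, lo), hi))


def draw_subject_spec(preset: GroupPreset, group: str, subject_id: str,
                      rng: np.random.Generator, seed: int) -> SubjectSpec:
    """Draw one subject's generative parameters from a group preset."""
    bands = [b for b in BANDS if preset.occupancy_mean.get(b, 0.0) > 0]
    alpha_conc = preset.occupancy_conc * np.array(
        [preset.occupancy_mean[b] for b in bands])
    occ_draw = rng.dirichlet(alpha_conc)
    occupancy = {b: 0.0 for b in BANDS}
    occupancy.update(dict(zip(bands, occ_draw.tolist())))

    f_alpha = _clip(rng.normal(preset.f_alpha_mean, preset.f_alpha_sd),
                    *_BAND_FREQ_CLIP["alpha"])
    f_slow = _clip(rng.normal(preset.f_slow_mean, preset.f_slow_sd),
                   *_BAND_FREQ_CLIP["pre_alpha"])
    band_freqs = {
        "alpha": f_alpha,
        "pre_alpha": f_slow,
        "theta": _clip(rng.normal(5.0, 0.25), *_BAND_FREQ_CLIP["theta"]),
        "delta": _clip(rng.normal(3.6, 0.2), *_BAND_FREQ_CLIP["delta"]),
        "beta": _clip(rng.normal(13.0, 0.25), *_BAND_FREQ_CLIP["beta"]),
    }
    return SubjectSpec(
        subject_id=subject_id, group=group, occupancy=occupancy,
        band_freqs=band_freqs,
        snr_db=float(rng.normal(preset.snr_db_mean, preset.snr_db_sd)),
        age=float(np.round(rng.normal(preset.age_mean, preset.age_sd), 1)),
        sex="M" if rng.uniform() < preset.male_prob else "F",
        moca=float(np.clip(np.round(rng.normal(preset.moca_mean, preset.moca_sd)),
                           0, 30)),
        seed=seed)


def synth_cohort(spec: CohortSpec) -> tuple[list[tuple[SubjectSpec, Recording]],
                                            pd.DataFrame]:
    """Generate a two-group cohort of recordings plus a metadata table.

    Per-subject seeds derive deterministically from the master seed, so
    the cohort is fully reproducible and any subject can be regenerated
    in isolation.
    """
    ss = np.random.SeedSequence(spec.seed)
    n_total = spec.n_cf + spec.n_non_cf
    children = ss.spawn(n_total + 1)
    rng = np.random.default_rng(children[0])
    out: list[tuple[SubjectSpec, Recording]] = []
    rows = []
    layout = [("cf", spec.cf_preset, spec.n_cf),
              ("non_cf", spec.non_cf_preset, spec.n_non_cf)]
    idx = 0
    for group, preset, n in layout:
        for k in range(n):
            sid = f"{group}_{k + 1:03d}"
            child_seed = int(children[idx + 1].generate_state(1)[0] % (2 ** 31))
            subj = draw_subject_spec(preset, group, sid, rng, child_seed)
            rec = synth_recording(subj, spec.duration_s, spec.fs, spec.channels)
            out.append((subj, rec))
            rows.append({"subject_id": sid, "group": group, "age": subj.age,
                         "sex": subj.sex, "moca": subj.moca, "seed": subj.seed})
            idx += 1
    return out, pd.DataFrame(rows)


def null_cohort_spec(base: CohortSpec | None = None, **overrides) -> CohortSpec:
    """A cohort spec whose two groups share one preset (null hypothesis)."""
    base = base or CohortSpec()
    return replace(base, cf_preset=base.non_cf_preset,
                   non_cf_preset=base.non_cf_preset, **overrides)
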