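"""Dominant-frequency features from per-epoch power spectra.

The method characterizes the resting dominant rhythm of each EEG channel
with four quantities computed over a set of short epochs:

* **DF** (dominant frequency): the frequency bin of maximum spectral power
  within the 3-14 Hz analysis window, per epoch.
* **DFV** (dominant-frequency variability): the sample standard deviation
  of DF across epochs.
* **DFP** (dominant-frequency prevalence): the percentage of epochs whose
  DF falls in each of five predefined bands (delta, theta, pre-alpha,
  alpha, beta); prevalences sum to 100%.
* **IAF** (individual alpha peak frequency): the per-epoch spectral peak
  restricted to the alpha band (8-12 Hz), averaged across epochs.

Channel-level values are then averaged over anatomically defined scalp
regions (anterior, temporal, posterior) and over all channels (global),
giving 7 features x 4 derivations = 28 candidate features per subject.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import (EmptyAnalysisError, InputError, InsufficientDataError,
                     ParameterError, RegionEmptyError)
from .preprocess import DEFAULT_BAND, EpochArray

logger = logging.getLogger(__name__)

#: Scalp regions (legacy 10-20 names). Global additionally includes Cz/C3/C4.
REGIONS: dict[str, tuple[str, ...]] = {
    "anterior": ("Fp1", "Fp2", "Fz", "F3", "F4", "F7", "F8"),
    "temporal": ("T3", "T4", "T5", "T6"),
    "posterior": ("Pz", "P3", "P4", "O1", "O2"),
}

DERIVATIONS: tuple[str, ...] = ("global", "anterior", "temporal", "posterior")

#: Features entering group comparison and modeling, per derivation.
CANDIDATE_FEATURE_KINDS: tuple[str, ...] = (
    "df", "dfv", "iaf", "dfp_alpha", "dfp_pre_alpha", "dfp_theta", "dfp_delta",
)

#: All 28 candidate feature columns (dfp_beta is retained in tables but is
#: not a modeling candidate, mirroring the four reported prevalence bands).
CANDIDATE_FEATURES: tuple[str, ...] = tuple(
    f"{region}_{kind}" for region in DERIVATIONS for kind in CANDIDATE_FEATURE_KINDS
)

IAF_BAND = (8.0, 12.0)


@dataclass(frozen=True)
class BandScheme:
    """Named frequency bands partitioning the analysis range.

    The printed band definitions (delta <= 4.0, theta 4.5-5.5, pre-alpha
    6.0-7.5, alpha 8.0-12.0, beta > 12.0 Hz) leave gaps between bands that
    no bin of the 0.5 Hz analysis grid can fall into. For totality the
    scheme stores half-open intervals whose edges bisect those gaps; the
    extension agrees with the printed closed intervals at every on-grid
    frequency.
    """

    edges: tuple[tuple[str, float, float], ...] = (
        ("delta", 0.0, 4.25),
        ("theta", 4.25, 5.75),
        ("pre_alpha", 5.75, 7.75),
        ("alpha", 7.75, 12.25),
        ("beta", 12.25, math.inf),
    )

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(name for name, _, _ in self.edges)

    def classify(self, f: float) -> str:
        if f < 0:
            raise ParameterError(f"frequency must be non-negative, got {f}")
        for name, lo, hi in self.edges:
            if lo <= f < hi:
                return name
        raise ParameterError(f"frequency {f} not covered by band scheme")


DEFAULT_BANDS = BandScheme()


def classify_band(f: float, scheme: BandScheme = DEFAULT_BANDS) -> str:
    """Band name for a frequency; total over f >= 0."""
    return scheme.classify(f)


@dataclass
class EpochSpectra:
    """One-sided power spectra for the kept epochs of a recording.

    ``power`` has shape (n_kept_epochs, n_channels, n_bins) in uV^2 and is
    normalized so that, per epoch and channel, ``power.sum()`` equals the
    mean-square amplitude of the time-domain epoch (Parseval).
    """

    power: np.ndarray
    freqs: np.ndarray
    channel_labels: list[str]

    @property
    def n_epochs(self) -> int:
        return self.power.shape[0]


def periodogram(ep: EpochArray) -> EpochSpectra:
    """Rectangular-window periodogram per kept epoch and channel.

    No taper and no zero-padding, so the bin spacing is exactly
    ``1/epoch_len_s`` (0.5 Hz for 2-s epochs) and an on-grid sinusoid
    concentrates all its power in a single bin.
    """
    if ep.n_kept == 0:
        raise EmptyAnalysisError("no kept epochs to compute spectra from")
    x = ep.kept_data
    n = x.shape[-1]
    spec = np.fft.rfft(x, axis=-1)
    power = (np.abs(spec) ** 2) / (n * n)
    # one-sided: double every bin with a conjugate partner (not DC; not
    # Nyquist when n is even)
    if n % 2 == 0:
        power[..., 1:-1] *= 2.0
    else:
        power[..., 1:] *= 2.0
    freqs = np.fft.rfftfreq(n, d=1.0 / ep.fs)
    return EpochSpectra(power, freqs, list(ep.channel_labels))


def dominant_frequency(spec: EpochSpectra, lo: float = DEFAULT_BAND[0],
                       hi: float = DEFAULT_BAND[1]) -> np.ndarray:
    """Per-epoch, per-channel dominant frequency (Hz).

    Argmax of power over bins with ``lo <= f <= hi``; exact power ties are
    broken toward the lowest frequency.
    """
    in_window = (spec.freqs >= lo) & (spec.freqs <= hi)
    if not in_window.any():
        raise ParameterError(f"analysis window [{lo}, {hi}] Hz excludes all bins")
    windowed = spec.power[..., in_window]
    idx = windowed.argmax(axis=-1)  # argmax returns the first (lowest) maximum
    return spec.freqs[in_window][idx]


@dataclass
class ChannelFeatureSet:
    """DF/DFV/DFP/IAF for one channel over a recording's kept epochs."""

    channel: str
    df_series: np.ndarray
    mean_df: float
    dfv: float
    dfp: dict[str, float]
    iaf_series: np.ndarray
    mean_iaf: float

    def scalar_features(self) -> dict[str, float]:
        out = {"df": self.mean_df, "dfv": self.dfv, "iaf": self.mean_iaf}
        out.update({f"dfp_{band}": pct for band, pct in self.dfp.items()})
        return out


def channel_features(spec: EpochSpectra, scheme: BandScheme = DEFAULT_BANDS,
                     lo: float = DEFAULT_BAND[0], hi: float = DEFAULT_BAND[1],
                     ) -> dict[str, ChannelFeatureSet]:
    """Compute the per-channel feature set from epoch spectra.

    DFV uses the sample standard deviation (n-1 denominator). IAF is the
    per-epoch alpha-band (8-12 Hz) peak, ties toward the lower frequency,
    averaged over epochs.
    """
    if spec.n_epochs < 2:
        raise InsufficientDataError(
            f"need >= 2 epochs for DFV, got {spec.n_epochs}")
    df = dominant_frequency(spec, lo, hi)          # epochs x channels
    iaf = dominant_frequency(spec, *IAF_BAND)      # alpha-restricted peak
    out: dict[str, ChannelFeatureSet] = {}
    for ci, channel in enumerate(spec.channel_labels):
        series = df[:, ci]
        bands = [scheme.classify(f) for f in series]
        dfp = {name: 100.0 * sum(b == name for b in bands) / len(bands)
               for name in scheme.names}
        out[channel] = ChannelFeatureSet(
            channel=channel,
            df_series=series,
            mean_df=float(series.mean()),
            dfv=float(series.std(ddof=1)),
            dfp=dfp,
            iaf_series=iaf[:, ci],
            mean_iaf=float(iaf[:, ci].mean()),
        )
    return out


@dataclass
class RegionFeatures:
    """Unweighted channel mean of each scalar feature over a derivation."""

    derivation: str
    values: dict[str, float]
    n_available: int
    n_expected: int

    @property
    def complete(self) -> bool:
        return self.n_available == self.n_expected


def aggregate_regions(per_channel: dict[str, ChannelFeatureSet],
                      regions: dict[str, tuple[str, ...]] | None = None,
                      ) -> dict[str, RegionFeatures]:
    """Average channel features within regions plus a global derivation.

    Each scalar feature is the unweighted mean over the region's available
    member channels; ``n_available``/``n_expected`` records completeness.
    The global derivation averages over all available analysis channels.
    """
    regions = dict(regions) if regions is not None else dict(REGIONS)
    out: dict[str, RegionFeatures] = {}
    available = set(per_channel)
    global_members = sorted(available)
    layouts = {"global": (global_members, len(global_members))}
    for name, members in regions.items():
        present = [ch for ch in members if ch in available]
        layouts[name] = (present, len(members))
    for name, (present, expected) in layouts.items():
        if not present:
            raise RegionEmptyError(f"region {name!r} has no available channels")
        if len(present) < expected:
            logger.warning("region %s incomplete: %d/%d channels",
                           name, len(present), expected)
        keys = per_channel[present[0]].scalar_features().keys()
        values = {k: float(np.mean([per_channel[ch].scalar_features()[k]
                                    for ch in present]))
                  for k in keys}
        out[name] = RegionFeatures(name, values, len(present), expected)
    return out


def extract_subject_features(ep: EpochArray, scheme: BandScheme = DEFAULT_BANDS,
                             n_epochs: int | None = 90,
                             ) -> tuple[dict[str, RegionFeatures],
                                        dict[str, ChannelFeatureSet]]:
    """Run spectra -> channel features -> regional aggregation for one subject.

    When more than ``n_epochs`` epochs are kept, the first ``n_epochs`` in
    temporal order are used (logged); fewer are used as-is.
    """
    from .preprocess import take_first_kept

    if n_epochs is not None and ep.n_kept > n_epochs:
        logger.info("using first %d of %d kept epochs", n_epochs, ep.n_kept)
        ep = take_first_kept(ep, n_epochs)
    spec = periodogram(ep)
    per_channel = channel_features(spec, scheme)
    return aggregate_regions(per_channel), per_channel


@dataclass
class FeatureTable:
    """Tidy per-subject feature table for the statistics and modeling layers.

    One row per subject: id, group, age, sex, MoCA, and the
    ``<derivation>_<feature>`` columns. ``candidate_features`` names the 28
    columns entering comparison/modeling (beta prevalence is carried in the
    table but excluded from the candidate set).
    """

    data: pd.DataFrame
    candidate_features: tuple[str, ...] = CANDIDATE_FEATURES

    def __post_init__(self) -> None:
        missing = [c for c in self.candidate_features if c not in self.data.columns]
        if missing:
            raise InputError(f"feature table lacks candidate columns {missing}")

    @property
    def groups(self) -> list[str]:
        return sorted(self.data["group"].unique())

    def df_range(self, derivation: str = "global") -> dict[str, tuple[float, float]]:
        """Per-group (min, max) of subject-level mean DF for a derivation."""
        col = f"{derivation}_df"
        return {g: (float(sub[col].min()), float(sub[col].max()))
                for g, sub in self.data.groupby("group")}

    def to_csv(self, path) -> None:
        self.data.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "FeatureTable":
        return cls(pd.read_csv(path))


@dataclass
class SubjectRecord:
    """Regional features plus metadata for one subject."""

    subject_id: str
    group: str
    age: float
    sex: str
    moca: float
    regional: dict[str, RegionFeatures]
    extra: dict[str, float] = field(default_factory=dict)


def build_feature_table(subjects: list[SubjectRecord]) -> FeatureTable:
    """Assemble the per-subject tidy table from regional feature sets."""
    if not subjects:
        raise InputError("at least one subject required")
    ids = [s.subject_id for s in subjects]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise InputError(f"duplicate subject ids: {dupes}")
    rows = []
    for s in subjects:
        if s.moca is None or not (0 <= s.moca <= 30):
            raise InputError(f"subject {s.subject_id}: MoCA must be in [0, 30]")
        row: dict[str, object] = {
            "subject_id": s.subject_id, "group": s.group,
            "age": s.age, "sex": s.sex, "moca": s.moca,
        }
        for deriv, feats in s.regional.items():
            for k, v in feats.values.items():
                row[f"{deriv}_{k}"] = v
            row[f"{deriv}_n_channels"] = feats.n_available
        row.update(s.extra)
        rows.append(row)
    return FeatureTable(pd.DataFrame(rows))
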