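"""EDF reading/writing and 10-20 channel-label canonicalization.

Recordings are held in memory as channels x time matrices of scalp
potentials in microvolts. Reading goes through MNE; a minimal EDF writer
is provided for the simulator and for test fixtures. Channel labels are
normalized onto the legacy 10-20 names (T3/T4/T5/T6 rather than their
modern 10-10 equivalents T7/T8/P7/P8) because the regional derivations
are defined with the legacy names.
"""

from __future__ import annotations

import datetime
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .errors import ContentError, FormatError, ParameterError, UnsupportedLayoutError

logger = logging.getLogger(__name__)

#: Canonical 10-20 montage order (19 scalp electrodes).
CANONICAL_ORDER: tuple[str, ...] = (
    "Fp1", "Fp2", "F7", "F3", "Fz", "F4", "F8",
    "T3", "C3", "Cz", "C4", "T4",
    "T5", "P3", "Pz", "P4", "T6",
    "O1", "O2",
)

#: Channels the extraction pipeline expects: the 16 region members plus Cz, C3, C4.
REQUIRED_CHANNELS: tuple[str, ...] = CANONICAL_ORDER

# Modern 10-10 temporal names map onto the legacy 10-20 names used by the
# regional definitions.
_MODERN_ALIASES = {"t7": "T3", "t8": "T4", "p7": "T5", "p8": "T6"}

_CANONICAL_LOOKUP = {name.casefold(): name for name in CANONICAL_ORDER}
_CANONICAL_LOOKUP.update(_MODERN_ALIASES)

_REFERENCE_SUFFIXES = ("-ref", "-le", "-a1a2", "-a1", "-a2", "-avg", "-m1", "-m2")


def canonicalize_label(raw: str) -> str | None:
    """Map a raw EDF channel label onto its canonical 10-20 name.

    Strips a leading modality prefix (``"EEG "``), a trailing reference
    suffix (``"-REF"``, ``"-LE"``, ``"-A1A2"``, ...), case-folds, and
    resolves modern temporal aliases (T7->T3, T8->T4, P7->T5, P8->T6).
    Returns ``None`` for labels that do not name a 10-20 scalp electrode.
    """
    label = raw.strip()
    if label.casefold().startswith("eeg"):
        label = label[3:].lstrip(" :")
    folded = label.casefold()
    for suffix in _REFERENCE_SUFFIXES:
        if folded.endswith(suffix):
            label = label[: len(label) - len(suffix)]
            folded = label.casefold()
            break
    return _CANONICAL_LOOKUP.get(folded.strip())


@dataclass
class Recording:
    """Multichannel scalp EEG in memory.

    Attributes
    ----------
    samples : ndarray, shape (n_channels, n_samples)
        Potentials in microvolts.
    fs : float
        Sampling rate in Hz.
    channel_labels : list of str
        Canonical 10-20 names, one per row of ``samples``.
    missing_channels : list of str
        Requested analysis channels absent from this recording.
    """

    samples: np.ndarray
    fs: float
    channel_labels: list[str]
    missing_channels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 2:
            raise ParameterError("samples must be a channels x time matrix")
        if self.fs <= 0:
            raise ParameterError(f"sampling rate must be positive, got {self.fs}")
        if len(self.channel_labels) != self.samples.shape[0]:
            raise ParameterError("one label required per channel row")
        if len(set(self.channel_labels)) != len(self.channel_labels):
            raise ParameterError("channel labels must be unique")

    @property
    def n_channels(self) -> int:
        return self.samples.shape[0]

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs

    def pick(self, labels: list[str]) -> "Recording":
        """Return a sub-recording restricted to ``labels`` (all must exist)."""
        idx = [self.channel_labels.index(lab) for lab in labels]
        return Recording(self.samples[idx], self.fs, list(labels),
                         list(self.missing_channels))


# ---------------------------------------------------------------------------
# EDF header inspection (for layout validation only; sample data go via MNE)
# ---------------------------------------------------------------------------

def _read_edf_signal_headers(path: Path) -> tuple[list[str], list[int], float]:
    """Return (labels, samples-per-record, record duration) from an EDF header."""
    with open(path, "rb") as fh:
        header = fh.read(256)
        if len(header) < 256:
            raise FormatError(f"{path}: truncated or empty EDF header")
        try:
            n_signals = int(header[252:256].decode("ascii").strip())
            record_dur = float(header[244:252].decode("ascii").strip())
        except (UnicodeDecodeError, ValueError) as exc:
            raise FormatError(f"{path}: malformed EDF header") from exc
        if n_signals <= 0:
            raise FormatError(f"{path}: EDF header declares no signals")
        sig_header = fh.read(n_signals * 256)
        if len(sig_header) < n_signals * 256:
            raise FormatError(f"{path}: truncated EDF signal headers")
    labels = [
        sig_header[i * 16:(i + 1) * 16].decode("ascii", errors="replace").strip()
        for i in range(n_signals)
    ]
    # samples-per-record field sits after label/transducer/dim/phys+dig ranges
    # /prefiltering blocks: 16+80+8+8+8+8+8+80 = 216 bytes per signal.
    off = n_signals * 216
    try:
        spr = [
            int(sig_header[off + i * 8: off + (i + 1) * 8].decode("ascii").strip())
            for i in range(n_signals)
        ]
    except (UnicodeDecodeError, ValueError) as exc:
        raise FormatError(f"{path}: malformed samples-per-record field") from exc
    return labels, spr, record_dur


def read_edf(path: str | Path, required: tuple[str, ...] = REQUIRED_CHANNELS) -> Recording:
    """Read an EDF recording, keeping only canonical 10-20 EEG channels.

    Non-EEG signals (ECG, photic, annotations, ...) and unmapped labels are
    dropped with a logged warning. Potentials are returned in microvolts
    (rescaled from the EDF physical dimension where necessary). Channels the
    analysis expects but that are absent are listed in
    ``Recording.missing_channels`` rather than aborting the read.

    Raises
    ------
    FormatError
        Unreadable or truncated file.
    ContentError
        No EEG channel remains after label filtering.
    UnsupportedLayoutError
        EEG channels with differing sampling rates.
    """
    import mne

    path = Path(path)
    labels, spr, _ = _read_edf_signal_headers(path)
    eeg_rates = {s for lab, s in zip(labels, spr) if canonicalize_label(lab)}
    if len(eeg_rates) > 1:
        raise UnsupportedLayoutError(
            f"{path}: EEG channels carry differing sampling rates {sorted(eeg_rates)}"
        )

    try:
        raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    except Exception as exc:
        raise FormatError(f"{path}: failed to parse EDF ({exc})") from exc

    mapping: dict[str, str] = {}
    for name in raw.ch_names:
        canonical = canonicalize_label(name)
        if canonical is None:
            logger.warning("dropping unmapped channel %r in %s", name, path.name)
        elif canonical in mapping.values():
            logger.warning("duplicate channel %s in %s; keeping first", canonical, path.name)
        else:
            mapping[name] = canonical
    if not mapping:
        raise ContentError(f"{path}: no EEG channels after label filtering")

    # keep canonical montage order
    ordered = [(orig, canon) for canon in CANONICAL_ORDER
               for orig, c in mapping.items() if c == canon]
    orig_names = [o for o, _ in ordered]
    canon_names = [c for _, c in ordered]
    data = raw.get_data(picks=orig_names, units="uV")
    missing = [ch for ch in required if ch not in canon_names]
    if missing:
        logger.warning("%s: missing analysis channels %s", path.name, missing)
    return Recording(np.asarray(data, dtype=float), float(raw.info["sfreq"]),
                     canon_names, missing)


# ---------------------------------------------------------------------------
# Minimal EDF writer (simulator output and test fixtures)
# ---------------------------------------------------------------------------

def _phys_bound(peak: float) -> float:
    """Smallest bound >= peak whose +-value prints in <= 8 ASCII chars."""
    cand = max(peak * 1.05, 1e-6)
    for _ in range(20):
        for prec in (6, 5, 4, 3, 2, 1):
            s = f"{cand:.{prec}g}"
            if len(s) <= 7 and float(s) >= peak:  # 7 leaves room for '-'
                return float(s)
        cand *= 1.05
    raise ParameterError(f"cannot represent physical range for peak {peak}")

def write_edf(path: str | Path, rec: Recording, physical_dim: str = "uV",
              physical_max: float | None = None) -> None:
    """Write a recording as a minimal single-rate EDF file.

    Samples are quantized to 16-bit over a symmetric physical range
    (+-``physical_max``; by default the smallest power-of-ten-ish bound
    covering the data). ``physical_dim`` may be ``"uV"``, ``"mV"`` or
    ``"V"``; internal microvolt values are rescaled accordingly so a
    round-trip through :func:`read_edf` recovers microvolts.
    """
    path = Path(path)
    fs = rec.fs
    if abs(fs - round(fs)) > 1e-9:
        raise ParameterError("EDF writer requires an integer sampling rate")
    fs_i = int(round(fs))
    n_records = rec.n_samples // fs_i  # 1-second records; trailing partial dropped
    if n_records < 1:
        raise ParameterError("recording shorter than one EDF record (1 s)")

    scale = {"uV": 1.0, "mV": 1e-3, "V": 1e-6}[physical_dim]
    data = rec.samples * scale
    if physical_max is None:
        peak = float(np.max(np.abs(data))) if data.size else 1.0
        physical_max = _phys_bound(peak)
    else:
        physical_max = _phys_bound(physical_max / 1.05)
    dig_max, dig_min = 32767, -32768
    # invert the reader's affine map phys = (dig - dig_min) * gain + phys_min
    gain = 2 * physical_max / (dig_max - dig_min)
    quantized = np.clip(np.round((data + physical_max) / gain + dig_min),
                        dig_min, dig_max).astype("<i2")

    ns = rec.n_channels
    now = datetime.datetime(2020, 1, 1)

    def fixed(text: str, width: int) -> bytes:
        return text.encode("ascii")[:width].ljust(width)

    header = b"".join([
        fixed("0", 8),
        fixed("X X X X", 80),
        fixed("Startdate 01-JAN-2020 X X X", 80),
        fixed(now.strftime("%d.%m.%y"), 8),
        fixed(now.strftime("%H.%M.%S"), 8),
        fixed(str(256 * (1 + ns)), 8),
        fixed("", 44),
        fixed(str(n_records), 8),
        fixed("1", 8),
        fixed(str(ns), 4),
    ])
    labels = b"".join(fixed(f"EEG {lab}", 16) for lab in rec.channel_labels)
    transducer = fixed("", 80) * ns
    phys_dim = fixed(physical_dim, 8) * ns
    pm_str = next(f"{physical_max:.{p}g}" for p in range(1, 8)
                  if float(f"{physical_max:.{p}g}") == physical_max)
    phys_min = fixed(f"-{pm_str}", 8) * ns
    phys_max_b = fixed(pm_str, 8) * ns
    dmin = fixed(str(dig_min), 8) * ns
    dmax = fixed(str(dig_max), 8) * ns
    prefilter = fixed("", 80) * ns
    spr = fixed(str(fs_i), 8) * ns
    reserved = fixed("", 32) * ns

    with open(path, "wb") as fh:
        fh.write(header + labels + transducer + phys_dim + phys_min + phys_max_b
                 + dmin + dmax + prefilter + spr + reserved)
        for r in range(n_records):
            block = quantized[:, r * fs_i:(r + 1) * fs_i]
            fh.write(block.tobytes())
    # struct sanity: header length must match the declared byte count
    assert path.stat().st_size >= 256 * (1 + ns), "short EDF write"
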