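"""End-to-end glue: recording -> filtered epochs -> features -> cohort table."""

from __future__ import annotations

import pandas as pd

from .preprocess import (DEFAULT_AMP_LIMIT_UV, DEFAULT_BAND, DEFAULT_EPOCH_LEN_S,
                         bandpass, screen_epochs, segment)
from .recording_io import Recording
from .spectral_features import (DEFAULT_BANDS, BandScheme, ChannelFeatureSet,
                                FeatureTable, RegionFeatures, SubjectRecord,
                                build_feature_table, extract_subject_features)


def extract_recording_features(
    rec: Recording,
    lo: float = DEFAULT_BAND[0],
    hi: float = DEFAULT_BAND[1],
    epoch_len_s: float = DEFAULT_EPOCH_LEN_S,
    n_epochs: int | None = 90,
    screen: bool = False,
    amp_limit_uv: float = DEFAULT_AMP_LIMIT_UV,
    scheme: BandScheme = DEFAULT_BANDS,
) -> tuple[dict[str, RegionFeatures], dict[str, ChannelFeatureSet]]:
    """Full single-recording pipeline: band-pass, segment, (screen), extract.

    Artifact screening is off by default (synthetic recordings are clean
    by construction); enable it for real clinical EDFs.
    """
    filtered = bandpass(rec, lo, hi)
    ep = segment(filtered, epoch_len_s)
    if screen:
        ep = screen_epochs(ep, amp_limit_uv)
    return extract_subject_features(ep, scheme, n_epochs)


def cohort_feature_table(pairs, metadata: pd.DataFrame | None = None,
                         **extract_kwargs) -> FeatureTable:
    """Build the per-subject feature table for a cohort.

    ``pairs`` is an iterable of ``(subject_like, Recording)`` where
    ``subject_like`` carries ``subject_id``/``group``/``age``/``sex``/
    ``moca`` either as attributes (e.g. a synthetic SubjectSpec) or as a
    mapping. Alternatively pass recordings keyed by id in ``pairs`` and a
    ``metadata`` table with those columns.
    """
    records = []
    meta_by_id = None
    if metadata is not None:
        meta_by_id = metadata.set_index("subject_id").to_dict("index")
    for subject_like, rec in pairs:
        if isinstance(subject_like, str):
            if meta_by_id is None:
                raise ValueError("metadata table required when passing bare ids")
            meta = dict(meta_by_id[subject_like], subject_id=subject_like)
        elif isinstance(subject_like, dict):
            meta = subject_like
        else:
            meta = {k: getattr(subject_like, k)
                    for k in ("subject_id", "group", "age", "sex", "moca")}
        regional, _ = extract_recording_features(rec, **extract_kwargs)
        records.append(SubjectRecord(
            subject_id=str(meta["subject_id"]), group=str(meta["group"]),
            age=float(meta["age"]), sex=str(meta["sex"]),
            moca=float(meta["moca"]), regional=regional))
    return build_feature_table(records)


def channel_long_table(per_channel_by_subject: dict[str, dict[str, ChannelFeatureSet]]
                       ) -> pd.DataFrame:
    """Long-format per-channel feature table (one row per subject x channel)."""
    rows = []
    for sid, per_channel in per_channel_by_subject.items():
        for ch, feats in per_channel.items():
            row = {"subject_id": sid, "channel": ch}
            row.update(feats.scalar_features())
            rows.append(row)
    return pd.DataFrame(rows)
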