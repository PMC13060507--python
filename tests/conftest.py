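"""Shared fixtures: synthetic subjects, cohorts, and feature tables."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from fluctex import CohortSpec, FeatureTable, SubjectSpec, cohort_feature_table, synth_cohort
from fluctex.spectral_features import CANDIDATE_FEATURES
from fluctex.synth_eeg import synth_recording


def make_subject(band: str = "alpha", f0: float = 10.0, snr_db: float = 20.0,
                 seed: int = 0, **occupancy_override) -> SubjectSpec:
    """Single-oscillator subject spec: 100% occupancy in one band at f0."""
    occupancy = {b: 0.0 for b in ("delta", "theta", "pre_alpha", "alpha", "beta")}
    occupancy[band] = 1.0
    occupancy.update(occupancy_override)
    total = sum(occupancy.values())
    occupancy = {b: v / total for b, v in occupancy.items()}
    band_freqs = {"delta": 3.6, "theta": 5.0, "pre_alpha": 6.5, "alpha": 10.0,
                  "beta": 13.0, band: f0}
    return SubjectSpec(subject_id=f"s{seed}", group="x", occupancy=occupancy,
                       band_freqs=band_freqs, snr_db=snr_db, age=72.0, sex="M",
                       moca=25.0, seed=seed)


def small_recording(spec: SubjectSpec, duration_s: float = 60.0, fs: float = 128.0,
                    channels=("O1", "O2")):
    return synth_recording(spec, duration_s=duration_s, fs=fs, channels=channels)


def random_feature_table(rng: np.random.Generator, n_a: int, n_b: int,
                         shift: dict[str, float] | None = None) -> FeatureTable:
    """Feature table with all 28 candidates drawn i.i.d. N(0,1), optional
    per-column mean shift in group b, and covariates; bypasses EEG synthesis."""
    shift = shift or {}
    n = n_a + n_b
    data = {c: rng.normal(size=n) for c in CANDIDATE_FEATURES}
    for col, delta in shift.items():
        data[col][n_a:] += delta
    data["subject_id"] = [f"s{i}" for i in range(n)]
    data["group"] = ["a"] * n_a + ["b"] * n_b
    data["age"] = rng.normal(73, 6, n)
    data["sex"] = rng.choice(["M", "F"], n)
    data["moca"] = rng.integers(10, 30, n).astype(float)
    return FeatureTable(pd.DataFrame(data))


@pytest.fixture(scope="session")
def paperlike_cohort():
    """Default paper-like cohort (29 CF vs 24 non-CF, seed 1) and its
    extracted feature table; shared across tests because synthesis plus
    extraction of 53 three-minute recordings takes several seconds."""
    spec = CohortSpec(n_cf=29, n_non_cf=24, seed=1)
    pairs, meta = synth_cohort(spec)
    ft = cohort_feature_table(pairs)
    return pairs, meta, ft
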