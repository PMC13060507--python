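"""Spectra, band classification, DF/DFV/DFP/IAF, regional aggregation."""

import numpy as np
import pandas as pd
import pytest

from fluctex import (CANDIDATE_FEATURES, DEFAULT_BANDS, FeatureTable, SubjectRecord,
                     aggregate_regions, build_feature_table, channel_features,
                     classify_band, dominant_frequency, periodogram)
from fluctex.errors import (InputError, InsufficientDataError, ParameterError,
                            RegionEmptyError)
from fluctex.preprocess import EpochArray
from fluctex.spectral_features import (ChannelFeatureSet, EpochSpectra,
                                       RegionFeatures, REGIONS)


def epochs_from_freqs(freqs_per_epoch, fs=128.0, epoch_len_s=2.0, channels=("Cz",),
                      amp=1.0):
    """EpochArray whose epoch e is a pure sinusoid at freqs_per_epoch[e]."""
    n = int(fs * epoch_len_s)
    t = np.arange(n) / fs
    data = np.stack([
        np.tile(amp * np.sin(2 * np.pi * f * t), (len(channels), 1))
        for f in freqs_per_epoch
    ])
    return EpochArray(data, fs, epoch_len_s, list(channels),
                      np.ones(len(freqs_per_epoch), dtype=bool))


# ---------------------------------------------------------------- periodogram

def test_on_grid_sinusoid_concentrates_in_one_bin():
    ep = epochs_from_freqs([10.0])
    spec = periodogram(ep)
    bin10 = np.argmin(np.abs(spec.freqs - 10.0))
    others = np.delete(spec.power[0, 0], bin10)
    assert spec.power[0, 0, bin10] == pytest.approx(0.5, rel=1e-9)  # A^2/2
    assert np.all(others < 1e-10)


def test_zero_signal_gives_zero_spectrum():
    ep = EpochArray(np.zeros((2, 1, 256)), 128.0, 2.0, ["Cz"],
                    np.ones(2, dtype=bool))
    assert np.all(periodogram(ep).power == 0)


@pytest.mark.parametrize("n_samples", [256, 255])  # even and odd epoch lengths
def test_parseval_equality(n_samples):
    """Total one-sided spectral power equals the mean-square amplitude."""
    rng = np.random.default_rng(11)
    data = rng.standard_normal((4, 3, n_samples))
    ep = EpochArray(data, 128.0, n_samples / 128.0, ["Fp1", "Cz", "O1"],
                    np.ones(4, dtype=bool))
    spec = periodogram(ep)
    total = spec.power.sum(axis=-1)
    ms = np.mean(np.square(data), axis=-1)
    np.testing.assert_allclose(total, ms, rtol=1e-6)


def test_frequency_grid_spacing_matches_epoch_length():
    ep = epochs_from_freqs([8.0], fs=256.0, epoch_len_s=2.0)
    spec = periodogram(ep)
    assert spec.freqs[1] - spec.freqs[0] == pytest.approx(0.5)


# ------------------------------------------------------------- band scheme

@pytest.mark.parametrize("f, band", [
    (3.0, "delta"), (4.0, "delta"),
    (4.5, "theta"), (5.5, "theta"),
    (6.0, "pre_alpha"), (7.5, "pre_alpha"),
    (8.0, "alpha"), (10.0, "alpha"), (12.0, "alpha"),
    (12.5, "beta"), (14.0, "beta"), (30.0, "beta"),
    (5.75, "pre_alpha"),  # off-grid gap midpoint, half-open extension
    (4.25, "theta"),
    (12.25, "beta"),
    (0.0, "delta"),
])
def test_classify_band(f, band):
    assert classify_band(f) == band


def test_band_scheme_total_and_disjoint_on_grid():
    """Every 0.5 Hz bin in [3, 14] belongs to exactly one band."""
    for f in np.arange(3.0, 14.01, 0.5):
        hits = [name for name, lo, hi in DEFAULT_BANDS.edges if lo <= f < hi]
        assert len(hits) == 1


def test_negative_frequency_rejected():
    with pytest.raises(ParameterError):
        classify_band(-1.0)


# ------------------------------------------------------- dominant frequency

def test_unique_maximum_found():
    ep = epochs_from_freqs([8.0, 6.0, 11.5])
    spec = periodogram(ep)
    df = dominant_frequency(spec)
    np.testing.assert_array_equal(df[:, 0], [8.0, 6.0, 11.5])


def test_exact_tie_broken_toward_lowest_frequency():
    freqs = np.arange(0, 65) * 0.5
    power = np.zeros((1, 1, 65))
    power[0, 0, np.argmin(np.abs(freqs - 6.0))] = 1.0
    power[0, 0, np.argmin(np.abs(freqs - 8.0))] = 1.0
    spec = EpochSpectra(power, freqs, ["Cz"])
    assert dominant_frequency(spec)[0, 0] == 6.0


def test_window_excluding_all_bins_errors():
    spec = periodogram(epochs_from_freqs([8.0]))
    with pytest.raises(ParameterError):
        dominant_frequency(spec, 100.0, 120.0)


def test_df_robust_to_noise_at_20db():
    """10 Hz + white noise at 20 dB SNR: DF = 10.0 in >= 99 of 100 epochs."""
    rng = np.random.default_rng(2024)
    fs, n = 128.0, 256
    t = np.arange(n) / fs
    sig = np.sin(2 * np.pi * 10.0 * t)
    noise_std = np.sqrt(0.5 / 10 ** (20 / 10))  # sinusoid power A^2/2 = 0.5
    data = sig[None, None, :] + noise_std * rng.standard_normal((100, 1, n))
    ep = EpochArray(data, fs, 2.0, ["Cz"], np.ones(100, dtype=bool))
    df = dominant_frequency(periodogram(ep))
    assert (df[:, 0] == 10.0).sum() >= 99


# -------------------------------------------------------- channel features

def test_constant_df_series():
    ep = epochs_from_freqs([6.0] * 90)
    feats = channel_features(periodogram(ep))["Cz"]
    assert feats.mean_df == 6.0
    assert feats.dfv == 0.0
    assert feats.dfp["pre_alpha"] == 100.0
    assert all(feats.dfp[b] == 0.0 for b in feats.dfp if b != "pre_alpha")


def test_dfv_is_sample_standard_deviation():
    ep = epochs_from_freqs([5.0, 6.0, 7.0])
    feats = channel_features(periodogram(ep))["Cz"]
    assert feats.dfv == pytest.approx(1.0)  # n-1 denominator
    assert feats.mean_df == pytest.approx(6.0)


def test_dfp_mixture_sums_to_100():
    ep = epochs_from_freqs([10.0] * 45 + [6.5] * 45)
    feats = channel_features(periodogram(ep))["Cz"]
    assert feats.dfp["alpha"] == pytest.approx(50.0)
    assert feats.dfp["pre_alpha"] == pytest.approx(50.0)
    assert sum(feats.dfp.values()) == pytest.approx(100.0, abs=1e-9)


def test_iaf_floor_behavior_for_slow_subjects():
    """With no alpha power, the alpha-restricted peak stays within [8, 12]."""
    ep = epochs_from_freqs([6.0, 6.5, 5.0, 7.0])
    feats = channel_features(periodogram(ep))["Cz"]
    assert 8.0 <= feats.mean_iaf <= 12.0


def test_single_epoch_insufficient_for_dfv():
    with pytest.raises(InsufficientDataError):
        channel_features(periodogram(epochs_from_freqs([8.0])))


# ----------------------------------------------------- regional aggregation

def _uniform_channel_features(channels, **overrides):
    out = {}
    for ch in channels:
        vals = {"df": 6.0, "dfv": 1.0, "iaf": 9.0,
                "dfp": {"delta": 0.0, "theta": 0.0, "pre_alpha": 100.0,
                        "alpha": 0.0, "beta": 0.0}}
        if ch in overrides:
            vals.update(overrides[ch])
        out[ch] = ChannelFeatureSet(
            channel=ch, df_series=np.array([6.0, 6.0]), mean_df=vals["df"],
            dfv=vals["dfv"], dfp=vals["dfp"],
            iaf_series=np.array([9.0, 9.0]), mean_iaf=vals["iaf"])
    return out


def test_identical_channels_aggregate_to_same_value():
    all_channels = sorted({c for m in REGIONS.values() for c in m} | {"Cz", "C3", "C4"})
    per_channel = _uniform_channel_features(all_channels)
    regional = aggregate_regions(per_channel)
    for deriv in ("global", "anterior", "temporal", "posterior"):
        assert regional[deriv].values["df"] == 6.0
        assert regional[deriv].complete


def test_posterior_dfp_alpha_mean():
    members = REGIONS["posterior"]
    alphas = [100.0, 50.0, 50.0, 0.0, 0.0]
    overrides = {ch: {"dfp": {"delta": 0.0, "theta": 0.0,
                              "pre_alpha": 100.0 - a, "alpha": a, "beta": 0.0}}
                 for ch, a in zip(members, alphas)}
    per_channel = _uniform_channel_features(members, **overrides)
    regional = aggregate_regions(per_channel, {"posterior": members})
    assert regional["posterior"].values["dfp_alpha"] == pytest.approx(40.0)


def test_incomplete_region_flagged():
    members = [c for c in REGIONS["anterior"] if c != "F7"]
    per_channel = _uniform_channel_features(members)
    regional = aggregate_regions(per_channel, {"anterior": REGIONS["anterior"]})
    ant = regional["anterior"]
    assert (ant.n_available, ant.n_expected) == (6, 7)
    assert not ant.complete
    assert ant.values["df"] == 6.0


def test_empty_region_errors():
    per_channel = _uniform_channel_features(["Fp1"])
    with pytest.raises(RegionEmptyError):
        aggregate_regions(per_channel, {"temporal": REGIONS["temporal"]})


# ----------------------------------------------------------- feature table

def _region_features(df=6.0):
    vals = {"df": df, "dfv": 1.0, "iaf": 9.0, "dfp_delta": 0.0, "dfp_theta": 0.0,
            "dfp_pre_alpha": 100.0, "dfp_alpha": 0.0, "dfp_beta": 0.0}
    return {d: RegionFeatures(d, dict(vals), 5, 5)
            for d in ("global", "anterior", "temporal", "posterior")}


def _subject(sid, group="a", df=6.0):
    return SubjectRecord(sid, group, 70.0, "F", 25.0, _region_features(df))


def test_feature_table_has_28_candidate_columns():
    ft = build_feature_table([_subject("s1"), _subject("s2", "b")])
    assert len(ft.candidate_features) == 28
    assert set(ft.candidate_features) <= set(ft.data.columns)
    # beta prevalence carried but not a candidate
    assert "global_dfp_beta" in ft.data.columns
    assert "global_dfp_beta" not in ft.candidate_features


def test_df_range_per_group():
    subs = [_subject("s1", "a", 5.5), _subject("s2", "a", 6.0),
            _subject("s3", "a", 7.0), _subject("s4", "b", 8.0)]
    ft = build_feature_table(subs)
    assert ft.df_range()["a"] == (5.5, 7.0)
    assert ft.df_range()["b"] == (8.0, 8.0)


def test_single_subject_table():
    ft = build_feature_table([_subject("only")])
    assert len(ft.data) == 1
    assert ft.df_range()["a"] == (6.0, 6.0)


def test_duplicate_subject_ids_rejected():
    with pytest.raises(InputError):
        build_feature_table([_subject("dup"), _subject("dup")])


def test_feature_table_csv_round_trip(tmp_path):
    ft = build_feature_table([_subject("s1"), _subject("s2", "b")])
    path = tmp_path / "features.csv"
    ft.to_csv(path)
    back = FeatureTable.from_csv(path)
    pd.testing.assert_frame_equal(
        back.data[list(CANDIDATE_FEATURES)], ft.data[list(CANDIDATE_FEATURES)])
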