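"""Group-comparison statistics: medians/IQR, Mann-Whitney U with effect
size r, Kruskal-Wallis, chi-square, and Benjamini-Hochberg FDR control.

The two-group contrast compares a case group (index group ``a``, the
CF-like group in the intended application) against a reference group
``b``; the effect size ``r = Z / sqrt(N)`` is signed so that features
tending *larger in the reference group* get positive r.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import InputError, ParameterError
from .spectral_features import CANDIDATE_FEATURE_KINDS, DERIVATIONS, FeatureTable


def median_iqr(x) -> tuple[float, float, float]:
    """Median with 25th/75th percentiles (linear interpolation)."""
    x = np.asarray(x, dtype=float)
    if x.size < 1:
        raise InputError("median_iqr needs at least one observation")
    q1, med, q3 = np.percentile(x, [25, 50, 75])
    return float(med), float(q1), float(q3)


def _tie_corrected_sigma(pooled: np.ndarray, na: int, nb: int) -> float:
    n = na + nb
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = float((counts ** 3 - counts).sum())
    var = na * nb / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    return float(np.sqrt(max(var, 0.0)))


def mann_whitney_r(a, b, method: str = "auto") -> tuple[float, float, float]:
    """Two-sided Mann-Whitney U test with effect size r = Z / sqrt(N).

    The p-value is the exact enumeration value for small tie-free samples
    (n_a + n_b <= 12), and otherwise the normal approximation with tie and
    continuity corrections. Z (hence r) is positive when sample ``b``
    tends larger. A pooled sample with all values identical returns
    (U, 1.0, 0.0) rather than erroring.

    Returns
    -------
    (U, p_two_sided, r) where U is the statistic of sample ``a``.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    na, nb = a.size, b.size
    if na < 2 or nb < 2:
        raise InputError(f"need >= 2 observations per group, got {na} and {nb}")
    pooled = np.concatenate([a, b])
    ranks = stats.rankdata(pooled)
    rb = ranks[na:].sum()
    u_b = rb - nb * (nb + 1) / 2.0
    u_a = na * nb - u_b
    mu = na * nb / 2.0
    sigma = _tie_corrected_sigma(pooled, na, nb)
    if sigma == 0.0:
        return float(u_a), 1.0, 0.0
    # continuity-corrected Z, signed toward the reference sample b
    delta = u_b - mu
    z = (delta - 0.5 * np.sign(delta)) / sigma if delta != 0 else 0.0
    r = float(z / np.sqrt(na + nb))
    has_ties = np.unique(pooled).size < pooled.size
    if method not in ("auto", "exact", "asymptotic"):
        raise ParameterError(f"unknown method {method!r}")
    use_exact = (method == "exact" or
                 (method == "auto" and na + nb <= 12 and not has_ties))
    if use_exact and has_ties:
        raise ParameterError("exact p-value requires a tie-free pooled sample")
    if use_exact:
        p = float(stats.mannwhitneyu(a, b, alternative="two-sided",
                                     method="exact").pvalue)
    else:
        p = float(min(1.0, 2.0 * stats.norm.sf(abs(z))))
    return float(u_a), p, r


def kruskal_wallis(*groups) -> tuple[float, float]:
    """Kruskal-Wallis H test across >= 2 groups (provided for multi-group layouts)."""
    if len(groups) < 2:
        raise InputError("kruskal_wallis needs >= 2 groups")
    res = stats.kruskal(*groups)
    return float(res.statistic), float(res.pvalue)


def chi2_test(table) -> tuple[float, float]:
    """Chi-square test of independence on a contingency table, no Yates correction."""
    res = stats.chi2_contingency(np.asarray(table), correction=False)
    return float(res.statistic), float(res.pvalue)


def bh_fdr(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values), capped at 1."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or np.any(~np.isfinite(p)):
        raise ParameterError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


@dataclass
class ComparisonReport:
    """Per-feature two-group comparison in the shape of the study's Table 1.

    One row per derivation x feature with group medians/IQRs, the raw
    Mann-Whitney p, the BH-adjusted q (joint family over all rows), and
    the signed effect size r.
    """

    table: pd.DataFrame
    group_a: str
    group_b: str

    def significant(self, q_threshold: float = 0.05) -> pd.DataFrame:
        return self.table[self.table["q"] < q_threshold]

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)


def compare_groups(ft: FeatureTable, reference: str | None = None) -> ComparisonReport:
    """Mann-Whitney comparison of every candidate feature between two groups.

    BH-FDR is applied jointly across all 28 derivation x feature tests.
    ``reference`` names group ``b`` (positive r = larger in reference);
    by default the lexicographically later group label, which places a
    ``cf`` vs ``non_cf`` cohort on the intended sign convention.
    """
    groups = ft.groups
    if len(groups) != 2:
        raise InputError(f"exactly two groups required, got {groups}")
    if reference is None:
        reference = groups[1]
    if reference not in groups:
        raise InputError(f"reference group {reference!r} not in {groups}")
    group_a = next(g for g in groups if g != reference)
    da = ft.data[ft.data["group"] == group_a]
    db = ft.data[ft.data["group"] == reference]
    if len(da) < 2 or len(db) < 2:
        raise InputError("each group needs >= 2 subjects")

    rows = []
    for deriv in DERIVATIONS:
        for kind in CANDIDATE_FEATURE_KINDS:
            col = f"{deriv}_{kind}"
            a, b = da[col].to_numpy(float), db[col].to_numpy(float)
            med_a, q1_a, q3_a = median_iqr(a)
            med_b, q1_b, q3_b = median_iqr(b)
            u, p, r = mann_whitney_r(a, b)
            rows.append({
                "derivation": deriv, "feature": kind, "column": col,
                f"median_{group_a}": med_a, f"q1_{group_a}": q1_a,
                f"q3_{group_a}": q3_a,
                f"median_{reference}": med_b, f"q1_{reference}": q1_b,
                f"q3_{reference}": q3_b,
                "U": u, "p": p, "r": r,
            })
    table = pd.DataFrame(rows)
    table["q"] = bh_fdr(table["p"].to_numpy())
    return ComparisonReport(table, group_a, reference)


def demographics_summary(ft: FeatureTable) -> pd.DataFrame:
    """Median (IQR) of age/MoCA and sex counts per group, with group tests."""
    rows = []
    groups = ft.groups
    for var in ("age", "moca"):
        per_group = {g: ft.data.loc[ft.data["group"] == g, var].to_numpy(float)
                     for g in groups}
        entry = {"variable": var}
        for g, x in per_group.items():
            med, q1, q3 = median_iqr(x)
            entry[g] = f"{med:.1f} ({q1:.1f}-{q3:.1f})"
        if len(groups) == 2:
            _, entry["p"], _ = mann_whitney_r(*per_group.values())
        rows.append(entry)
    counts = pd.crosstab(ft.data["sex"], ft.data["group"])
    entry = {"variable": "sex"}
    for g in groups:
        entry[g] = "/".join(f"{lvl}:{counts.loc[lvl, g]}" for lvl in counts.index)
    if counts.shape == (2, 2) or counts.size >= 4:
        _, entry["p"] = chi2_test(counts.to_numpy())
    rows.append(entry)
    return pd.DataFrame(rows)
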