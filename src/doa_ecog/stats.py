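"""Anesthetic-modulation statistics.

Each feature is averaged per (animal, concentration), pooling same-
concentration segments, and then compared between every pair of unequal
concentrations with a two-sided Mann-Whitney U test. False-discovery-rate
control uses the Benjamini-Hochberg step-up procedure; by default each
feature's family is its three concentration pairs (the family structure is
ambiguous in the source protocol, so a per-pair family mode is also exposed
and the active mode is recorded in every report).
"""

from __future__ import annotations

from dataclasses import dataclass
import warnings

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .features import feature_columns

__all__ = [
    "ModulationResult",
    "per_animal_means",
    "mann_whitney_u",
    "bh_fdr",
    "modulation_report",
]

EXACT_MAX_COMBINED_N = 12


@dataclass(frozen=True)
class ModulationResult:
    feature: str
    pair: tuple[float, float]
    u_statistic: float
    p_value: float
    p_adjusted: float
    reject: bool
    medians: dict[float, float]


def per_animal_means(
    table: pd.DataFrame, features: list[str] | None = None
) -> pd.DataFrame:
    """Mean of each feature per (animal, concentration), pooling all windows of
    all same-concentration segments. Animals missing a concentration are
    dropped from that feature's comparisons with a warning."""
    features = features or feature_columns(table)
    means = table.groupby(["animal_id", "concentration"])[features].mean().reset_index()
    counts = means.groupby("animal_id").size()
    n_conc = table["concentration"].nunique()
    incomplete = counts[counts < n_conc].index.tolist()
    if incomplete:
        warnings.warn(f"animals missing concentrations excluded: {incomplete}")
        means = means[~means["animal_id"].isin(incomplete)]
    return means


def mann_whitney_u(
    x: np.ndarray, y: np.ndarray, alternative: str = "two-sided"
) -> tuple[float, float]:
    """Mann-Whitney U with mid-rank tie handling.

    Exact p when the combined sample is small (n1 + n2 <= 12) and tie-free;
    normal approximation with tie correction otherwise. Fully tied samples
    give p = 1.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be nonempty")
    pooled = np.concatenate([x, y])
    if np.all(pooled == pooled[0]):
        return float(x.size * y.size / 2.0), 1.0
    has_ties = np.unique(pooled).size < pooled.size
    method = "exact" if (x.size + y.size <= EXACT_MAX_COMBINED_N and not has_ties) else "asymptotic"
    res = sps.mannwhitneyu(x, y, alternative=alternative, method=method)
    return float(res.statistic), float(res.pvalue)


def bh_fdr(p_values: np.ndarray, q: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up: rejection flags and adjusted p-values
    (adjusted p = min over k' >= k of m*p_(k')/k', capped at 1)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return np.zeros(0, dtype=bool), np.zeros(0)
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    reject, p_adj, _, _ = multipletests(p, alpha=q, method="fdr_bh")
    return reject, p_adj


def modulation_report(
    table: pd.DataFrame,
    q: float = 0.05,
    features: list[str] | None = None,
    family: str = "per_feature",
) -> pd.DataFrame:
    """Pairwise U tests of per-animal feature means across concentrations.

    ``family`` controls the BH grouping: "per_feature" corrects each feature's
    set of concentration pairs together (default); "per_pair" corrects across
    features within each concentration pair.
    """
    if family not in ("per_feature", "per_pair"):
        raise ValueError("family must be 'per_feature' or 'per_pair'")
    features = features or feature_columns(table)
    means = per_animal_means(table, features)
    n_animals = means["animal_id"].nunique()
    degenerate = n_animals < 2
    if degenerate:
        warnings.warn("fewer than 2 animals: all p-values reported as 1")
    concs = sorted(means["concentration"].unique())
    pairs = [(c1, c2) for i, c1 in enumerate(concs) for c2 in concs[i + 1 :]]
    rows = []
    for feat in features:
        by_conc = {c: means.loc[means["concentration"] == c, feat].dropna().to_numpy() for c in concs}
        medians = {c: (float(np.median(v)) if v.size else float("nan")) for c, v in by_conc.items()}
        for c1, c2 in pairs:
            if degenerate or by_conc[c1].size == 0 or by_conc[c2].size == 0:
                u, p = float("nan"), 1.0
            else:
                u, p = mann_whitney_u(by_conc[c1], by_conc[c2])
            rows.append(
                {
                    "feature": feat,
                    "c1": c1,
                    "c2": c2,
                    "U": u,
                    "p": p,
                    **{f"median_c{c}": medians[c] for c in concs},
                }
            )
    report = pd.DataFrame(rows)
    report["p_adj"] = np.nan
    report["reject"] = False
    group_key = "feature" if family == "per_feature" else ["c1", "c2"]
    for _, idx in report.groupby(group_key).groups.items():
        rej, padj = bh_fdr(report.loc[idx, "p"].to_numpy(), q=q)
        report.loc[idx, "p_adj"] = padj
        report.loc[idx, "reject"] = rej
    report.attrs["bh_family_mode"] = family
    report.attrs["q"] = q
    return report
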