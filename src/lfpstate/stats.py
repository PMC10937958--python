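"""Condition comparisons honoring the Animal/Session/Channel nesting.

Electrophysiological observations are not exchangeable across animals:
channels repeat within animals and sessions repeat within animals (and,
for between-drug contrasts, within condition).  The primary comparison is
therefore a hierarchical permutation test that permutes condition labels
at the session level within each animal, with the test statistic computed
on animal-level means — a distribution-free stand-in for a nested ANOVA.
Rank-based group tests (Wilcoxon rank sum, Kruskal-Wallis) cover the
animal-level state-similarity comparisons, and Benjamini-Hochberg FDR is
applied when a test is repeated across the 11 structures.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as scstats
from statsmodels.stats.multitest import multipletests


@dataclass
class ComparisonResult:
    estimate: float            # condition effect (mean difference / statistic)
    p: float
    method: str
    n: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if np.isfinite(self.p) and not (0.0 <= self.p <= 1.0):
            raise ValueError("p-value outside [0, 1]")


def _check_design(df: pd.DataFrame, value: str) -> None:
    needed = {value, "condition", "animal", "session"}
    missing = needed - set(df.columns)
    if missing:
        raise ValueError(f"design is missing columns: {sorted(missing)}")
    if df[value].isna().any():
        raise ValueError("value column contains missing observations")


def hierarchical_permutation_test(design: pd.DataFrame, value: str,
                                  n_perm: int = 1000, seed: int = 0,
                                  rank_based: bool = False) -> ComparisonResult:
    """Two-condition comparison permuting session labels within animal.

    The observed statistic T is the difference of animal-level means, where
    an animal's per-condition value is the mean of its session means (each
    session mean pools that session's channels).  Under the null the
    assignment of sessions to conditions is exchangeable within an animal,
    so condition labels are permuted at the session level within each
    animal; p = (1 + #{|T*| >= |T|}) / (1 + n_perm).  ``rank_based``
    replaces values by global ranks first, making the test invariant to
    monotone transforms.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    _check_design(design, value)
    df = design.copy()
    conditions = sorted(df["condition"].unique())
    if len(conditions) != 2:
        raise ValueError(f"need exactly 2 conditions, got {conditions}")
    if rank_based:
        df[value] = scstats.rankdata(df[value])

    # session-level means (pool channels within a session)
    sess = (df.groupby(["animal", "session", "condition"], sort=True)[value]
              .mean().reset_index())
    # exchangeability: animals contributing sessions under >= 2 conditions
    per_animal = sess.groupby("animal")["condition"].nunique()
    usable = per_animal[per_animal >= 2].index
    if len(usable) == 0:
        raise ValueError(
            "no animal has sessions under both conditions; session-level "
            "permutation is impossible for this design")
    sess = sess.loc[sess["animal"].isin(usable)].reset_index(drop=True)

    animals = sess["animal"].astype("category")
    a_code = animals.cat.codes.to_numpy()
    n_animals = len(animals.cat.categories)
    vals = sess[value].to_numpy(float)
    labels = (sess["condition"] == conditions[1]).to_numpy().astype(np.int64)

    def statistic(lab: np.ndarray) -> float:
        # animal x condition means via bincount; within-animal permutation
        # preserves label counts, so every cell stays populated
        cell = a_code * 2 + lab
        sums = np.bincount(cell, weights=vals, minlength=2 * n_animals)
        cnts = np.bincount(cell, minlength=2 * n_animals)
        means = sums / np.maximum(cnts, 1)
        present = (cnts[0::2] > 0) & (cnts[1::2] > 0)
        diffs = means[0::2][present] - means[1::2][present]
        return float(diffs.mean())

    t_obs = statistic(labels)
    rng = np.random.default_rng(seed)
    animal_idx = [np.flatnonzero(a_code == c) for c in range(n_animals)]
    count = 0
    for _ in range(n_perm):
        perm = labels.copy()
        for idx in animal_idx:
            perm[idx] = perm[idx][rng.permutation(len(idx))]
        if abs(statistic(perm)) >= abs(t_obs) - 1e-12:
            count += 1
    p = (1 + count) / (1 + n_perm)
    return ComparisonResult(
        estimate=t_obs, p=p, method="hierarchical_permutation",
        n={"animals": int(len(usable)), "sessions": int(len(sess)),
           "observations": int(len(df)), "permutations": n_perm})


def rank_sum_test(group_a: np.ndarray, group_b: np.ndarray,
                  min_n: int = 3) -> ComparisonResult:
    """Wilcoxon rank sum (two-sided); exact distribution for small samples."""
    a = np.asarray(group_a, float)
    b = np.asarray(group_b, float)
    if len(a) < min_n or len(b) < min_n:
        raise ValueError(
            f"groups of {len(a)} and {len(b)} animal-level values are below "
            f"the minimum of {min_n}; test suppressed")
    method = "exact" if (len(a) <= 20 and len(b) <= 20
                         and len(np.unique(np.concatenate([a, b])))
                         == len(a) + len(b)) else "asymptotic"
    res = scstats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return ComparisonResult(
        estimate=float(np.median(a) - np.median(b)), p=float(res.pvalue),
        method=f"rank_sum_{method}", n={"a": len(a), "b": len(b)})


def kruskal_wallis(groups: list[np.ndarray]) -> ComparisonResult:
    """Kruskal-Wallis H (tie-corrected) with chi-square p-value."""
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    if sum(len(g) for g in groups) < 5:
        raise ValueError("need at least 5 observations in total")
    flat = np.concatenate([np.asarray(g, float) for g in groups])
    if np.all(flat == flat[0]):
        import warnings
        warnings.warn("all values tied; Kruskal-Wallis degenerate")
        return ComparisonResult(estimate=0.0, p=1.0, method="kruskal_wallis",
                                n={"groups": len(groups)})
    h, p = scstats.kruskal(*groups)
    return ComparisonResult(estimate=float(h), p=float(p),
                            method="kruskal_wallis",
                            n={"groups": len(groups),
                               "total": int(len(flat))})


def fdr_adjust(p_values: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values (structure-wise maps)."""
    _, p_adj, *_ = multipletests(np.asarray(p_values, float), method="fdr_bh")
    return p_adj


def structure_significance_map(results: pd.DataFrame, alpha: float = 0.05
                               ) -> pd.DataFrame:
    """Per-structure significance map with raw and FDR-adjusted calls.

    ``results`` needs columns (structure, estimate, p).  The sign of the
    estimate gives the direction (reduction vs increase).
    """
    out = results.copy()
    out["p_fdr"] = fdr_adjust(out["p"].to_numpy())
    out["significant_raw"] = out["p"] < alpha
    out["significant_fdr"] = out["p_fdr"] < alpha
    out["direction"] = np.sign(out["estimate"])
    return out
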