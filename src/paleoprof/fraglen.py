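"""Fragment-length statistics and group comparisons.

Per-sample / per-taxon length profiles, the median displacement of a read
class (e.g. host reads) against a reference class, Cohen's d effect sizes,
the 400-read per-(sample, taxon) subsampling normalization, and rank-based
group tests (Mann-Whitney U for two groups, Kruskal-Wallis above).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Hashable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class LengthProfile:
    label: str
    lengths: np.ndarray
    median: float
    mean: float
    iqr: float


def length_stats(lengths: Sequence[float], label: str = "") -> LengthProfile:
    """Summary statistics of a non-empty length distribution.

    Median uses the mean-of-middle-two convention for even counts; IQR is
    the 75th minus 25th percentile (linear interpolation).
    """
    arr = np.asarray(lengths, dtype=float)
    if arr.size == 0:
        raise ValueError(f"length profile {label!r}: empty input")
    q25, q75 = np.percentile(arr, [25, 75])
    return LengthProfile(
        label=label,
        lengths=arr,
        median=float(np.median(arr)),
        mean=float(arr.mean()),
        iqr=float(q75 - q25),
    )


def median_displacement(
    group_lengths: Sequence[float], reference_lengths: Sequence[float]
) -> float:
    """median(group) - median(reference); negative means the group is shorter."""
    group = np.asarray(group_lengths, dtype=float)
    reference = np.asarray(reference_lengths, dtype=float)
    if group.size == 0 or reference.size == 0:
        raise ValueError("median_displacement requires non-empty inputs")
    return float(np.median(group) - np.median(reference))


def cohens_d(group_a: Sequence[float], group_b: Sequence[float]) -> float:
    """Standardized mean difference (mean_a - mean_b) / pooled SD.

    Pooled SD uses the (n_a + n_b - 2) denominator; antisymmetric under
    argument swap.  Raises on zero pooled SD.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("cohens_d requires >= 2 values per group")
    pooled_var = ((a.size - 1) * a.var(ddof=1) + (b.size - 1) * b.var(ddof=1)) / (
        a.size + b.size - 2
    )
    if pooled_var == 0.0:
        raise ValueError("zero pooled standard deviation")
    return float((a.mean() - b.mean()) / np.sqrt(pooled_var))


@dataclass(frozen=True)
class SubsampleConfig:
    """Per-(sample, taxon) normalization: sample groups down to a common size
    (default 400 reads) so sample-specific depth does not distort pooled
    length distributions."""

    n_per_group: int = 400
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_per_group < 1:
            raise ValueError("n_per_group must be >= 1")


def subsample_per_taxon(
    groups: Mapping[Hashable, Sequence],
    config: SubsampleConfig | None = None,
) -> tuple[dict[Hashable, list], dict[Hashable, int]]:
    """Sample each group without replacement to exactly n_per_group members.

    Groups smaller than n_per_group are excluded and tallied (key -> size).
    Deterministic given config.seed; groups are processed in sorted key
    order so dict insertion order cannot change the draws.
    """
    config = config or SubsampleConfig()
    rng = np.random.default_rng(config.seed)
    sampled: dict[Hashable, list] = {}
    excluded: dict[Hashable, int] = {}
    for key in sorted(groups, key=repr):
        members = list(groups[key])
        if len(members) < config.n_per_group:
            excluded[key] = len(members)
            continue
        if len(members) == config.n_per_group:
            sampled[key] = members
        else:
            idx = rng.choice(len(members), size=config.n_per_group, replace=False)
            sampled[key] = [members[i] for i in sorted(idx)]
    return sampled, excluded


# ---------------------------------------------------------------------------
# Rank tests
# ---------------------------------------------------------------------------

@dataclass
class RankTestResult:
    statistic: float
    pvalue: float
    method: str  # 'exact' or 'asymptotic'


def mann_whitney(
    x: Sequence[float],
    y: Sequence[float],
    alternative: str = "two-sided",
    exact_max_product: int = 400,
) -> RankTestResult:
    """Mann-Whitney U test (statistic is U of ``x``).

    Exact null distribution when there are no ties and nx*ny <=
    ``exact_max_product``; otherwise the tie-corrected normal approximation
    with continuity correction.  Degenerate all-equal pooled data gives p=1.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("mann_whitney requires non-empty groups")
    pooled = np.concatenate([x, y])
    has_ties = np.unique(pooled).size < pooled.size
    if np.all(pooled == pooled[0]):
        u = x.size * y.size / 2.0
        return RankTestResult(u, 1.0, "asymptotic")
    if not has_ties and x.size * y.size <= exact_max_product:
        method = "exact"
    else:
        method = "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative=alternative, method=method)
    return RankTestResult(float(res.statistic), float(res.pvalue), method)


@dataclass
class GroupComparison:
    key: str
    groups: dict[str, np.ndarray]          # group label -> pooled lengths
    medians: dict[str, float]
    test: RankTestResult | None            # None when a single group
    test_name: str | None


def group_compare(
    lengths_by_taxon: Mapping[str, Sequence[float]],
    metadata: pd.DataFrame,
    key: str,
) -> GroupComparison:
    """Pool per-taxon length distributions by a metadata category and test.

    ``key`` is a metadata column ('gram', 's_layer' or 'gc_class'); every
    taxon must carry a non-null value for it or a KeyError lists the
    offenders.  Two groups are compared with Mann-Whitney U, more with
    Kruskal-Wallis; a single group yields no test.
    """
    if key not in metadata.columns:
        raise KeyError(f"metadata has no column {key!r}")
    missing = [
        t
        for t in lengths_by_taxon
        if t not in metadata.index or pd.isna(metadata.loc[t, key])
    ]
    if missing:
        raise KeyError(f"taxa missing metadata {key!r}: {sorted(missing)}")
    pooled: dict[str, list[float]] = {}
    for taxon, lengths in lengths_by_taxon.items():
        group = str(metadata.loc[taxon, key])
        pooled.setdefault(group, []).extend(float(v) for v in lengths)
    groups = {g: np.asarray(v, dtype=float) for g, v in sorted(pooled.items())}
    medians = {g: float(np.median(v)) for g, v in groups.items()}
    if len(groups) == 1:
        return GroupComparison(key, groups, medians, None, None)
    if len(groups) == 2:
        a, b = groups.values()
        return GroupComparison(key, groups, medians, mann_whitney(a, b), "mann_whitney")
    stat, p = stats.kruskal(*groups.values())
    return GroupComparison(
        key, groups, medians, RankTestResult(float(stat), float(p), "asymptotic"),
        "kruskal_wallis",
    )


# ---------------------------------------------------------------------------
# Plot helper (not part of the tested contract)
# ---------------------------------------------------------------------------

def plot_length_profiles(profiles: Sequence[LengthProfile], path):
    """Plain overlaid length histograms, one per profile."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    for profile in profiles:
        ax.hist(profile.lengths, bins=40, histtype="step", label=profile.label,
                density=True)
    ax.set_xlabel("fragment length (bp)")
    ax.set_ylabel("density")
    ax.legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
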