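"""Community composition: relative abundance, Bray-Curtis, PCoA, alpha
diversity and nested source classification.

The source classification sorts each species into an ordered category path
within a controlled nested vocabulary (environmental vs human-microbiome
branches, with oral / pathobiont / opportunistic-pathogen refinements) and
reports per-sample proportions at every node, exportable as Krona-style
text (count, tab-separated path).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from skbio import DistanceMatrix
from skbio.diversity.alpha import shannon, observed_features
from skbio.stats.ordination import pcoa as _skbio_pcoa

CONTROLLED_VOCABULARY = frozenset(
    {
        "environmental",
        "uncultured environmental",
        "human microbiome",
        "human oral",
        "pathobiont",
        "opportunistic pathogen",
    }
)

UNCLASSIFIED = "unclassified"


def relative_abundance(table: pd.DataFrame) -> pd.DataFrame:
    """Row-normalize a sample x species count table to proportions.

    Raises ValueError naming any sample with zero total.
    """
    totals = table.sum(axis=1)
    zero = totals[totals <= 0]
    if len(zero):
        raise ValueError(f"samples with zero total counts: {list(zero.index)}")
    return table.div(totals, axis=0)


def bray_curtis(table: pd.DataFrame, normalize: bool = True) -> pd.DataFrame:
    """Pairwise Bray-Curtis dissimilarity BC(a,b) = sum|a-b| / sum(a+b).

    Computed on proportion-normalized rows by default (raw counts with
    ``normalize=False``).  Returns a symmetric zero-diagonal DataFrame.
    """
    if len(table) < 2:
        raise ValueError("bray_curtis requires >= 2 samples")
    data = relative_abundance(table) if normalize else table.astype(float)
    condensed = pdist(data.to_numpy(), metric="braycurtis")
    matrix = squareform(condensed)
    return pd.DataFrame(matrix, index=table.index, columns=table.index)


@dataclass
class PCoAResult:
    coordinates: pd.DataFrame        # samples x axes (PC1, PC2, ...)
    eigenvalues: np.ndarray          # all eigenvalues, descending (negatives kept)
    variance_explained: np.ndarray   # per retained axis, over positive eigenvalues


def pcoa(dissimilarity: pd.DataFrame, n_axes: int | None = None) -> PCoAResult:
    """Classical scaling (principal coordinates) of a dissimilarity matrix.

    Eigendecomposition of the double-centered Gower matrix via scikit-bio;
    axes are ordered by eigenvalue.  Negative eigenvalues (non-Euclidean
    input such as Bray-Curtis) are reported, not dropped; variance explained
    is computed over positive eigenvalues only and no correction is applied.
    """
    matrix = np.asarray(dissimilarity, dtype=float)
    if matrix.ndim != 2 or matrix.shape[0] != matrix.shape[1]:
        raise ValueError("dissimilarity matrix must be square")
    if not np.allclose(matrix, matrix.T, atol=1e-12):
        raise ValueError("dissimilarity matrix must be symmetric")
    ids = [str(i) for i in dissimilarity.index]
    result = _skbio_pcoa(DistanceMatrix(matrix, ids), method="eigh")
    eigvals = result.eigvals.to_numpy()
    coords = result.samples
    positive = eigvals[eigvals > 0]
    n_keep = positive.size if n_axes is None else min(n_axes, coords.shape[1])
    coords = coords.iloc[:, :n_keep]
    coords.columns = [f"PC{i + 1}" for i in range(coords.shape[1])]
    coords.index = dissimilarity.index
    var_exp = np.where(
        eigvals[:n_keep] > 0, eigvals[:n_keep] / positive.sum(), 0.0
    )
    return PCoAResult(
        coordinates=coords, eigenvalues=eigvals, variance_explained=var_exp
    )


def alpha_diversity(table: pd.DataFrame, metric: str = "shannon") -> pd.Series:
    """Per-sample alpha diversity: Shannon index H = -sum p ln p (natural
    log) by default, or 'richness' (observed species)."""
    totals = table.sum(axis=1)
    if (totals <= 0).any():
        bad = list(totals[totals <= 0].index)
        raise ValueError(f"samples with zero total counts: {bad}")
    if metric == "shannon":
        values = [shannon(row.to_numpy(), base=np.e) for _, row in table.iterrows()]
    elif metric == "richness":
        values = [observed_features(row.to_numpy()) for _, row in table.iterrows()]
    else:
        raise ValueError(f"unknown alpha-diversity metric {metric!r}")
    return pd.Series(values, index=table.index, name=metric, dtype=float)


# ---------------------------------------------------------------------------
# Nested source classification
# ---------------------------------------------------------------------------

@dataclass
class SourceProfile:
    """Per-sample proportions over the nested source scheme.

    ``proportions`` maps every node path (tuple of categories from the root)
    to its proportion; a parent's proportion equals the sum of its children
    and leaf proportions sum to 1.
    """

    sample_id: str
    proportions: dict[tuple[str, ...], float]
    leaf_counts: dict[tuple[str, ...], float]


def parse_source_path(path: str) -> tuple[str, ...]:
    """Parse a '>'-joined nested category path, validating the vocabulary."""
    parts = tuple(p.strip() for p in str(path).split(">") if p.strip())
    for part in parts:
        if part not in CONTROLLED_VOCABULARY:
            raise ValueError(
                f"source category {part!r} not in controlled vocabulary "
                f"{sorted(CONTROLLED_VOCABULARY)}"
            )
    if not parts:
        raise ValueError("empty source path")
    return parts


def classify_sources(
    table: pd.DataFrame, metadata: pd.DataFrame
) -> list[SourceProfile]:
    """Aggregate per-sample read proportions over the nested source scheme.

    ``metadata`` must carry a ``source_path`` column ('>'-joined categories
    from the controlled vocabulary).  Species absent from the metadata (or
    with a null path) are collected under an explicit 'unclassified' leaf —
    tracked, never an error.
    """
    paths: dict[str, tuple[str, ...]] = {}
    for species in table.columns:
        if species in metadata.index and not pd.isna(
            metadata.loc[species].get("source_path")
        ):
            paths[species] = parse_source_path(metadata.loc[species, "source_path"])
        else:
            paths[species] = (UNCLASSIFIED,)
    proportions = relative_abundance(table)
    profiles: list[SourceProfile] = []
    for sample_id, row in proportions.iterrows():
        node: dict[tuple[str, ...], float] = {}
        leaves: dict[tuple[str, ...], float] = {}
        counts = table.loc[sample_id]
        for species, p in row.items():
            path = paths[species]
            leaves[path] = leaves.get(path, 0.0) + float(counts[species])
            for depth in range(1, len(path) + 1):
                prefix = path[:depth]
                node[prefix] = node.get(prefix, 0.0) + float(p)
        profiles.append(
            SourceProfile(sample_id=str(sample_id), proportions=node,
                          leaf_counts=leaves)
        )
    return profiles


def krona_text(profile: SourceProfile) -> str:
    """Krona text export: one line per leaf path, leading count column."""
    lines = []
    for path in sorted(profile.leaf_counts):
        count = profile.leaf_counts[path]
        count_str = f"{count:g}"
        lines.append("\t".join([count_str, *path]))
    return "\n".join(lines) + "\n"


def write_krona(profiles: Sequence[SourceProfile], out_dir: str | Path) -> list[Path]:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = []
    for profile in profiles:
        path = out_dir / f"{profile.sample_id}.krona.txt"
        path.write_text(krona_text(profile))
        written.append(path)
    return written
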