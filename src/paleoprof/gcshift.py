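"""GC-content-vs-fragment-length curves and shift-onset detection.

Degradation removes short AT-rich fragments preferentially (lower melting
temperature), so in a degraded sample the mean GC of surviving reads rises
as fragment length falls.  This module bins reads by length, standardizes
per-bin mean GC against a baseline built from the longest bins (where
survival is unbiased), and reports the onset length below which the curve
is persistently shifted by at least ``z_threshold`` standard scores.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class GCShiftConfig:
    """Binning and detection parameters.

    bin_width: length-bin width in bp (1 matches per-length curves).
    min_reads_per_bin: bins below this count are ineligible (mean too noisy).
    z_threshold: standard-score shift regarded as substantial.
    persistence: number of consecutive shifted bins required before an onset
        is called, guarding against single-bin noise.
    baseline_quantile: fraction of the *longest* eligible bins that defines
        the baseline mean and SD (long fragments survive regardless of GC).
    min_length: eligible length floor, inherited from read QC.
    """

    bin_width: int = 1
    min_reads_per_bin: int = 50
    z_threshold: float = 1.0
    persistence: int = 3
    baseline_quantile: float = 0.25
    min_length: int = 30

    def __post_init__(self) -> None:
        if self.bin_width < 1:
            raise ValueError("bin_width must be >= 1")
        if self.z_threshold <= 0:
            raise ValueError("z_threshold must be > 0")
        if self.persistence < 1:
            raise ValueError("persistence must be >= 1")
        if not (0.0 < self.baseline_quantile <= 1.0):
            raise ValueError("baseline_quantile must be in (0, 1]")


@dataclass
class GCShiftResult:
    table: pd.DataFrame          # length, mean_gc, count, eligible, z
    onset_length: int | None
    baseline_mean: float
    baseline_sd: float


def bin_mean_gc(
    lengths: Sequence[float],
    gc_fractions: Sequence[float],
    config: GCShiftConfig | None = None,
) -> pd.DataFrame:
    """Mean GC fraction and read count per half-open length bin [L, L+width).

    Reads below config.min_length are excluded before binning.  Bins with
    fewer than min_reads_per_bin reads are flagged ineligible.  Raises on
    empty input.
    """
    config = config or GCShiftConfig()
    lengths = np.asarray(lengths, dtype=float)
    gc = np.asarray(gc_fractions, dtype=float)
    if lengths.size != gc.size:
        raise ValueError("lengths and gc_fractions must be the same size")
    keep = lengths >= config.min_length
    lengths, gc = lengths[keep], gc[keep]
    if lengths.size == 0:
        raise ValueError("no reads at or above the minimum length")
    lo = int(np.floor(lengths.min() / config.bin_width) * config.bin_width)
    bin_start = (
        (np.floor((lengths - lo) / config.bin_width)).astype(np.int64)
        * config.bin_width
        + lo
    )
    frame = pd.DataFrame({"length": bin_start, "gc": gc})
    grouped = frame.groupby("length")["gc"].agg(["mean", "count"]).reset_index()
    grouped = grouped.rename(columns={"mean": "mean_gc"})
    grouped["eligible"] = grouped["count"] >= config.min_reads_per_bin
    return grouped[["length", "mean_gc", "count", "eligible"]]


def zscore_curve(
    binned: pd.DataFrame, config: GCShiftConfig | None = None
) -> pd.DataFrame:
    """Standardize eligible per-bin means against the longest-bin baseline.

    Baseline = the longest ceil(baseline_quantile * n_eligible) eligible
    bins; z = (bin mean - baseline mean) / baseline SD (ddof=1).  A
    perfectly flat curve returns z = 0 everywhere; zero baseline SD with
    non-flat bins raises, advising a larger baseline.  Requires >= 4
    eligible bins.
    """
    config = config or GCShiftConfig()
    eligible = binned[binned["eligible"]].sort_values("length").reset_index(drop=True)
    if len(eligible) < 4:
        raise ValueError(f"need >= 4 eligible bins, got {len(eligible)}")
    n_base = max(2, int(np.ceil(config.baseline_quantile * len(eligible))))
    baseline = eligible.tail(n_base)
    base_mean = float(baseline["mean_gc"].mean())
    base_sd = float(baseline["mean_gc"].std(ddof=1))
    out = binned.copy()
    out.attrs["baseline_mean"] = base_mean
    out.attrs["baseline_sd"] = base_sd
    if base_sd == 0.0:
        if np.allclose(eligible["mean_gc"], base_mean):
            out["z"] = np.where(out["eligible"], 0.0, np.nan)
            return out
        raise ValueError(
            "baseline SD is zero but the curve is not flat; "
            "increase baseline_quantile to include more bins"
        )
    out["z"] = np.where(out["eligible"], (out["mean_gc"] - base_mean) / base_sd, np.nan)
    return out


def detect_shift_onset(
    zcurve: pd.DataFrame, config: GCShiftConfig | None = None
) -> int | None:
    """Largest length L such that every eligible bin at length <= L is
    shifted (z >= z_threshold), provided that run spans at least
    ``persistence`` consecutive eligible bins; None if never satisfied."""
    config = config or GCShiftConfig()
    eligible = zcurve[zcurve["eligible"]].sort_values("length")
    run = 0
    onset = None
    for _, row in eligible.iterrows():
        if row["z"] >= config.z_threshold:
            run += 1
            if run >= config.persistence:
                onset = int(row["length"])
        else:
            break
    return onset


def gc_shift(
    lengths: Sequence[float],
    gc_fractions: Sequence[float],
    config: GCShiftConfig | None = None,
) -> GCShiftResult:
    """Full analysis: bin, standardize, detect onset."""
    config = config or GCShiftConfig()
    binned = bin_mean_gc(lengths, gc_fractions, config)
    zcurve = zscore_curve(binned, config)
    onset = detect_shift_onset(zcurve, config)
    return GCShiftResult(
        table=zcurve,
        onset_length=onset,
        baseline_mean=zcurve.attrs.get("baseline_mean", float("nan")),
        baseline_sd=zcurve.attrs.get("baseline_sd", float("nan")),
    )
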