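"""Terminal misincorporation profiling and overhang-deamination parameter fits.

Ancient DNA carries an excess of C->T substitutions at 5' fragment ends
(and complementary G->A at 3' ends in double-stranded libraries) that decays
geometrically into the molecule.  This module estimates the positionwise
substitution profile from gap-free alignments, fits the three-parameter
overhang model

    r_i = delta_s + (delta_d - delta_s) * (1 - lam)**i,

calls damage presence/absence with a binomial confidence bound against the
interior baseline, and compares paired damage rates with an exact Wilcoxon
signed-rank test.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .io_qc import AlignmentRecord, write_table
from .sim_reads import BriggsParams

_A, _C, _G, _T = (ord(c) for c in "ACGT")


@dataclass
class DamageProfile:
    """Positionwise terminal substitution frequencies.

    ct5[i-1] is the C->T frequency at 5' position i (1-based); ga3[j-1] the
    G->A frequency at 3' position j.  Frequencies are NaN where the
    opportunity count is zero (undefined, not zero).
    """

    k: int
    ct5: np.ndarray
    ga3: np.ndarray
    ct5_opportunities: np.ndarray
    ct5_hits: np.ndarray
    ga3_opportunities: np.ndarray
    ga3_hits: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "position": np.arange(1, self.k + 1),
                "ct5": self.ct5,
                "ct5_opportunities": self.ct5_opportunities,
                "ga3": self.ga3,
                "ga3_opportunities": self.ga3_opportunities,
            }
        )

    def write(self, path: str | Path, meta: dict | None = None) -> None:
        write_table(self.to_frame(), path, meta=meta, index=False)


def misincorporation_profile(
    alignments: Iterable[AlignmentRecord], k: int = 15
) -> DamageProfile:
    """Count terminal C->T (5') and G->A (3') substitutions over ``k`` positions.

    Reads shorter than 2k contribute each position to only one terminus:
    the 5' half (position i <= ceil(L/2)) to the 5' profile, the rest to 3'.
    """
    ct5_opp = np.zeros(k, dtype=np.int64)
    ct5_hit = np.zeros(k, dtype=np.int64)
    ga3_opp = np.zeros(k, dtype=np.int64)
    ga3_hit = np.zeros(k, dtype=np.int64)
    for aln in alignments:
        ref = np.frombuffer(aln.ref_seq.encode(), dtype=np.uint8)
        read = np.frombuffer(aln.read_seq.encode(), dtype=np.uint8)
        n = ref.size
        if n == 0:
            continue
        i5 = np.arange(1, n + 1)  # 1-based from 5'
        i3 = i5[::-1]             # 1-based from 3'
        if n >= 2 * k:
            in5 = i5 <= k
            in3 = i3 <= k
        else:
            half = -(-n // 2)  # ceil(n/2)
            in5 = (i5 <= k) & (i5 <= half)
            in3 = (i3 <= k) & (i5 > half)
        ref_c = ref == _C
        ref_g = ref == _G
        sel5 = in5 & ref_c
        sel3 = in3 & ref_g
        if sel5.any():
            idx = i5[sel5] - 1
            np.add.at(ct5_opp, idx, 1)
            np.add.at(ct5_hit, idx[read[sel5] == _T], 1)
        if sel3.any():
            idx = i3[sel3] - 1
            np.add.at(ga3_opp, idx, 1)
            np.add.at(ga3_hit, idx[read[sel3] == _A], 1)
    with np.errstate(invalid="ignore", divide="ignore"):
        ct5 = np.where(ct5_opp > 0, ct5_hit / np.maximum(ct5_opp, 1), np.nan)
        ga3 = np.where(ga3_opp > 0, ga3_hit / np.maximum(ga3_opp, 1), np.nan)
    return DamageProfile(
        k=k,
        ct5=ct5,
        ga3=ga3,
        ct5_opportunities=ct5_opp,
        ct5_hits=ct5_hit,
        ga3_opportunities=ga3_opp,
        ga3_hits=ga3_hit,
    )


# ---------------------------------------------------------------------------
# Parameter fit
# ---------------------------------------------------------------------------

@dataclass
class BriggsFit:
    """Result of fitting the overhang model to a damage profile."""

    params: BriggsParams
    rss: float
    n_positions: int
    lam_identifiable: bool

    def to_dict(self) -> dict:
        return {
            "lam": self.params.lam,
            "delta_d": self.params.delta_d,
            "delta_s": self.params.delta_s,
            "rss": self.rss,
            "n_positions": self.n_positions,
            "lam_identifiable": self.lam_identifiable,
        }


def fit_briggs(
    profile: DamageProfile, pool_ga3: bool = False, min_positions: int = 5
) -> BriggsFit:
    """Least-squares fit of r_i = delta_s + (delta_d-delta_s)(1-lam)^i.

    Fits the 5' C->T profile by default; ``pool_ga3`` adds the 3' G->A
    profile as additional observations of the same law.  Grid-initialized
    over lam, then refined with bounded least squares.  A flat-zero profile
    returns delta_d = delta_s = 0 with lam flagged unidentifiable.
    """
    pos_list = []
    rate_list = []
    defined5 = ~np.isnan(profile.ct5)
    pos_list.append(np.arange(1, profile.k + 1)[defined5])
    rate_list.append(profile.ct5[defined5])
    if pool_ga3:
        defined3 = ~np.isnan(profile.ga3)
        pos_list.append(np.arange(1, profile.k + 1)[defined3])
        rate_list.append(profile.ga3[defined3])
    positions = np.concatenate(pos_list).astype(float)
    rates = np.concatenate(rate_list)
    if positions.size < min_positions:
        raise ValueError(
            f"need >= {min_positions} positions with defined rates, got {positions.size}"
        )
    if np.allclose(rates, 0.0):
        return BriggsFit(
            params=BriggsParams(lam=1.0, delta_d=0.0, delta_s=0.0),
            rss=0.0,
            n_positions=int(positions.size),
            lam_identifiable=False,
        )

    def residuals(theta):
        lam, dd, ds = theta
        return ds + (dd - ds) * (1.0 - lam) ** positions - rates

    best = None
    for lam0 in np.linspace(0.02, 0.98, 25):
        x = (1.0 - lam0) ** positions
        # linear LS for (ds, dd-ds) at fixed lam, clipped into bounds
        design = np.column_stack([np.ones_like(x), x])
        coef, *_ = np.linalg.lstsq(design, rates, rcond=None)
        ds0 = float(np.clip(coef[0], 0.0, 1.0))
        dd0 = float(np.clip(coef[0] + coef[1], 0.0, 1.0))
        rss0 = float(np.sum((design @ coef - rates) ** 2))
        if best is None or rss0 < best[0]:
            best = (rss0, (lam0, dd0, ds0))
    sol = optimize.least_squares(
        residuals,
        x0=np.array(best[1]),
        bounds=([1e-9, 0.0, 0.0], [1.0, 1.0, 1.0]),
        xtol=1e-15,
        ftol=1e-15,
        gtol=1e-15,
    )
    lam, dd, ds = sol.x
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # recovered dd < ds is a fit outcome, not misuse
        params = BriggsParams(lam=float(lam), delta_d=float(dd), delta_s=float(ds))
    return BriggsFit(
        params=params,
        rss=float(np.sum(sol.fun**2)),
        n_positions=int(positions.size),
        lam_identifiable=True,
    )


# ---------------------------------------------------------------------------
# Damage presence
# ---------------------------------------------------------------------------

@dataclass
class DamageVerdict:
    """Presence/absence call with its evidence.

    status is 'positive', 'negative' or 'indeterminate' (under-powered:
    fewer than ``min_opportunities`` reference C at position 1).
    """

    status: str
    terminal_rate: float
    terminal_lower_bound: float
    baseline_rate: float
    n_opportunities: int

    @property
    def is_damaged(self) -> bool | None:
        if self.status == "indeterminate":
            return None
        return self.status == "positive"


def damage_presence(
    profile: DamageProfile,
    min_terminal_rate: float = 0.05,
    baseline_positions: Sequence[int] | None = None,
    alpha: float = 0.05,
    min_opportunities: int = 100,
) -> DamageVerdict:
    """Call damage present iff ct5[1] >= min_terminal_rate and its one-sided
    (1-alpha) Clopper-Pearson lower bound exceeds the mean interior rate.

    Interior baseline defaults to positions 11..k.  Fewer than
    ``min_opportunities`` opportunities at position 1 yields 'indeterminate'.
    """
    if baseline_positions is None:
        baseline_positions = range(11, profile.k + 1)
    n1 = int(profile.ct5_opportunities[0])
    x1 = int(profile.ct5_hits[0])
    if n1 == 0 or np.isnan(profile.ct5[0]):
        raise ValueError("ct5 at position 1 is undefined (zero opportunities)")
    base_idx = [p - 1 for p in baseline_positions if 1 <= p <= profile.k]
    base_rates = profile.ct5[base_idx]
    baseline = float(np.nanmean(base_rates)) if np.any(~np.isnan(base_rates)) else 0.0
    rate1 = float(profile.ct5[0])
    if n1 < min_opportunities:
        return DamageVerdict("indeterminate", rate1, np.nan, baseline, n1)
    lower = float(stats.beta.ppf(alpha, x1, n1 - x1 + 1)) if x1 > 0 else 0.0
    positive = rate1 >= min_terminal_rate and lower > baseline
    return DamageVerdict(
        "positive" if positive else "negative", rate1, lower, baseline, n1
    )


# ---------------------------------------------------------------------------
# Paired comparison (Wilcoxon signed-rank)
# ---------------------------------------------------------------------------

@dataclass
class PairedTestResult:
    statistic: float  # W+ = sum of ranks of positive differences
    pvalue: float
    n_used: int       # pairs remaining after dropping zero differences
    method: str       # 'exact' or 'normal'


def _signed_rank_exact_pvalue(ranks: np.ndarray, w_plus: float) -> float:
    """Exact two-sided p for the signed-rank statistic via shift convolution.

    Mid-ranks are doubled to integers so tied ranks are handled exactly.
    """
    scaled = np.rint(2 * ranks).astype(np.int64)
    total = int(scaled.sum())
    dist = np.zeros(total + 1)
    dist[0] = 1.0
    for r in scaled:
        shifted = np.zeros_like(dist)
        shifted[r:] = dist[: total + 1 - r]
        dist = dist + shifted
    dist /= dist.sum()
    w2 = int(round(2 * w_plus))
    cdf = float(dist[: w2 + 1].sum())
    sf = float(dist[w2:].sum())
    return min(1.0, 2.0 * min(cdf, sf))


def wilcoxon_signed_rank(
    a: Sequence[float], b: Sequence[float], exact_max_n: int = 25
) -> PairedTestResult:
    """Two-sided Wilcoxon signed-rank test for paired samples.

    Zero differences are dropped; ties in |difference| receive mid-ranks.
    Exact distribution (sign-flip enumeration via convolution) for
    n <= ``exact_max_n`` pairs, tie-corrected normal approximation above.
    All-zero differences give p = 1 with a warning.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired vectors must have equal length")
    d = a - b
    d = d[d != 0]
    n = d.size
    if n == 0:
        warnings.warn("all paired differences are zero; p = 1", stacklevel=2)
        return PairedTestResult(statistic=0.0, pvalue=1.0, n_used=0, method="exact")
    ranks = stats.rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    if n <= exact_max_n:
        p = _signed_rank_exact_pvalue(ranks, w_plus)
        return PairedTestResult(w_plus, p, n, "exact")
    mean = n * (n + 1) / 4.0
    _, tie_counts = np.unique(ranks, return_counts=True)
    tie_term = float(np.sum(tie_counts**3 - tie_counts)) / 48.0
    var = n * (n + 1) * (2 * n + 1) / 24.0 - tie_term
    # continuity correction: the statistic lives on a half-integer lattice
    deviation = max(abs(w_plus - mean) - 0.5, 0.0)
    p = float(2.0 * stats.norm.sf(deviation / np.sqrt(var)))
    return PairedTestResult(w_plus, min(1.0, p), n, "normal")


def compare_paired_damage(
    rates_a: Sequence[float], rates_b: Sequence[float]
) -> PairedTestResult:
    """Compare paired per-individual damage rates (e.g. dentin vs calculus
    terminal C->T rates) with the Wilcoxon signed-rank test."""
    return wilcoxon_signed_rank(rates_a, rates_b)
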