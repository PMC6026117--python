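"""Three-criterion authentication of candidate host (endogenous) reads.

A candidate read is retained in the high-confidence set when it
(1) meets strict mapping criteria — at most one mismatch per 50 aligned
    bases, with a floor of one allowed mismatch;
(2) is assigned to the target taxon by the (externally produced) lowest
    common ancestor assignment; and
(3) belongs to a read set whose pooled terminal misincorporation profile
    shows ancient-DNA damage (sample-level verdict, not per read).

Deamination-consistent mismatches (C->T in the 5' half, G->A in the 3'
half of the read) are excluded from the mismatch budget by default, so the
strict filter does not penalize authentically damaged ancient reads.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from .damage import DamageVerdict, damage_presence, misincorporation_profile
from .io_qc import AlignmentRecord

UNASSIGNED = "unassigned"


@dataclass(frozen=True)
class AuthConfig:
    """Authentication thresholds.

    mismatches_per_bp: strict-mapping budget (default 1/50); the allowance
        for a read of length L is max(1, floor(L * mismatches_per_bp)).
    target_taxon: label a read's LCA assignment must equal exactly.
    damage_aware: exclude deamination-consistent mismatches from the budget.
    min_terminal_rate: terminal C->T rate required for the damage verdict.
    """

    target_taxon: str = "Homo_sapiens"
    mismatches_per_bp: float = 1.0 / 50.0
    damage_aware: bool = True
    min_terminal_rate: float = 0.05
    profile_k: int = 15

    def __post_init__(self) -> None:
        if self.mismatches_per_bp <= 0:
            raise ValueError("mismatches_per_bp must be > 0")

    def allowance(self, length: int) -> int:
        return max(1, int(length * self.mismatches_per_bp))


def effective_edit_distance(aln: AlignmentRecord, damage_aware: bool = True) -> int:
    """Mismatch count, optionally discounting deamination-consistent columns:
    reference C read T in the 5' half, reference G read A in the 3' half."""
    if not damage_aware:
        return aln.edit_distance
    half = -(-aln.length // 2)  # ceil(L/2): first half is 5', rest 3'
    n = 0
    for pos, ref, read in aln.mismatches:
        if ref == "C" and read == "T" and pos < half:
            continue
        if ref == "G" and read == "A" and pos >= half:
            continue
        n += 1
    return n


def strict_map_filter(
    alignments: Sequence[AlignmentRecord], config: AuthConfig
) -> tuple[set[str], float]:
    """Pass set of read ids meeting the per-length mismatch allowance, plus
    the fraction passing."""
    passed: set[str] = set()
    total = 0
    for aln in alignments:
        total += 1
        if effective_edit_distance(aln, config.damage_aware) <= config.allowance(
            aln.length
        ):
            passed.add(aln.read_id)
    fraction = len(passed) / total if total else 0.0
    return passed, fraction


def assignment_concordance(
    assignments: Mapping[str, str],
    target_taxon: str,
    read_ids: Iterable[str] | None = None,
) -> tuple[set[str], float, int]:
    """Pass set of reads whose assignment equals ``target_taxon`` exactly.

    ``read_ids`` restricts (and completes) the universe: reads present there
    but absent from the assignment table count as unassigned.  Returns
    (pass set, fraction passing, number unassigned).
    """
    universe = set(read_ids) if read_ids is not None else set(assignments)
    passed: set[str] = set()
    unassigned = 0
    for rid in universe:
        label = assignments.get(rid, UNASSIGNED)
        if label == target_taxon:
            passed.add(rid)
        elif label == UNASSIGNED:
            unassigned += 1
    fraction = len(passed) / len(universe) if universe else 0.0
    return passed, fraction, unassigned


@dataclass
class AuthReport:
    n_input: int
    n_pass_strict: int
    n_pass_assignment: int
    n_high_confidence: int
    fraction_strict: float
    fraction_assignment: float
    n_unassigned: int
    damage: DamageVerdict | None

    @property
    def damage_status(self) -> str:
        return self.damage.status if self.damage is not None else "indeterminate"

    def to_dict(self) -> dict:
        return {
            "n_input": self.n_input,
            "n_pass_strict": self.n_pass_strict,
            "n_pass_assignment": self.n_pass_assignment,
            "n_high_confidence": self.n_high_confidence,
            "fraction_strict": round(self.fraction_strict, 6),
            "fraction_assignment": round(self.fraction_assignment, 6),
            "n_unassigned": self.n_unassigned,
            "damage_status": self.damage_status,
        }


def authenticate(
    alignments: Sequence[AlignmentRecord],
    assignments: Mapping[str, str],
    config: AuthConfig,
) -> tuple[set[str], AuthReport]:
    """Run the three criteria; returns (high-confidence read ids, report).

    The high-confidence set is the intersection of the strict-mapping and
    assignment pass sets; the damage criterion is then evaluated once on
    that set's pooled misincorporation profile.  An empty surviving set
    yields an 'indeterminate' damage verdict.
    """
    read_ids = [aln.read_id for aln in alignments]
    strict_pass, frac_strict = strict_map_filter(alignments, config)
    assign_pass, frac_assign, n_unassigned = assignment_concordance(
        assignments, config.target_taxon, read_ids
    )
    surviving = strict_pass & assign_pass
    survivors = [aln for aln in alignments if aln.read_id in surviving]
    verdict: DamageVerdict | None = None
    if survivors:
        profile = misincorporation_profile(survivors, k=config.profile_k)
        if profile.ct5_opportunities[0] > 0:
            verdict = damage_presence(
                profile, min_terminal_rate=config.min_terminal_rate
            )
    report = AuthReport(
        n_input=len(alignments),
        n_pass_strict=len(strict_pass),
        n_pass_assignment=len(assign_pass & set(read_ids)),
        n_high_confidence=len(surviving),
        fraction_strict=frac_strict,
        fraction_assignment=frac_assign,
        n_unassigned=n_unassigned,
        damage=verdict,
    )
    return surviving, report


def write_report(report: AuthReport, path: str | Path) -> None:
    """Key-value TSV export of an authentication report."""
    with open(path, "w") as out:
        out.write("key\tvalue\n")
        for key, value in report.to_dict().items():
            out.write(f"{key}\t{value}\n")
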