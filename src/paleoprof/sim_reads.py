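"""Synthetic ancient-metagenome read simulation with known ground truth.

Generates multi-taxon samples whose reads carry the hallmarks of ancient
DNA — short lognormal-ish fragment lengths, terminal cytosine deamination
under a geometric-overhang model, melting-temperature-dependent fragment
survival, and an undamaged modern-contaminant fraction — together with a
per-read truth table so every downstream estimator has an oracle.

The damage model: a double-stranded fragment carries single-stranded
overhangs at both ends whose length is Geometric(lam) on {0,1,2,...}, so
position i (1-based from a terminus) is single-stranded with probability
(1-lam)**i.  A cytosine deaminates (read as C->T) with probability delta_d
when single-stranded and delta_s otherwise; the complementary strand's
deamination appears as G->A measured from the read's 3' end.  The marginal
C->T rate at 5' position i is therefore

    r_i = delta_s + (delta_d - delta_s) * (1 - lam)**i.

Fragment survival is modelled through a Marmur–Doty-style melting
temperature proxy Tm = 64.9 + 41*(gc_count - 16.4)/length (degrees C),
which is monotone increasing in GC at fixed length and in length at fixed
GC fraction — short AT-rich fragments melt, high-GC short fragments persist.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .io_qc import AlignmentRecord, ReadRecord, gc_fraction, revcomp, write_fastq

_ACGT = frozenset(b"ACGT")

_A, _C, _G, _T = (ord(c) for c in "ACGT")


def _as_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ReferenceGenome:
    """A reference sequence with its taxon label."""

    taxon_id: str
    sequence: str

    def __post_init__(self) -> None:
        if not set(self.sequence.encode()) <= _ACGT:
            raise ValueError(f"reference {self.taxon_id!r}: sequence must be over A/C/G/T")

    @property
    def genomic_gc(self) -> float:
        return gc_fraction(self.sequence)

    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def gc_cumsum(self) -> np.ndarray:
        """Cumulative G+C count; gc in [a,b) is gc_cumsum[b]-gc_cumsum[a]."""
        arr = np.frombuffer(self.sequence.encode(), dtype=np.uint8)
        is_gc = (arr == _G) | (arr == _C)
        out = np.zeros(len(arr) + 1, dtype=np.int64)
        np.cumsum(is_gc, out=out[1:])
        return out


def random_genome(taxon_id: str, length: int, gc: float, seed) -> ReferenceGenome:
    """I.i.d. random genome with expected GC fraction ``gc``."""
    rng = _as_rng(seed)
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    bases = rng.choice(np.frombuffer(b"ACGT", dtype=np.uint8), size=length, p=p)
    return ReferenceGenome(taxon_id, bases.tobytes().decode())


@dataclass(frozen=True)
class LengthModel:
    """Fragment length distribution.

    ``lognormal``: location is the median length in bp, scale the log-space
    sigma; draws are rounded and clipped to [min_len, max_len].
    ``empirical``: resample (with replacement) from ``lengths``.
    """

    family: str = "lognormal"
    location: float = 70.0
    scale: float = 0.35
    min_len: int = 20
    max_len: int = 250
    lengths: tuple[int, ...] | None = None

    def __post_init__(self) -> None:
        if self.family not in ("lognormal", "empirical"):
            raise ValueError(f"unknown length-model family {self.family!r}")
        if self.min_len < 1 or self.max_len < self.min_len:
            raise ValueError("require 1 <= min_len <= max_len")
        if self.family == "empirical" and not self.lengths:
            raise ValueError("empirical length model requires lengths")

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        if self.family == "lognormal":
            draws = rng.lognormal(mean=np.log(self.location), sigma=self.scale, size=n)
            lengths = np.rint(draws).astype(np.int64)
        else:
            lengths = rng.choice(np.asarray(self.lengths, dtype=np.int64), size=n)
        return np.clip(lengths, self.min_len, self.max_len)

    def shifted(self, delta_bp: float) -> "LengthModel":
        """Same model with the median displaced by ``delta_bp``."""
        return replace(self, location=self.location + delta_bp)


def melting_temperature(length, gc_count):
    """Marmur–Doty-style Tm proxy in degrees C (vectorized)."""
    return 64.9 + 41.0 * (np.asarray(gc_count, dtype=float) - 16.4) / np.asarray(
        length, dtype=float
    )


@dataclass(frozen=True)
class SurvivalModel:
    """Fragment survival probability model.

    mode 'none': every fragment survives.
    mode 'hard_threshold': pure length cutoff — survive iff length >= midpoint (bp).
    mode 'logistic_tm': logistic(steepness * (Tm(length, gc_count) - midpoint)),
    midpoint in degrees C; monotone non-decreasing in GC at fixed length and
    in length at fixed GC fraction.
    mode 'length_gated_tm': fragments of at least ``midpoint`` bp always
    survive; shorter fragments survive with the logistic-Tm probability
    against the melting point of a ``midpoint``-bp fragment at the
    calibration GC — short fragments persist only when GC-enriched, the
    survival bias that produces a GC-vs-length shift with a sharp onset at
    ``midpoint`` bp.
    """

    mode: str = "none"
    midpoint: float = 0.0
    steepness: float = 1.0
    calibration_gc: float | None = None

    def __post_init__(self) -> None:
        if self.mode not in ("none", "hard_threshold", "logistic_tm", "length_gated_tm"):
            raise ValueError(f"unknown survival mode {self.mode!r}")
        if self.mode == "length_gated_tm" and self.calibration_gc is None:
            raise ValueError("length_gated_tm requires calibration_gc")

    @classmethod
    def none(cls) -> "SurvivalModel":
        return cls(mode="none")

    @classmethod
    def hard_threshold(cls, length_bp: float) -> "SurvivalModel":
        return cls(mode="hard_threshold", midpoint=length_bp)

    @classmethod
    def logistic_tm(cls, midpoint_c: float, steepness: float = 1.0) -> "SurvivalModel":
        return cls(mode="logistic_tm", midpoint=midpoint_c, steepness=steepness)

    @classmethod
    def sharp_length_cutoff(
        cls, length_bp: float, gc: float, steepness: float = 10.0
    ) -> "SurvivalModel":
        """Length-gated GC selection: fragments >= length_bp always survive,
        shorter fragments only if their melting temperature reaches that of
        a length_bp fragment at GC fraction ``gc`` — the GC-dependent
        analogue of a hard length cutoff at ``length_bp``."""
        return cls(
            mode="length_gated_tm",
            midpoint=length_bp,
            steepness=steepness,
            calibration_gc=gc,
        )


def survival_probability(length, gc_count, model: SurvivalModel):
    """Per-fragment survival probability in [0,1] (vectorized).

    Raises ValueError if any gc_count exceeds its length or is negative.
    """
    length = np.asarray(length, dtype=float)
    gc_count = np.asarray(gc_count, dtype=float)
    if np.any(gc_count > length) or np.any(gc_count < 0):
        raise ValueError("gc_count must satisfy 0 <= gc_count <= length")
    if model.mode == "none":
        p = np.ones_like(length)
    elif model.mode == "hard_threshold":
        p = (length >= model.midpoint).astype(float)
    elif model.mode == "logistic_tm":
        tm = melting_temperature(length, gc_count)
        p = 1.0 / (1.0 + np.exp(-model.steepness * (tm - model.midpoint)))
    else:  # length_gated_tm
        tm = melting_temperature(length, gc_count)
        tm_cut = melting_temperature(
            model.midpoint, model.calibration_gc * model.midpoint
        )
        p = 1.0 / (1.0 + np.exp(-model.steepness * (tm - tm_cut)))
        p = np.where(length >= model.midpoint, 1.0, p)
    return p if p.ndim else float(p)


@dataclass(frozen=True)
class BriggsParams:
    """Overhang-deamination parameters: lam (geometric overhang parameter),
    delta_d (single-stranded C->T probability), delta_s (double-stranded)."""

    lam: float = 0.3
    delta_d: float = 0.4
    delta_s: float = 0.01

    def __post_init__(self) -> None:
        if not (0.0 < self.lam <= 1.0):
            raise ValueError("lam must be in (0, 1]")
        for name in ("delta_d", "delta_s"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0, 1]")
        if self.delta_d < self.delta_s:
            warnings.warn(
                "delta_d < delta_s: single-stranded deamination is expected "
                "to exceed double-stranded",
                stacklevel=2,
            )

    def expected_rate(self, positions) -> np.ndarray:
        """Marginal terminal C->T rate r_i = delta_s + (delta_d-delta_s)(1-lam)^i
        at 1-based terminal positions ``positions``."""
        i = np.asarray(positions, dtype=float)
        return self.delta_s + (self.delta_d - self.delta_s) * (1.0 - self.lam) ** i


@dataclass(frozen=True)
class SampleConfig:
    """Everything needed to simulate one sample deterministically."""

    taxa: tuple[tuple[ReferenceGenome, float], ...]
    n_reads: int
    length_model: LengthModel = LengthModel()
    survival: SurvivalModel = SurvivalModel()
    damage: BriggsParams = BriggsParams()
    contaminant_fraction: float = 0.0
    seed: int = 0
    sample_id: str = "sample"
    error_rate: float = 0.0  # optional uniform sequencing-error rate, off by default

    def __post_init__(self) -> None:
        if self.n_reads < 0:
            raise ValueError("n_reads must be >= 0")
        if self.n_reads > 0 and not self.taxa:
            raise ValueError("taxa list is empty")
        if self.taxa:
            total = sum(a for _, a in self.taxa)
            if abs(total - 1.0) > 1e-9:
                raise ValueError(f"taxon abundances sum to {total}, expected 1")
        if not (0.0 <= self.contaminant_fraction <= 1.0):
            raise ValueError("contaminant_fraction must be in [0, 1]")


@dataclass(frozen=True)
class TruthRecord:
    """Ground truth for one emitted read.  Coordinates are 0-based half-open
    on the reference; damaged_positions are 0-based read coordinates."""

    read_id: str
    taxon_id: str
    start: int
    end: int
    strand: str
    length: int
    damaged_positions: tuple[int, ...]
    is_contaminant: bool

    def __post_init__(self) -> None:
        if self.end - self.start != self.length:
            raise ValueError(f"truth {self.read_id!r}: end - start != length")
        if any(p < 0 or p >= self.length for p in self.damaged_positions):
            raise ValueError(f"truth {self.read_id!r}: damaged position out of read")


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------

def draw_fragments(
    ref: ReferenceGenome, n: int, model: LengthModel, seed
) -> list[tuple[int, int, str]]:
    """Draw ``n`` fragment intervals (start, end, strand) uniformly from ``ref``.

    Lengths come from ``model`` (clipped to its range), starts are uniform
    over valid placements, strands are equiprobable.  Deterministic given seed.
    """
    if len(ref) <= model.max_len:
        raise ValueError(
            f"reference {ref.taxon_id!r} (length {len(ref)}) is shorter than "
            f"the length model's max_len {model.max_len}"
        )
    if n == 0:
        return []
    rng = _as_rng(seed)
    lengths = model.sample(n, rng)
    starts = np.floor(rng.random(n) * (len(ref) - lengths + 1)).astype(np.int64)
    strands = rng.random(n) < 0.5
    return [
        (int(s), int(s + l), "-" if m else "+")
        for s, l, m in zip(starts, lengths, strands)
    ]


def fragment_gc_counts(
    ref: ReferenceGenome, fragments: Sequence[tuple[int, int, str]]
) -> np.ndarray:
    """G+C count per fragment interval (strand-independent)."""
    cum = ref.gc_cumsum
    starts = np.array([f[0] for f in fragments], dtype=np.int64)
    ends = np.array([f[1] for f in fragments], dtype=np.int64)
    return cum[ends] - cum[starts]


def apply_damage(
    sequence: str, params: BriggsParams, seed
) -> tuple[str, list[int]]:
    """Deaminate one fragment; returns (damaged sequence, 0-based positions hit).

    Overhang lengths at each end are Geometric(lam) on {0,1,...}; a C at a
    5'-single-stranded position (or a G at a 3'-single-stranded position)
    converts with probability delta_d, elsewhere with probability delta_s.
    Only C->T and G->A substitutions are introduced; length is unchanged.
    """
    arr = np.frombuffer(sequence.encode(), dtype=np.uint8).copy()
    bad = ~np.isin(arr, np.frombuffer(b"ACGT", dtype=np.uint8))
    if bad.any():
        pos = int(np.flatnonzero(bad)[0])
        raise ValueError(f"non-ACGT character {sequence[pos]!r} at position {pos}")
    n = arr.size
    if n == 0:
        return "", []
    rng = _as_rng(seed)
    # geometric(lam) on {1,2,...} minus 1 gives P(overhang >= i) = (1-lam)^i
    over5 = rng.geometric(params.lam) - 1
    over3 = rng.geometric(params.lam) - 1
    pos5 = np.arange(1, n + 1)          # 1-based from 5'
    pos3 = pos5[::-1]                   # 1-based from 3'
    p_ct = np.where(pos5 <= over5, params.delta_d, params.delta_s)
    p_ga = np.where(pos3 <= over3, params.delta_d, params.delta_s)
    u = rng.random(n)
    hit_c = (arr == _C) & (u < p_ct)
    hit_g = (arr == _G) & (u < p_ga)
    arr[hit_c] = _T
    arr[hit_g] = _A
    positions = np.flatnonzero(hit_c | hit_g)
    return arr.tobytes().decode(), [int(p) for p in positions]


def inject_mismatches(sequence: str, n_mismatches: int, seed) -> str:
    """Substitute ``n_mismatches`` distinct positions with a uniformly random
    different base — a stand-in for divergent or error-laden contaminant reads."""
    rng = _as_rng(seed)
    arr = np.frombuffer(sequence.encode(), dtype=np.uint8).copy()
    n_mismatches = min(n_mismatches, arr.size)
    if n_mismatches == 0:
        return sequence
    sites = rng.choice(arr.size, size=n_mismatches, replace=False)
    alphabet = np.frombuffer(b"ACGT", dtype=np.uint8)
    for s in sites:
        choices = alphabet[alphabet != arr[s]]
        arr[s] = rng.choice(choices)
    return arr.tobytes().decode()


def simulate_reads(
    config: SampleConfig,
) -> tuple[list[ReadRecord], list[TruthRecord]]:
    """Simulate a sample in memory.

    Pipeline per read: choose taxon by abundance -> draw fragment ->
    survival-thin -> orient (minus strand reverse-complemented) ->
    deaminate (skipped for the contaminant fraction) -> optional uniform
    sequencing error.  Emitted read count is <= n_reads because survival
    thins fragments.  Deterministic given config.seed.
    """
    rng = np.random.default_rng(config.seed)
    reads: list[ReadRecord] = []
    truths: list[TruthRecord] = []
    if config.n_reads == 0:
        return reads, truths

    taxa = list(config.taxa)
    abundances = np.array([a for _, a in taxa])
    assignment = rng.choice(len(taxa), size=config.n_reads, p=abundances)
    counter = 0
    for t_idx, (ref, _) in enumerate(taxa):
        n_t = int(np.sum(assignment == t_idx))
        if n_t == 0:
            continue
        frags = draw_fragments(ref, n_t, config.length_model, rng)
        gc_counts = fragment_gc_counts(ref, frags)
        lengths = np.array([end - start for start, end, _ in frags])
        p_surv = survival_probability(lengths, gc_counts, config.survival)
        keep = rng.random(n_t) < p_surv
        for frag, kept in zip(frags, keep):
            if not kept:
                continue
            start, end, strand = frag
            fragment = ref.sequence[start:end]
            if strand == "-":
                fragment = revcomp(fragment)
            contaminant = bool(rng.random() < config.contaminant_fraction)
            if contaminant:
                seq, damaged = fragment, []
            else:
                seq, damaged = apply_damage(fragment, config.damage, rng)
            if config.error_rate > 0.0:
                err = rng.random(len(seq)) < config.error_rate
                if err.any():
                    arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
                    alphabet = np.frombuffer(b"ACGT", dtype=np.uint8)
                    for s in np.flatnonzero(err):
                        arr[s] = rng.choice(alphabet[alphabet != arr[s]])
                    seq = arr.tobytes().decode()
            read_id = f"{config.sample_id}:{ref.taxon_id}:{counter:06d}"
            counter += 1
            reads.append(
                ReadRecord(
                    read_id=read_id,
                    sequence=seq,
                    qualities="I" * len(seq),
                    sample_id=config.sample_id,
                    taxon_id=ref.taxon_id,
                )
            )
            truths.append(
                TruthRecord(
                    read_id=read_id,
                    taxon_id=ref.taxon_id,
                    start=start,
                    end=end,
                    strand=strand,
                    length=end - start,
                    damaged_positions=tuple(damaged),
                    is_contaminant=contaminant,
                )
            )
    return reads, truths


TRUTH_COLUMNS = (
    "read_id",
    "taxon_id",
    "start",
    "end",
    "strand",
    "length",
    "damaged_positions",
    "is_contaminant",
)


def write_truth(truths: Iterable[TruthRecord], path: str | Path) -> int:
    n = 0
    with open(path, "w") as out:
        out.write("\t".join(TRUTH_COLUMNS) + "\n")
        for t in truths:
            out.write(
                "\t".join(
                    [
                        t.read_id,
                        t.taxon_id,
                        str(t.start),
                        str(t.end),
                        t.strand,
                        str(t.length),
                        ",".join(str(p) for p in t.damaged_positions),
                        "1" if t.is_contaminant else "0",
                    ]
                )
                + "\n"
            )
            n += 1
    return n


def read_truth(path: str | Path) -> list[TruthRecord]:
    truths: list[TruthRecord] = []
    with open(path) as handle:
        header = handle.readline().rstrip("\n").split("\t")
        if tuple(header) != TRUTH_COLUMNS:
            raise ValueError(f"{path}: unexpected truth-table header {header}")
        for line in handle:
            f = line.rstrip("\n").split("\t")
            truths.append(
                TruthRecord(
                    read_id=f[0],
                    taxon_id=f[1],
                    start=int(f[2]),
                    end=int(f[3]),
                    strand=f[4],
                    length=int(f[5]),
                    damaged_positions=tuple(
                        int(p) for p in f[6].split(",") if p != ""
                    ),
                    is_contaminant=f[7] == "1",
                )
            )
    return truths


def simulate_sample(
    config: SampleConfig, fastq_path: str | Path, truth_path: str | Path
) -> tuple[list[ReadRecord], list[TruthRecord]]:
    """Simulate and write a FASTQ plus its truth TSV; returns the records."""
    reads, truths = simulate_reads(config)
    write_fastq(reads, fastq_path)
    write_truth(truths, truth_path)
    return reads, truths


def perfect_alignments(
    reads: Sequence[ReadRecord],
    truths: Sequence[TruthRecord],
    references: dict[str, ReferenceGenome],
) -> list[AlignmentRecord]:
    """Place simulated reads back on their true reference intervals.

    The resulting records carry read/reference columns in read orientation,
    so every mismatch is a simulated damage or error event — the alignment
    oracle for the damage and authentication stages.
    """
    by_id = {t.read_id: t for t in truths}
    out: list[AlignmentRecord] = []
    for read in reads:
        t = by_id[read.read_id]
        ref = references[t.taxon_id]
        ref_sub = ref.sequence[t.start : t.end]
        if t.strand == "-":
            ref_sub = revcomp(ref_sub)
        out.append(
            AlignmentRecord(
                read_id=read.read_id,
                reference_id=t.taxon_id,
                position=t.start,
                strand=t.strand,
                read_seq=read.sequence,
                ref_seq=ref_sub,
            )
        )
    return out
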