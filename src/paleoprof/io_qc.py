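"""Read/write the pipeline's standard formats and apply read-level QC.

Formats handled here are deliberately plain-text: FASTQ (4-line records),
a header-optional SAM subset (CIGAR restricted to M/=/X; mismatches
reconstructed from the MD tag), and headered TSV tables.  Alignments with
indels or clips are rejected with a counted warning rather than partially
parsed, because every downstream statistic (terminal misincorporation,
edit-distance filters) assumes a gap-free read-to-reference column map.
"""

from __future__ import annotations

import re
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np
import pandas as pd
from Bio.SeqIO.QualityIO import FastqGeneralIterator

PHRED_OFFSET = 33

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(sequence: str) -> str:
    """Reverse-complement a nucleotide string (A/C/G/T/N)."""
    return sequence.translate(_COMPLEMENT)[::-1]


def gc_fraction(sequence: str) -> float:
    """Fraction of G+C bases; 0.0 for the empty string."""
    if not sequence:
        return 0.0
    return (sequence.count("G") + sequence.count("C")) / len(sequence)


# ---------------------------------------------------------------------------
# Record types
# ---------------------------------------------------------------------------

@dataclass
class ReadRecord:
    """A sequenced fragment after adapter removal and pair merging.

    ``gc_fraction`` and ``length`` are derived from ``sequence`` at
    construction; ``n_count`` tallies ambiguous bases.
    """

    read_id: str
    sequence: str
    qualities: str
    sample_id: str | None = None
    taxon_id: str | None = None
    length: int = field(init=False)
    gc_fraction: float = field(init=False)
    n_count: int = field(init=False)

    def __post_init__(self) -> None:
        if len(self.sequence) != len(self.qualities):
            raise ValueError(
                f"read {self.read_id!r}: sequence length {len(self.sequence)} "
                f"!= quality length {len(self.qualities)}"
            )
        self.length = len(self.sequence)
        self.gc_fraction = gc_fraction(self.sequence)
        self.n_count = self.sequence.count("N")

    @property
    def mean_quality(self) -> float:
        if not self.qualities:
            return 0.0
        return float(np.mean([ord(c) - PHRED_OFFSET for c in self.qualities]))


@dataclass
class AlignmentRecord:
    """A read placed gap-free on a reference.

    ``read_seq`` and ``ref_seq`` are stored in the orientation of the read
    as sequenced (5'->3' of the molecule); for minus-strand placements the
    reference substring is therefore reverse-complemented.  ``position`` is
    the 0-based leftmost reference coordinate of the placement.
    """

    read_id: str
    reference_id: str
    position: int
    strand: str
    read_seq: str
    ref_seq: str
    mapq: int | None = None
    edit_distance: int = field(init=False)

    def __post_init__(self) -> None:
        if len(self.read_seq) != len(self.ref_seq):
            raise ValueError(
                f"alignment {self.read_id!r}: read/reference length mismatch "
                f"({len(self.read_seq)} vs {len(self.ref_seq)}) — indels are not supported"
            )
        if self.strand not in "+-":
            raise ValueError(f"alignment {self.read_id!r}: strand must be '+' or '-'")
        self.edit_distance = sum(
            1 for a, b in zip(self.read_seq, self.ref_seq) if a != b
        )

    @property
    def length(self) -> int:
        return len(self.read_seq)

    @property
    def pairs(self) -> list[tuple[int, str, str]]:
        """(read position, reference base, read base) per aligned column."""
        return [
            (i, r, q)
            for i, (r, q) in enumerate(zip(self.ref_seq, self.read_seq))
        ]

    @property
    def mismatches(self) -> list[tuple[int, str, str]]:
        return [(i, r, q) for i, r, q in self.pairs if r != q]


@dataclass
class QCConfig:
    """Read-level quality control thresholds.

    Defaults follow common ancient-metagenome practice: minimum mean base
    quality 20 (Phred) and minimum fragment length 30 bp.  The quality
    threshold is applied to the read-mean quality (see module docs).
    """

    min_base_quality: float = 20.0
    min_length: int = 30


# ---------------------------------------------------------------------------
# FASTQ
# ---------------------------------------------------------------------------

def read_fastq(path: str | Path, sample_id: str | None = None) -> Iterator[ReadRecord]:
    """Lazily stream ReadRecords from a FASTQ file.

    Raises ValueError naming the (0-based) record index on truncated or
    malformed records.
    """
    index = 0
    with open(path) as handle:
        iterator = FastqGeneralIterator(handle)
        while True:
            try:
                title, seq, qual = next(iterator)
            except StopIteration:
                return
            except ValueError as exc:
                raise ValueError(
                    f"{path}: malformed FASTQ at record index {index}: {exc}"
                ) from exc
            yield ReadRecord(
                read_id=title.split()[0],
                sequence=seq.upper(),
                qualities=qual,
                sample_id=sample_id,
            )
            index += 1


def write_fastq(reads: Iterable[ReadRecord], path: str | Path) -> int:
    """Write 4-line FASTQ records; returns the number written."""
    n = 0
    with open(path, "w") as out:
        for read in reads:
            out.write(f"@{read.read_id}\n{read.sequence}\n+\n{read.qualities}\n")
            n += 1
    return n


# ---------------------------------------------------------------------------
# QC filter
# ---------------------------------------------------------------------------

def qc_filter(
    reads: Iterable[ReadRecord], config: QCConfig | None = None
) -> tuple[list[ReadRecord], Counter]:
    """Keep reads with length >= min_length and mean quality >= min_base_quality.

    Returns (kept reads, Counter of drop reasons).  The length criterion is
    checked first, so a short high-quality read is tallied under 'length'.
    Conservation: len(kept) + sum(dropped.values()) == number of input reads.
    """
    config = config or QCConfig()
    kept: list[ReadRecord] = []
    dropped: Counter = Counter()
    for read in reads:
        if read.length < config.min_length:
            dropped["length"] += 1
        elif read.mean_quality < config.min_base_quality:
            dropped["quality"] += 1
        else:
            kept.append(read)
    return kept, dropped


# ---------------------------------------------------------------------------
# SAM subset
# ---------------------------------------------------------------------------

_CIGAR_RE = re.compile(r"(\d+)([MIDNSHP=X])")
_MD_RE = re.compile(r"(\d+)|(\^[A-Z]+)|([A-Z])")


def _reconstruct_reference(seq: str, md: str) -> str:
    """Rebuild the reference substring under a gap-free alignment from MD."""
    ref = []
    pos = 0
    for num, deletion, base in _MD_RE.findall(md):
        if num:
            n = int(num)
            ref.append(seq[pos : pos + n])
            pos += n
        elif deletion:
            raise ValueError(f"MD tag {md!r} encodes a deletion; indels unsupported")
        else:
            ref.append(base)
            pos += 1
    if pos != len(seq):
        raise ValueError(f"MD tag {md!r} covers {pos} bases but SEQ has {len(seq)}")
    return "".join(ref)


def _build_md(ref_fwd: str, seq_fwd: str) -> str:
    """MD tag for a gap-free alignment in reference orientation."""
    parts: list[str] = []
    run = 0
    for r, q in zip(ref_fwd, seq_fwd):
        if r == q:
            run += 1
        else:
            parts.append(str(run))
            parts.append(r)
            run = 0
    parts.append(str(run))
    return "".join(parts)


def read_alignments(path: str | Path) -> tuple[list[AlignmentRecord], Counter]:
    """Parse the header-optional SAM subset into AlignmentRecords.

    Unmapped records (FLAG & 4) are skipped and tallied under 'unmapped';
    records whose CIGAR contains operations other than M/=/X are tallied
    under 'indel_or_clip'.  Mismatch columns require an MD tag; records
    without one are tallied under 'no_md'.  A malformed line raises
    ValueError with its 1-based line number.
    """
    records: list[AlignmentRecord] = []
    tally: Counter = Counter()
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("@") or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 10:
                raise ValueError(f"{path}:{lineno}: SAM line has {len(fields)} fields (<10)")
            try:
                qname, flag_s, rname, pos_s, mapq_s, cigar = fields[:6]
                seq = fields[9].upper()
                flag = int(flag_s)
                pos = int(pos_s)
                mapq = int(mapq_s)
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: unparseable SAM fields: {exc}") from exc
            if flag & 4 or rname == "*":
                tally["unmapped"] += 1
                continue
            ops = _CIGAR_RE.findall(cigar)
            if not ops or "".join(f"{n}{op}" for n, op in ops) != cigar:
                raise ValueError(f"{path}:{lineno}: unparseable CIGAR {cigar!r}")
            if any(op not in "M=X" for _, op in ops):
                tally["indel_or_clip"] += 1
                continue
            aligned_len = sum(int(n) for n, op in ops)
            if aligned_len != len(seq):
                raise ValueError(
                    f"{path}:{lineno}: CIGAR length {aligned_len} != SEQ length {len(seq)}"
                )
            md = None
            for tagfield in fields[11:]:
                if tagfield.startswith("MD:Z:"):
                    md = tagfield[5:]
            if md is None:
                tally["no_md"] += 1
                continue
            ref_fwd = _reconstruct_reference(seq, md)
            if flag & 16:
                strand = "-"
                read_seq = revcomp(seq)
                ref_seq = revcomp(ref_fwd)
            else:
                strand = "+"
                read_seq = seq
                ref_seq = ref_fwd
            records.append(
                AlignmentRecord(
                    read_id=qname,
                    reference_id=rname,
                    position=pos - 1,
                    strand=strand,
                    read_seq=read_seq,
                    ref_seq=ref_seq,
                    mapq=mapq,
                )
            )
    return records, tally


def write_sam(
    alignments: Iterable[AlignmentRecord],
    path: str | Path,
    reference_lengths: dict[str, int] | None = None,
) -> int:
    """Write alignments as the SAM subset read back by :func:`read_alignments`.

    SEQ is emitted in reference-forward orientation (reverse-complemented for
    minus-strand records, FLAG 16) with MD and NM tags; returns count written.
    """
    n = 0
    with open(path, "w") as out:
        out.write("@HD\tVN:1.6\tSO:unsorted\n")
        if reference_lengths:
            for name, length in reference_lengths.items():
                out.write(f"@SQ\tSN:{name}\tLN:{length}\n")
        for aln in alignments:
            if aln.strand == "-":
                flag = 16
                seq_fwd = revcomp(aln.read_seq)
                ref_fwd = revcomp(aln.ref_seq)
            else:
                flag = 0
                seq_fwd = aln.read_seq
                ref_fwd = aln.ref_seq
            md = _build_md(ref_fwd, seq_fwd)
            mapq = 255 if aln.mapq is None else aln.mapq
            out.write(
                "\t".join(
                    [
                        aln.read_id,
                        str(flag),
                        aln.reference_id,
                        str(aln.position + 1),
                        str(mapq),
                        f"{aln.length}M",
                        "*",
                        "0",
                        "0",
                        seq_fwd,
                        "*",
                        f"NM:i:{aln.edit_distance}",
                        f"MD:Z:{md}",
                    ]
                )
                + "\n"
            )
            n += 1
    return n


# ---------------------------------------------------------------------------
# TSV tables
# ---------------------------------------------------------------------------

def write_table(df: pd.DataFrame, path: str | Path, meta: dict | None = None,
                index: bool = True) -> None:
    """Write a TSV with optional '# key=value ...' provenance comment line."""
    with open(path, "w") as out:
        if meta:
            out.write("# " + " ".join(f"{k}={v}" for k, v in sorted(meta.items())) + "\n")
        df.to_csv(out, sep="\t", index=index)


def read_table(path: str | Path, index_col: int | None = 0) -> pd.DataFrame:
    """Read a headered TSV, skipping '#' comment lines."""
    return pd.read_csv(path, sep="\t", comment="#", index_col=index_col)


def read_taxon_table(path: str | Path) -> pd.DataFrame:
    """Sample x species count table (samples as rows); validates non-negativity."""
    table = read_table(path)
    if (table.to_numpy() < 0).any():
        raise ValueError(f"{path}: taxon table contains negative counts")
    if table.index.duplicated().any() or table.columns.duplicated().any():
        raise ValueError(f"{path}: duplicate sample or species labels")
    return table


def write_taxon_table(table: pd.DataFrame, path: str | Path,
                      meta: dict | None = None) -> None:
    write_table(table, path, meta=meta)


def read_species_metadata(path: str | Path) -> pd.DataFrame:
    """Per-species metadata table indexed by taxon_id.

    Expected columns (superset allowed): gram, s_layer, genomic_gc, gc_class,
    source_path ('>'-joined nested category path).
    """
    meta = read_table(path)
    meta.index.name = "taxon_id"
    return meta
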