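"""Readers and writers for every external file the pipeline touches.

All coordinates are 0-based half-open throughout the package, matching the
BED/narrowPeak convention; nothing is ever shifted on input or output.
Readers validate strictly and raise :class:`FormatError` with a line number
rather than silently repairing malformed input.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Mapping, Sequence

from Bio import SeqIO

logger = logging.getLogger(__name__)

VALID_BASES = frozenset("ACGTN")


class FormatError(ValueError):
    """Malformed input file; carries the offending line number when known."""

    def __init__(self, message: str, path=None, line: int | None = None):
        loc = ""
        if path is not None:
            loc = f"{path}"
            if line is not None:
                loc += f", line {line}"
            loc = f" ({loc})"
        super().__init__(message + loc)
        self.path = path
        self.line = line


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GenomicInterval:
    """A 0-based half-open genomic interval, optionally stranded.

    ``strand`` is ``"+"``, ``"-"`` or ``"."`` (unspecified).
    """

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self):
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"require 0 <= start < end, got [{self.start}, {self.end})"
            )
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        """True iff the two intervals share >= 1 base (strand ignored)."""
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and self.end > other.start
        )

    def unstranded(self) -> "GenomicInterval":
        return GenomicInterval(self.chrom, self.start, self.end)


@dataclass(frozen=True)
class NarrowPeakRecord:
    """One ENCODE narrowPeak (BED6+4) line; signalValue is the CTCF
    binding intensity used downstream."""

    interval: GenomicInterval
    name: str
    signal_value: float
    score: int = 0
    p_value: float = -1.0
    q_value: float = -1.0
    peak_offset: int = -1

    def __post_init__(self):
        if self.signal_value < 0:
            raise ValueError(f"signalValue must be >= 0, got {self.signal_value}")


@dataclass(frozen=True)
class LoopRecord:
    """A ChIA-PET interaction: two anchor intervals plus its FDR."""

    anchor_a: GenomicInterval
    anchor_b: GenomicInterval
    fdr: float

    def __post_init__(self):
        if not (0.0 <= self.fdr <= 1.0):
            raise ValueError(f"fdr must be in [0, 1], got {self.fdr}")


@dataclass
class SequenceRecord:
    """A named DNA sequence over {A,C,G,T,N}, upper-cased on construction."""

    id: str
    bases: str

    def __post_init__(self):
        if not self.bases:
            raise ValueError(f"sequence {self.id!r} is empty")
        bases = self.bases.upper()
        bad = set(bases) - VALID_BASES
        if bad:
            # other IUPAC ambiguity codes carry no usable information for the
            # A/T/C/G one-hot scheme; collapse them to N
            logger.warning(
                "sequence %s: mapping %d non-ACGTN characters to N", self.id,
                sum(bases.count(c) for c in bad),
            )
            bases = "".join(b if b in VALID_BASES else "N" for b in bases)
        self.bases = bases

    def __len__(self) -> int:
        return len(self.bases)


class Genome(Mapping[str, SequenceRecord]):
    """In-memory random-access genome: lookup by id and by (id, start, end)."""

    def __init__(self, records: Sequence[SequenceRecord]):
        self._records = {}
        for rec in records:
            if rec.id in self._records:
                raise ValueError(f"duplicate sequence id {rec.id!r}")
            self._records[rec.id] = rec

    def __getitem__(self, key: str) -> SequenceRecord:
        return self._records[key]

    def __iter__(self) -> Iterator[str]:
        return iter(self._records)

    def __len__(self) -> int:
        return len(self._records)

    def fetch(self, chrom: str, start: int, end: int) -> str:
        """Slice of the chromosome, 0-based half-open. Out-of-bounds raises."""
        rec = self._records[chrom]
        if start < 0 or end > len(rec.bases) or start >= end:
            raise IndexError(
                f"slice [{start}, {end}) outside {chrom} (length {len(rec.bases)})"
            )
        return rec.bases[start:end]

    def fetch_interval(self, interval: GenomicInterval) -> str:
        return self.fetch(interval.chrom, interval.start, interval.end)


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def _validate_fasta_structure(path) -> None:
    """Strict structural pass producing line-numbered errors.

    Checks what a lenient parser would silently repair: leading junk before
    the first header, empty headers, and records with no sequence lines.
    """
    seen_any = False
    header_line = None
    have_seq = False
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            if line.startswith(">"):
                if header_line is not None and not have_seq:
                    raise FormatError(
                        "FASTA record has no sequence", path, header_line
                    )
                if not line[1:].strip():
                    raise FormatError("empty FASTA header", path, lineno)
                header_line = lineno
                have_seq = False
                seen_any = True
            else:
                if header_line is None:
                    raise FormatError(
                        "sequence data before any FASTA header", path, lineno
                    )
                have_seq = True
    if not seen_any:
        raise FormatError("empty FASTA file", path, 1)
    if header_line is not None and not have_seq:
        raise FormatError("FASTA record has no sequence", path, header_line)


def read_fasta(path) -> Genome:
    """Read a (wrapped or unwrapped) multi-record FASTA into a :class:`Genome`.

    Sequences are upper-cased; non-ACGTN characters become N with a warning.
    """
    _validate_fasta_structure(path)
    records = [
        SequenceRecord(rec.id, str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")
    ]
    return Genome(records)


def write_fasta(records: Sequence[SequenceRecord], path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            for i in range(0, len(rec.bases), width):
                fh.write(rec.bases[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# narrowPeak
# ---------------------------------------------------------------------------

def read_narrowpeak(path) -> list[NarrowPeakRecord]:
    """Read an ENCODE narrowPeak (BED6+4) file: exactly 10 tab-separated
    columns per line, column 7 (signalValue) becoming the binding intensity."""
    out: list[NarrowPeakRecord] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) != 10:
                raise FormatError(
                    f"narrowPeak line has {len(fields)} columns, expected 10",
                    path, lineno,
                )
            try:
                interval = GenomicInterval(
                    fields[0], int(fields[1]), int(fields[2]),
                    fields[5] if fields[5] in ("+", "-") else ".",
                )
                rec = NarrowPeakRecord(
                    interval=interval,
                    name=fields[3],
                    score=int(fields[4]),
                    signal_value=float(fields[6]),
                    p_value=float(fields[7]),
                    q_value=float(fields[8]),
                    peak_offset=int(fields[9]),
                )
            except ValueError as exc:
                raise FormatError(f"bad narrowPeak line: {exc}", path, lineno) from exc
            out.append(rec)
    return out


def write_narrowpeak(records: Sequence[NarrowPeakRecord], path) -> None:
    with open(path, "w") as fh:
        for r in records:
            fh.write(
                "\t".join([
                    r.interval.chrom, str(r.interval.start), str(r.interval.end),
                    r.name, str(r.score),
                    r.interval.strand if r.interval.strand in ("+", "-") else ".",
                    f"{r.signal_value:g}", f"{r.p_value:g}", f"{r.q_value:g}",
                    str(r.peak_offset),
                ]) + "\n"
            )


# ---------------------------------------------------------------------------
# loop TSV (ChIA-PET2-style post-processed interactions)
# ---------------------------------------------------------------------------

LOOP_COLUMNS = ("chromA", "startA", "endA", "chromB", "startB", "endB", "fdr")


def read_loops(path) -> list[LoopRecord]:
    """Read the 7-column loop dialect: chromA startA endA chromB startB endB fdr.

    An optional header line (first field starting with "chrom") is skipped.
    """
    out: list[LoopRecord] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if lineno == 1 and fields[0].lower().startswith("chrom"):
                continue
            if len(fields) < 7:
                raise FormatError(
                    f"loop line has {len(fields)} columns, expected >= 7",
                    path, lineno,
                )
            try:
                rec = LoopRecord(
                    anchor_a=GenomicInterval(fields[0], int(fields[1]), int(fields[2])),
                    anchor_b=GenomicInterval(fields[3], int(fields[4]), int(fields[5])),
                    fdr=float(fields[6]),
                )
            except ValueError as exc:
                raise FormatError(f"bad loop line: {exc}", path, lineno) from exc
            out.append(rec)
    return out


def write_loops(loops: Sequence[LoopRecord], path, header: bool = True) -> None:
    with open(path, "w") as fh:
        if header:
            fh.write("\t".join(LOOP_COLUMNS) + "\n")
        for lp in loops:
            fh.write(
                "\t".join([
                    lp.anchor_a.chrom, str(lp.anchor_a.start), str(lp.anchor_a.end),
                    lp.anchor_b.chrom, str(lp.anchor_b.start), str(lp.anchor_b.end),
                    f"{lp.fdr:g}",
                ]) + "\n"
            )


# ---------------------------------------------------------------------------
# feature matrix TSV
# ---------------------------------------------------------------------------

def write_feature_matrix(rows, path) -> None:
    """Write FeatureRows as TSV: site_id, one one-hot column per
    (position, channel), intensity, label."""
    from .features import feature_names  # local import to avoid a cycle

    rows = list(rows)
    if rows:
        dim = len(rows[0].onehot)
        for r in rows:
            if len(r.onehot) != dim:
                raise ValueError("ragged feature rows")
        names = feature_names(dim // 4)
    else:
        names = feature_names()
    with open(path, "w") as fh:
        fh.write("site_id\t" + "\t".join(names) + "\tlabel\n")
        for r in rows:
            fh.write(
                r.site_id + "\t"
                + "\t".join(str(int(v)) for v in r.onehot)
                + f"\t{r.intensity!r}\t{r.label}\n"
            )


def read_feature_matrix(path):
    from .features import FeatureRow

    import numpy as np

    out = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n")
        if not header.startswith("site_id\t"):
            raise FormatError("missing feature-matrix header", path, 1)
        ncol = len(header.split("\t"))
        for lineno, raw in enumerate(fh, start=2):
            line = raw.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != ncol:
                raise FormatError(
                    f"feature row has {len(fields)} columns, expected {ncol}",
                    path, lineno,
                )
            out.append(
                FeatureRow(
                    site_id=fields[0],
                    onehot=np.array([int(v) for v in fields[1:-2]], dtype=np.int8),
                    intensity=float(fields[-2]),
                    label=int(fields[-1]),
                )
            )
    return out


def write_labeled_bed(sites, path) -> None:
    """Optional BED export of labeled sites (name = label, score = motif score)."""
    with open(path, "w") as fh:
        for s in sites:
            iv = s.hit.interval
            fh.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\t{s.label}\t"
                f"{s.hit.score:.4f}\t{iv.strand}\n"
            )
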