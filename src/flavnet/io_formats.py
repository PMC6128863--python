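"""Tabular and FASTQ input/output for the analysis pipeline.

All tables are tab-separated text with a header row; gene and sample
identifiers are opaque, case-sensitive strings.  Writers emit rows and
columns in a stable order so that outputs are diffable.

The FASTQ reader uses the legacy Solexa/Illumina-1.3 quality convention
Q = ASCII code − 64 by default (the convention of the sequencing runs this
pipeline models); an ``offset`` argument supports modern Phred+33 data.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("flavnet")

DEFAULT_STAGES: tuple[str, ...] = ("BD", "BB", "EB", "FB")


class SchemaError(ValueError):
    """A table does not conform to its documented schema."""


class MalformedQualityError(ValueError):
    """A FASTQ quality character is below the encoding offset."""


# ---------------------------------------------------------------------------
# sample sheet / count matrix containers
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SampleSheet:
    """Maps sample ids to (stage, replicate) under an ordered stage list."""

    samples: Mapping[str, tuple[str, int]]
    stages: tuple[str, ...] = DEFAULT_STAGES

    def __post_init__(self) -> None:
        if len(self.stages) < 2:
            raise SchemaError("a sample sheet needs at least two ordered stages")
        seen: dict[tuple[str, int], str] = {}
        for sample, (stage, rep) in self.samples.items():
            if stage not in self.stages:
                raise SchemaError(
                    f"sample {sample!r} maps to unknown stage {stage!r}"
                )
            key = (stage, rep)
            if key in seen:
                raise SchemaError(
                    f"replicate index {rep} duplicated within stage {stage!r} "
                    f"({seen[key]!r} and {sample!r})"
                )
            seen[key] = sample

    def samples_for(self, stage: str) -> list[str]:
        """Sample ids of one stage, ordered by replicate index."""
        if stage not in self.stages:
            raise SchemaError(f"unknown stage {stage!r}")
        members = [(rep, s) for s, (st, rep) in self.samples.items() if st == stage]
        return [s for _, s in sorted(members)]

    @property
    def sample_ids(self) -> list[str]:
        return list(self.samples)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"sample": s, "stage": st, "replicate": rep}
            for s, (st, rep) in self.samples.items()
        ]
        return pd.DataFrame(rows, columns=["sample", "stage", "replicate"])

    @classmethod
    def from_frame(
        cls, frame: pd.DataFrame, stages: Sequence[str] | None = None
    ) -> "SampleSheet":
        required = {"sample", "stage", "replicate"}
        if not required.issubset(frame.columns):
            raise SchemaError(f"sample sheet needs columns {sorted(required)}")
        if stages is None:
            stages = tuple(dict.fromkeys(frame["stage"]))
        samples = {
            str(r["sample"]): (str(r["stage"]), int(r["replicate"]))
            for _, r in frame.iterrows()
        }
        return cls(samples=samples, stages=tuple(stages))


@dataclass
class CountMatrix:
    """Gene × sample raw counts with per-gene lengths and a design.

    ``counts`` is indexed by gene id with one integer column per sample;
    ``lengths`` holds transcript lengths in bp on the same gene index.
    """

    counts: pd.DataFrame
    lengths: pd.Series
    sheet: SampleSheet

    def __post_init__(self) -> None:
        if not self.counts.index.equals(self.lengths.index):
            raise SchemaError("counts and lengths must share one gene index")
        if (self.counts.to_numpy() < 0).any():
            raise SchemaError("counts must be non-negative")
        if (self.lengths.to_numpy() <= 0).any():
            raise SchemaError("gene lengths must be positive")
        unknown = set(self.counts.columns) - set(self.sheet.samples)
        if unknown:
            raise SchemaError(f"samples missing from sheet: {sorted(unknown)}")
        self.counts = self.counts.astype(np.int64)

    @property
    def genes(self) -> pd.Index:
        return self.counts.index

    def stage_columns(self, stage: str) -> list[str]:
        return [s for s in self.sheet.samples_for(stage) if s in self.counts.columns]


# ---------------------------------------------------------------------------
# FASTQ quality filtering
# ---------------------------------------------------------------------------


@dataclass
class ReadRecord:
    id: str
    sequence: str
    quality: list[int]


@dataclass
class FilterCounts:
    kept: int = 0
    removed: int = 0
    malformed: int = 0

    @property
    def total(self) -> int:
        return self.kept + self.removed + self.malformed


def phred_offset64(quality_char: str) -> int:
    """Decode one quality character with the Q = ASCII − 64 convention."""
    code = ord(quality_char)
    if code < 64:
        raise MalformedQualityError(
            f"quality character {quality_char!r} (code {code}) is below the "
            "+64 encoding offset"
        )
    return code - 64


def parse_fastq(path: str | Path, offset: int = 64) -> Iterator[ReadRecord]:
    """Iterate 4-line FASTQ records, decoding qualities at ``offset``.

    Records whose sequence and quality strings differ in length are still
    yielded (with the mismatched quality vector) so that the filter can
    count them as malformed rather than aborting the stream.
    """
    with open(path) as handle:
        while True:
            header = handle.readline()
            if not header:
                return
            header = header.rstrip("\n")
            if not header.startswith("@"):
                raise SchemaError(f"expected '@' header line, got {header!r}")
            seq = handle.readline().rstrip("\n")
            plus = handle.readline()
            if not plus.startswith("+"):
                raise SchemaError(f"expected '+' separator for read {header!r}")
            qual_str = handle.readline().rstrip("\n")
            if offset == 64:
                quality = [phred_offset64(c) for c in qual_str]
            else:
                quality = [ord(c) - offset for c in qual_str]
                if any(q < 0 for q in quality):
                    raise MalformedQualityError(
                        f"quality string of {header!r} underflows offset {offset}"
                    )
            yield ReadRecord(id=header[1:].split()[0], sequence=seq, quality=quality)


def filter_reads(
    reads: Iterable[ReadRecord], min_q: int = 10, mode: str = "mean"
) -> tuple[list[ReadRecord], FilterCounts]:
    """Drop low-quality reads; a read fails when its mean (or min) Q < min_q.

    The boundary is strict: a read whose summary Q equals ``min_q`` is kept.
    Length-mismatched records are skipped and counted separately; kept
    records are never altered.
    """
    if mode not in {"mean", "min"}:
        raise ValueError(f"qc mode must be 'mean' or 'min', got {mode!r}")
    kept: list[ReadRecord] = []
    counts = FilterCounts()
    for read in reads:
        if len(read.sequence) != len(read.quality):
            logger.warning(
                "read %s: sequence length %d != quality length %d; skipped",
                read.id,
                len(read.sequence),
                len(read.quality),
            )
            counts.malformed += 1
            continue
        if not read.quality:
            counts.removed += 1
            continue
        summary = (
            sum(read.quality) / len(read.quality)
            if mode == "mean"
            else min(read.quality)
        )
        if summary < min_q:
            counts.removed += 1
        else:
            counts.kept += 1
            kept.append(read)
    return kept, counts


def write_fastq(reads: Iterable[ReadRecord], path: str | Path, offset: int = 64) -> None:
    with open(path, "w") as handle:
        for read in reads:
            qual = "".join(chr(q + offset) for q in read.quality)
            handle.write(f"@{read.id}\n{read.sequence}\n+\n{qual}\n")


# ---------------------------------------------------------------------------
# tabular readers / writers
# ---------------------------------------------------------------------------


def write_table(obj: pd.DataFrame, path: str | Path, index: bool = False) -> None:
    """Write a DataFrame as TSV with a stable column order."""
    obj.to_csv(path, sep="\t", index=index)


def write_counts(cm: CountMatrix, path: str | Path) -> None:
    out = cm.counts.copy()
    out.insert(0, "length", cm.lengths)
    out.index.name = "gene_id"
    out.to_csv(path, sep="\t")


def read_counts(path: str | Path, sheet: SampleSheet) -> CountMatrix:
    """Read a counts TSV (gene_id, length, one column per sample)."""
    frame = pd.read_csv(path, sep="\t", dtype={"gene_id": str})
    if "gene_id" not in frame.columns or "length" not in frame.columns:
        raise SchemaError("counts table needs 'gene_id' and 'length' columns")
    frame = frame.set_index("gene_id")
    lengths = frame.pop("length")
    values = frame.to_numpy()
    if not np.allclose(values, np.round(values)):
        bad = np.argwhere(~np.isclose(values, np.round(values)))[0]
        raise SchemaError(
            f"non-integer count at row {bad[0] + 2} (gene {frame.index[bad[0]]!r})"
        )
    if (values < 0).any():
        bad = np.argwhere(values < 0)[0]
        raise SchemaError(
            f"negative count at row {bad[0] + 2} (gene {frame.index[bad[0]]!r})"
        )
    counts = frame.astype(np.int64)
    return CountMatrix(counts=counts, lengths=lengths.astype(np.int64), sheet=sheet)


def write_sample_sheet(sheet: SampleSheet, path: str | Path) -> None:
    write_table(sheet.to_frame(), path)


def read_sample_sheet(path: str | Path, stages: Sequence[str] | None = None) -> SampleSheet:
    frame = pd.read_csv(path, sep="\t", dtype={"sample": str, "stage": str})
    return SampleSheet.from_frame(frame, stages=stages)


#: column names of NCBI BLAST tabular (outfmt 6) output
BLAST6_COLUMNS = (
    "query", "subject", "pident", "length", "mismatch", "gapopen",
    "qstart", "qend", "sstart", "send", "evalue", "bitscore",
)


def read_hits(path: str | Path) -> pd.DataFrame:
    """Read a homology hit table (BLAST outfmt-6-like TSV).

    Accepts either headerless 12-column outfmt 6 or a headered TSV with at
    least ``query``, ``subject`` and ``evalue`` columns.  E-values are parsed
    but not filtered here; the cutoff is applied downstream.
    """
    with open(path) as handle:
        first = handle.readline()
    if "query" in first and "evalue" in first:
        frame = pd.read_csv(path, sep="\t", dtype={"query": str, "subject": str})
    else:
        frame = pd.read_csv(path, sep="\t", header=None, names=BLAST6_COLUMNS,
                            dtype={"query": str, "subject": str})
    missing = {"query", "subject", "evalue"} - set(frame.columns)
    if missing:
        raise SchemaError(f"hit table lacks columns {sorted(missing)}")
    frame["evalue"] = frame["evalue"].astype(float)
    if "bitscore" in frame.columns:
        frame["bitscore"] = frame["bitscore"].astype(float)
    return frame


def read_gene2go(path: str | Path) -> pd.DataFrame:
    frame = pd.read_csv(path, sep="\t", dtype=str)
    missing = {"gene_id", "go_id"} - set(frame.columns)
    if missing:
        raise SchemaError(f"gene2go table lacks columns {sorted(missing)}")
    return frame[["gene_id", "go_id"]]


def read_families(path: str | Path) -> pd.Series:
    frame = pd.read_csv(path, sep="\t", dtype=str)
    missing = {"gene_id", "family"} - set(frame.columns)
    if missing:
        raise SchemaError(f"family table lacks columns {sorted(missing)}")
    return frame.set_index("gene_id")["family"]


def read_lengths(path: str | Path) -> pd.Series:
    """Read per-sequence lengths from a two-column TSV or a FASTA file."""
    path = Path(path)
    with open(path) as handle:
        first = handle.readline()
    if first.startswith(">"):
        lengths: dict[str, int] = {}
        name = None
        size = 0
        with open(path) as handle:
            for line in handle:
                line = line.rstrip("\n")
                if line.startswith(">"):
                    if name is not None:
                        lengths[name] = size
                    name = line[1:].split()[0]
                    size = 0
                else:
                    size += len(line)
        if name is not None:
            lengths[name] = size
        return pd.Series(lengths, name="length")
    frame = pd.read_csv(path, sep="\t", dtype={"gene_id": str})
    if "gene_id" not in frame.columns or "length" not in frame.columns:
        raise SchemaError("length table needs 'gene_id' and 'length' columns")
    return frame.set_index("gene_id")["length"].astype(int)
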