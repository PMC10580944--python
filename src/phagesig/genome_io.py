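"""Reading genomes and feature tables; writing interval results.

Internal coordinates are 0-based half-open everywhere. Human-facing output
(TSV dialect) is 1-based inclusive; BED output keeps the 0-based half-open
convention of that format.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO

logger = logging.getLogger(__name__)

_VALID = set("ACGTN")
# IUPAC one-letter codes that degrade to N (plus anything else non-ACGTU)
_AMBIGUOUS = set("RYSWKMBDHVN")


class FormatError(ValueError):
    """Malformed input file."""


@dataclass(frozen=True)
class SequenceRecord:
    """A single genome sequence, normalized to the {A,C,G,T,N} alphabet."""

    id: str
    seq: str

    @property
    def length(self) -> int:
        return len(self.seq)

    def __post_init__(self) -> None:
        if len(self.seq) == 0:
            raise FormatError(f"zero-length sequence for record {self.id!r}")
        bad = set(self.seq) - _VALID
        if bad:
            raise FormatError(
                f"record {self.id!r} contains non-normalized characters {sorted(bad)}; "
                "use normalize_sequence() first"
            )


@dataclass(frozen=True, order=True)
class FeatureInterval:
    """A genomic feature (e.g. an ORF) in 0-based half-open coordinates."""

    start: int
    end: int
    feature_id: str = field(compare=False)
    strand: str = field(default=".", compare=False)

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise FormatError(
                f"feature {self.feature_id!r}: invalid interval [{self.start}, {self.end})"
            )
        if self.strand not in {"+", "-", "."}:
            raise FormatError(f"feature {self.feature_id!r}: bad strand {self.strand!r}")

    def overlaps(self, start: int, end: int) -> bool:
        return self.start < end and start < self.end


def normalize_sequence(seq: str) -> tuple[str, int]:
    """Uppercase, map U->T, and degrade other IUPAC ambiguity codes to N.

    Returns the normalized sequence and the number of characters that were
    mapped to N from an ambiguity code (logged as a warning when nonzero).
    """
    up = seq.upper().replace("U", "T")
    n_ambig = 0
    if not set(up) <= _VALID:
        out = []
        for ch in up:
            if ch in _VALID:
                out.append(ch)
            else:
                out.append("N")
                n_ambig += 1
        up = "".join(out)
        logger.warning("normalized %d ambiguity/unknown characters to N", n_ambig)
    return up, n_ambig


def read_fasta(path: str | Path) -> SequenceRecord:
    """Read the first record of a FASTA file, normalized.

    Multi-record files are accepted with a warning naming the record used;
    phage assemblies are expected to be single-contig.
    """
    path = Path(path)
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise FormatError(f"{path}: no FASTA records found")
    if len(records) > 1:
        logger.warning(
            "%s: %d records found; using the first (%s)", path, len(records), records[0].id
        )
    first = records[0]
    seq, _ = normalize_sequence(str(first.seq))
    if not seq:
        raise FormatError(f"{path}: record {first.id!r} has an empty sequence")
    return SequenceRecord(id=first.id, seq=seq)


def _validate_features(
    feats: list[FeatureInterval], record: SequenceRecord | None
) -> list[FeatureInterval]:
    seen: set[str] = set()
    for f in feats:
        if f.feature_id in seen:
            raise FormatError(f"duplicate feature id {f.feature_id!r}")
        seen.add(f.feature_id)
        if record is not None and f.end > record.length:
            raise FormatError(
                f"feature {f.feature_id!r} extends past sequence end "
                f"({f.end} > {record.length})"
            )
    return sorted(feats)


def read_features(
    path: str | Path,
    fmt: str = "tsv",
    record: SequenceRecord | None = None,
) -> list[FeatureInterval]:
    """Read ORF/feature intervals from a 4-column TSV or a GFF3 file.

    TSV columns: feature_id, start (1-based inclusive), end (1-based
    inclusive), strand. GFF3: lines of type CDS or gene are used, with the
    ID attribute (or a positional fallback) as the feature id. Intervals are
    converted to 0-based half-open and returned sorted by start. An empty
    file yields an empty list, which disables window-to-feature mapping
    downstream.
    """
    path = Path(path)
    feats: list[FeatureInterval] = []
    if fmt == "tsv":
        try:
            df = pd.read_csv(
                path,
                sep="\t",
                header=None,
                comment="#",
                names=["feature_id", "start", "end", "strand"],
                dtype={"feature_id": str, "strand": str},
            )
        except pd.errors.EmptyDataError:
            return []
        # tolerate a header row written by write_interval_table
        if len(df) and str(df.iloc[0]["start"]).lower() in {"start", "start_1based"}:
            df = df.iloc[1:]
        for row in df.itertuples(index=False):
            start1, end1 = int(row.start), int(row.end)
            if end1 < start1:
                raise FormatError(f"feature {row.feature_id!r}: end {end1} < start {start1}")
            feats.append(
                FeatureInterval(
                    start=start1 - 1,
                    end=end1,
                    feature_id=str(row.feature_id),
                    strand=str(row.strand) if str(row.strand) in {"+", "-"} else ".",
                )
            )
    elif fmt == "gff3":
        n_anon = 0
        with open(path) as fh:
            for line in fh:
                line = line.rstrip("\n")
                if not line or line.startswith("#"):
                    continue
                cols = line.split("\t")
                if len(cols) < 8:
                    raise FormatError(f"{path}: malformed GFF3 line: {line[:80]}")
                ftype = cols[2]
                if ftype not in {"CDS", "gene"}:
                    continue
                start1, end1 = int(cols[3]), int(cols[4])
                if end1 < start1:
                    raise FormatError(f"{path}: GFF3 end < start on line: {line[:80]}")
                attrs = cols[8] if len(cols) > 8 else ""
                fid = None
                for kv in attrs.split(";"):
                    if kv.startswith("ID="):
                        fid = kv[3:]
                        break
                if fid is None:
                    n_anon += 1
                    fid = f"{ftype}_{n_anon}"
                strand = cols[6] if cols[6] in {"+", "-"} else "."
                feats.append(
                    FeatureInterval(start=start1 - 1, end=end1, feature_id=fid, strand=strand)
                )
    else:
        raise ValueError(f"unknown feature format {fmt!r} (expected 'tsv' or 'gff3')")
    return _validate_features(feats, record)


def write_interval_table(
    records: Sequence[tuple[int, int, str, float]],
    path: str | Path,
    fmt: str = "tsv",
    chrom: str = "chr",
) -> None:
    """Write scored intervals (start, end, name, score) as BED or TSV.

    BED is 0-based half-open with score in column 5; TSV is 1-based
    inclusive with a header. TSV coordinates round-trip losslessly through
    :func:`read_features`.
    """
    path = Path(path)
    with open(path, "w") as fh:
        if fmt == "bed":
            for start, end, name, score in records:
                fh.write(f"{chrom}\t{start}\t{end}\t{name}\t{score}\n")
        elif fmt == "tsv":
            fh.write("name\tstart_1based\tend_1based\tscore\n")
            for start, end, name, score in records:
                fh.write(f"{name}\t{start + 1}\t{end}\t{score}\n")
        else:
            raise ValueError(f"unknown output format {fmt!r} (expected 'bed' or 'tsv')")


def write_features_tsv(feats: Iterable[FeatureInterval], path: str | Path) -> None:
    """Write features in the 4-column 1-based TSV dialect read_features accepts."""
    with open(path, "w") as fh:
        for f in feats:
            fh.write(f"{f.feature_id}\t{f.start + 1}\t{f.end}\t{f.strand}\n")
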