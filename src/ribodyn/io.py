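"""On-disk formats and library-level filtering/normalization.

All coordinates are transcript-relative, 0-based, half-open. Footprint
libraries are tab-delimited records (transcript_id, five_prime_pos, length,
count); transcriptomes are FASTA plus a CDS annotation TSV
(transcript_id, cds_start, cds_end).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

FOOTPRINT_COLUMNS = ["transcript_id", "five_prime_pos", "length", "count"]

MIN_FOOTPRINT_LEN = 17
MAX_FOOTPRINT_LEN = 80


class DataError(ValueError):
    """Malformed or inconsistent input data."""


@dataclass(frozen=True)
class Transcript:
    """A CDS-bearing transcript; the coordinate frame for all footprints."""

    id: str
    sequence: str
    cds_start: int
    cds_end: int

    def __post_init__(self) -> None:
        if not self.id:
            raise DataError("transcript id must be non-empty")
        if set(self.sequence) - set("ACGTN"):
            bad = sorted(set(self.sequence) - set("ACGTN"))
            raise DataError(f"{self.id}: sequence contains non-ACGTN characters {bad}")
        if not (0 <= self.cds_start < self.cds_end <= len(self.sequence)):
            raise DataError(
                f"{self.id}: CDS [{self.cds_start},{self.cds_end}) outside "
                f"sequence of length {len(self.sequence)}"
            )
        if (self.cds_end - self.cds_start) % 3:
            raise DataError(
                f"{self.id}: CDS length {self.cds_end - self.cds_start} "
                "not divisible by 3"
            )

    @property
    def cds(self) -> str:
        return self.sequence[self.cds_start : self.cds_end]

    @property
    def n_codons(self) -> int:
        return (self.cds_end - self.cds_start) // 3

    def codon(self, index: int) -> str:
        """Codon at 0-based codon index within the CDS."""
        if not 0 <= index < self.n_codons:
            raise IndexError(f"{self.id}: codon index {index} out of range")
        start = self.cds_start + 3 * index
        return self.sequence[start : start + 3]

    def codon_identities(self) -> np.ndarray:
        cds = self.cds
        return np.array([cds[i : i + 3] for i in range(0, len(cds), 3)])


class TranscriptSet(Mapping[str, Transcript]):
    """Immutable id -> Transcript mapping with duplicate rejection."""

    def __init__(self, transcripts: Iterable[Transcript]):
        self._by_id: dict[str, Transcript] = {}
        for t in transcripts:
            if t.id in self._by_id:
                raise DataError(f"duplicate transcript id {t.id!r}")
            self._by_id[t.id] = t

    def __getitem__(self, key: str) -> Transcript:
        return self._by_id[key]

    def __iter__(self) -> Iterator[str]:
        return iter(self._by_id)

    def __len__(self) -> int:
        return len(self._by_id)


@dataclass
class FootprintSet:
    """One library of aggregated footprint records.

    ``records`` has columns transcript_id, five_prime_pos, length, count with
    one row per distinct (transcript, position, length); ``total_count`` is
    the library size used as the RPM denominator.
    """

    library_id: str
    records: pd.DataFrame
    total_count: int = field(init=False)

    def __post_init__(self) -> None:
        df = self.records
        missing = [c for c in FOOTPRINT_COLUMNS if c not in df.columns]
        if missing:
            raise DataError(f"{self.library_id}: missing columns {missing}")
        df = df[FOOTPRINT_COLUMNS].copy()
        if len(df):
            if (df["count"] < 1).any():
                raise DataError(f"{self.library_id}: counts must be >= 1")
            if (df["five_prime_pos"] < 0).any():
                raise DataError(f"{self.library_id}: negative positions")
            # collapse duplicate (transcript, position, length) keys
            df = (
                df.groupby(FOOTPRINT_COLUMNS[:3], as_index=False, sort=False)["count"]
                .sum()
            )
        self.records = df.reset_index(drop=True)
        self.total_count = int(df["count"].sum()) if len(df) else 0

    def __len__(self) -> int:
        return len(self.records)

    def sorted(self) -> "FootprintSet":
        """Canonical record order: transcript id, position, length."""
        df = self.records.sort_values(
            FOOTPRINT_COLUMNS[:3], kind="mergesort"
        ).reset_index(drop=True)
        return FootprintSet(self.library_id, df)


def read_transcriptome(fasta_path, annotation_path) -> TranscriptSet:
    """Load FASTA sequences plus CDS annotations, validating both."""
    seqs = {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(fasta_path), "fasta")}
    annot = pd.read_csv(annotation_path, sep="\t")
    required = {"transcript_id", "cds_start", "cds_end"}
    if not required <= set(annot.columns):
        raise DataError(f"annotation lacks columns {sorted(required - set(annot.columns))}")
    transcripts = []
    errors = []
    for row in annot.itertuples(index=False):
        tid = str(row.transcript_id)
        if tid not in seqs:
            errors.append(f"{tid}: sequence missing from FASTA")
            continue
        try:
            transcripts.append(
                Transcript(tid, seqs[tid], int(row.cds_start), int(row.cds_end))
            )
        except DataError as exc:
            errors.append(str(exc))
    if errors:
        raise DataError("invalid transcriptome: " + "; ".join(errors))
    return TranscriptSet(transcripts)


def write_transcriptome(ts: TranscriptSet, fasta_path, annotation_path) -> None:
    records = [
        SeqRecord(Seq(t.sequence), id=t.id, description="") for t in ts.values()
    ]
    SeqIO.write(records, str(fasta_path), "fasta")
    pd.DataFrame(
        {
            "transcript_id": [t.id for t in ts.values()],
            "cds_start": [t.cds_start for t in ts.values()],
            "cds_end": [t.cds_end for t in ts.values()],
        }
    ).to_csv(annotation_path, sep="\t", index=False)


def read_footprints(path, library_id: str | None = None) -> FootprintSet:
    """Read a footprint TSV; duplicate keys are merged by summing counts."""
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", dtype={"transcript_id": str})
    except (ValueError, pd.errors.ParserError) as exc:
        raise DataError(f"{path}: unparseable footprint table ({exc})") from exc
    missing = [c for c in FOOTPRINT_COLUMNS if c not in df.columns]
    if missing:
        raise DataError(f"{path}: missing columns {missing}")
    for col in FOOTPRINT_COLUMNS[1:]:
        bad = df.index[pd.to_numeric(df[col], errors="coerce").isna()]
        if len(bad):
            # +2: header line plus 1-based numbering
            raise DataError(f"{path}: malformed {col} at line {bad[0] + 2}")
        df[col] = df[col].astype(np.int64)
    for col, ok in [
        ("five_prime_pos", df["five_prime_pos"] >= 0),
        ("length", df["length"].between(MIN_FOOTPRINT_LEN, MAX_FOOTPRINT_LEN)),
        ("count", df["count"] >= 1),
    ]:
        bad = df.index[~ok]
        if len(bad):
            raise DataError(f"{path}: invalid {col} at line {bad[0] + 2}")
    return FootprintSet(library_id or path.stem, df)


def write_footprints(fs: FootprintSet, path) -> None:
    """Write records in canonical sort order (round-trip stable)."""
    fs.sorted().records.to_csv(path, sep="\t", index=False)


def filter_by_length(
    fs: FootprintSet,
    keep_min: int = MIN_FOOTPRINT_LEN,
    keep_max: int = 34,
    exclude_range: tuple[int, int] | None = (20, 22),
) -> FootprintSet:
    """Retain lengths in [keep_min, keep_max] outside the excluded range.

    The default exclusion removes 20-22-nt footprints, which come from
    ribosomes with an open (empty) A-site and lack 3-nt periodicity.
    ``total_count`` is recomputed from the retained records.
    """
    if keep_min > keep_max:
        raise ValueError(f"inverted keep range [{keep_min},{keep_max}]")
    keep = fs.records["length"].between(keep_min, keep_max)
    if exclude_range is not None:
        lo, hi = exclude_range
        if lo > hi:
            raise ValueError(f"inverted exclude range [{lo},{hi}]")
        keep &= ~fs.records["length"].between(lo, hi)
    return FootprintSet(fs.library_id, fs.records[keep])


def rpm(fs: FootprintSet) -> pd.Series:
    """Per-record reads-per-million weight: count * 1e6 / library size."""
    if fs.total_count == 0:
        raise DataError(f"{fs.library_id}: empty library has no RPM")
    return fs.records["count"] * 1e6 / fs.total_count


def read_counts_table(path) -> pd.Series:
    """Read a per-transcript count table (transcript_id, count) as a Series."""
    df = pd.read_csv(path, sep="\t", dtype={"transcript_id": str})
    if not {"transcript_id", "count"} <= set(df.columns):
        raise DataError(f"{path}: expected transcript_id and count columns")
    return df.set_index("transcript_id")["count"].astype(float)


def write_counts_table(counts: pd.Series, path) -> None:
    counts.rename("count").rename_axis("transcript_id").reset_index().to_csv(
        path, sep="\t", index=False
    )
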