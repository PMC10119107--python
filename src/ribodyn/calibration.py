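"""3-nt periodicity scoring, read-length selection, and A/P/E-site assignment.

The A-site of a 28-30-nt footprint is taken 15 nt downstream of its 5' end;
the P- and E-sites are one and two codons upstream of the A-site. Periodicity
is scored per read length as the modal-frame fraction of CDS-overlapping 5'
ends; lengths scoring >= 0.5 (and not in the open-A-site 20-22-nt range) are
retained. The first and last five codons of every CDS are excluded from all
profiles to avoid the atypical densities around start and stop codons.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .io import DataError, FootprintSet, Transcript, TranscriptSet

#: Default A-site offsets: 15 nt from the 5' end for 28-30-nt reads.
DEFAULT_OFFSETS: dict[int, int] = {28: 15, 29: 15, 30: 15}

EDGE_EXCLUDE = 5

SITE_SHIFT = {"A": 0, "P": 1, "E": 2}  # codons upstream of the A-site


def analysis_window(t: Transcript) -> slice:
    """Codon-index slice [5, n_codons - 5) analyzed for this transcript."""
    return slice(EDGE_EXCLUDE, t.n_codons - EDGE_EXCLUDE)


def frame_score_by_length(fs: FootprintSet, ts: TranscriptSet) -> pd.DataFrame:
    """Tally 5' ends of CDS-overlapping reads by frame relative to the CDS
    start, per read length; score = modal frame fraction.

    Returns a frame per length with columns frame0/1/2, score (NaN where a
    length has no CDS-overlapping reads).
    """
    df = fs.records
    rows = []
    starts = {tid: t.cds_start for tid, t in ts.items()}
    ends = {tid: t.cds_end for tid, t in ts.items()}
    known = df["transcript_id"].map(starts).notna()
    df = df[known]
    cds_start = df["transcript_id"].map(starts).astype(int)
    cds_end = df["transcript_id"].map(ends).astype(int)
    overlaps = (df["five_prime_pos"] < cds_end) & (
        df["five_prime_pos"] + df["length"] > cds_start
    )
    df = df[overlaps]
    frame = ((df["five_prime_pos"] - cds_start[overlaps]) % 3).astype(int)
    tab = (
        pd.DataFrame({"length": df["length"], "frame": frame, "count": df["count"]})
        .pivot_table(index="length", columns="frame", values="count", aggfunc="sum", fill_value=0)
        .reindex(columns=[0, 1, 2], fill_value=0)
    )
    for length, row in tab.iterrows():
        total = row.sum()
        rows.append(
            {
                "length": int(length),
                "frame0": int(row[0]),
                "frame1": int(row[1]),
                "frame2": int(row[2]),
                "score": row.max() / total if total else np.nan,
            }
        )
    return pd.DataFrame(rows).set_index("length") if rows else pd.DataFrame(
        columns=["frame0", "frame1", "frame2", "score"]
    ).rename_axis("length")


def select_lengths(
    scores: pd.DataFrame,
    threshold: float = 0.5,
    exclude_range: tuple[int, int] | None = (20, 22),
    offsets: Mapping[int, int] | None = None,
) -> list[int]:
    """Lengths scoring >= threshold, outside the excluded range, and present
    in the offset table (only lengths with a known A-site offset can
    contribute to occupancy)."""
    offsets = DEFAULT_OFFSETS if offsets is None else offsets
    out = []
    for length in sorted(offsets):
        if exclude_range is not None and exclude_range[0] <= length <= exclude_range[1]:
            continue
        if length in scores.index:
            s = scores.loc[length, "score"]
            if np.isfinite(s) and s >= threshold:
                out.append(int(length))
        elif threshold <= 0:
            out.append(int(length))
    return out


def assign_sites(
    fs: FootprintSet,
    ts: TranscriptSet,
    offsets: Mapping[int, int] | None = None,
    usable_lengths: Iterable[int] | None = None,
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Map each footprint record to its A-site codon.

    A-site nt = 5' end + offset(length); a_codon = floor((A-nt - cds_start)/3);
    records are dropped (with a tally) when the length has no offset, the
    A-site codon lies outside the analyzed window [5, n_codons - 6], or the
    read is assigned off-frame is recorded in the ``in_frame`` column.

    Returns (assignments, drop_tallies); assignments columns:
    transcript_id, a_codon, in_frame, length, count.
    """
    offsets = DEFAULT_OFFSETS if offsets is None else offsets
    df = fs.records
    tallies = {"no_offset": 0, "unknown_transcript": 0, "out_of_window": 0}
    if usable_lengths is not None:
        usable = set(int(l) for l in usable_lengths) & set(offsets)
    else:
        usable = set(offsets)
    keep = df["length"].isin(usable)
    tallies["no_offset"] = int(df.loc[~keep, "count"].sum())
    df = df[keep]
    known = df["transcript_id"].isin(ts.keys())
    tallies["unknown_transcript"] = int(df.loc[~known, "count"].sum())
    df = df[known]
    if not len(df):
        empty = pd.DataFrame(
            columns=["transcript_id", "a_codon", "in_frame", "length", "count"]
        )
        return empty, tallies

    cds_start = df["transcript_id"].map({tid: t.cds_start for tid, t in ts.items()})
    n_codons = df["transcript_id"].map({tid: t.n_codons for tid, t in ts.items()})
    offset = df["length"].map(dict(offsets))
    a_nt = df["five_prime_pos"] + offset
    rel = a_nt - cds_start
    a_codon = np.floor_divide(rel, 3)
    in_frame = (rel % 3) == 0
    in_window = (a_codon >= EDGE_EXCLUDE) & (a_codon <= n_codons - EDGE_EXCLUDE - 1)
    tallies["out_of_window"] = int(df.loc[~in_window, "count"].sum())
    out = pd.DataFrame(
        {
            "transcript_id": df.loc[in_window, "transcript_id"],
            "a_codon": a_codon[in_window].astype(int),
            "in_frame": in_frame[in_window],
            "length": df.loc[in_window, "length"],
            "count": df.loc[in_window, "count"],
        }
    ).reset_index(drop=True)
    return out, tallies


@dataclass
class ProfileSet:
    """Per-transcript codon-level footprint density (RPM) for one library.

    ``profiles[tid]`` is a full-length vector over codon indices whose
    A-site-assigned RPM mass lies in the analysis window [5, n_codons - 6];
    entries outside the window are zero by construction. P-/E-site views are
    exact one-/two-codon shifts of the A profile.
    """

    library_id: str
    transcripts: TranscriptSet
    profiles: dict[str, np.ndarray]
    total_count: int  # RPM denominator (library size)
    dropped: dict[str, int] = field(default_factory=dict)

    def site_values(self, tid: str, site: str = "A") -> np.ndarray:
        """Density over the analysis window, indexed by the *site* codon.

        value[j] for site P is the A-profile at codon j+1 (the read whose
        P-site sits at j has its A-site at j+1), so P/E are shifts of A.
        """
        shift = SITE_SHIFT[site.upper()]
        t = self.transcripts[tid]
        prof = self.profiles[tid]
        win = analysis_window(t)
        idx = np.arange(win.start, win.stop) + shift
        vals = np.zeros(win.stop - win.start)
        ok = idx < t.n_codons
        vals[ok] = prof[idx[ok]]
        return vals

    def window_codons(self, tid: str) -> np.ndarray:
        t = self.transcripts[tid]
        return t.codon_identities()[analysis_window(t)]

    def rpm_per_count(self) -> float:
        return 1e6 / self.total_count


def build_profiles(
    fs: FootprintSet,
    ts: TranscriptSet,
    offsets: Mapping[int, int] | None = None,
    usable_lengths: Iterable[int] | None = None,
    include_offframe: bool = False,
) -> ProfileSet:
    """RPM-weighted per-transcript A-site codon profiles.

    Off-frame reads are excluded by default (the A-site codon identity is
    ill-defined off-frame). The RPM denominator is the library's
    ``total_count``, i.e. the library size after whatever length filtering
    produced ``fs``.
    """
    if usable_lengths is not None and not list(usable_lengths):
        raise DataError("usable_lengths is empty; no reads can be assigned")
    if fs.total_count == 0:
        raise DataError(f"{fs.library_id}: empty library")
    assigned, tallies = assign_sites(fs, ts, offsets, usable_lengths)
    if not include_offframe:
        tallies["off_frame"] = int(assigned.loc[~assigned["in_frame"], "count"].sum())
        assigned = assigned[assigned["in_frame"]]
    scale = 1e6 / fs.total_count
    profiles = {tid: np.zeros(t.n_codons) for tid, t in ts.items()}
    grouped = assigned.groupby("transcript_id", sort=False)
    for tid, grp in grouped:
        counts = grp.groupby("a_codon")["count"].sum()
        profiles[tid][counts.index.to_numpy()] += counts.to_numpy() * scale
    return ProfileSet(fs.library_id, ts, profiles, fs.total_count, tallies)


def calibration_report(
    scores: pd.DataFrame,
    retained: Iterable[int],
    offsets: Mapping[int, int] | None = None,
) -> pd.DataFrame:
    """Table of per-length frame counts, score, retained flag and offset."""
    offsets = DEFAULT_OFFSETS if offsets is None else offsets
    retained = set(retained)
    rep = scores.copy()
    rep["retained"] = [int(l) in retained for l in rep.index]
    rep["offset"] = [offsets.get(int(l), pd.NA) for l in rep.index]
    return rep
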