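"""Disome (collided-ribosome) footprint processing and peak analysis.

Disome fragments of 50-80 nt protect two ribosomes; the record is mapped to
the codon decoded by the leading (downstream, stalled) ribosome, whose
A-site is taken length - 15 nt from the fragment 5' end — the monosome
offset rule applied from the fragment 3' end. The alternative trailing-
ribosome convention (5' end + 15 nt) is available via ``offset_rule``.
Peak calling is a declared, configurable rule: codons whose disome density
reaches ``k_fold`` times the transcript's median nonzero density with at
least ``min_count`` raw reads, merged within ``merge_gap`` codons.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .calibration import EDGE_EXCLUDE, ProfileSet, analysis_window
from .io import DataError, FootprintSet, TranscriptSet

A_SITE_OFFSET = 15
PEAK_COLUMNS = ["transcript_id", "codon_start", "codon_end", "summit", "intensity"]


def build_disome_profiles(
    fs: FootprintSet,
    ts: TranscriptSet,
    offset_rule: str = "leading",
    min_len: int = 50,
    max_len: int = 80,
) -> ProfileSet:
    """Codon-level disome density (RPM) per transcript.

    Records outside [min_len, max_len] or mapping outside the analysis
    window are dropped with a tally; frame is not required (collision
    positions need not be frame-pure).
    """
    if offset_rule not in ("leading", "trailing"):
        raise ValueError("offset_rule must be 'leading' or 'trailing'")
    df = fs.records
    tallies = {"bad_length": 0, "unknown_transcript": 0, "out_of_window": 0}
    keep = df["length"].between(min_len, max_len)
    tallies["bad_length"] = int(df.loc[~keep, "count"].sum())
    df = df[keep]
    known = df["transcript_id"].isin(ts.keys())
    tallies["unknown_transcript"] = int(df.loc[~known, "count"].sum())
    df = df[known]
    profiles = {tid: np.zeros(t.n_codons) for tid, t in ts.items()}
    if len(df):
        cds_start = df["transcript_id"].map({tid: t.cds_start for tid, t in ts.items()})
        n_codons = df["transcript_id"].map({tid: t.n_codons for tid, t in ts.items()})
        if offset_rule == "leading":
            a_nt = df["five_prime_pos"] + df["length"] - A_SITE_OFFSET
        else:
            a_nt = df["five_prime_pos"] + A_SITE_OFFSET
        codon = np.floor_divide(a_nt - cds_start, 3)
        ok = (codon >= EDGE_EXCLUDE) & (codon <= n_codons - EDGE_EXCLUDE - 1)
        tallies["out_of_window"] = int(df.loc[~ok, "count"].sum())
        scale = 1e6 / fs.total_count if fs.total_count else 0.0
        sub = pd.DataFrame(
            {
                "transcript_id": df.loc[ok, "transcript_id"],
                "codon": codon[ok].astype(int),
                "count": df.loc[ok, "count"],
            }
        )
        for tid, grp in sub.groupby("transcript_id", sort=False):
            counts = grp.groupby("codon")["count"].sum()
            profiles[tid][counts.index.to_numpy()] += counts.to_numpy() * scale
    return ProfileSet(fs.library_id, ts, profiles, fs.total_count, tallies)


def call_peaks(
    ps: ProfileSet,
    k_fold: float = 4.0,
    min_count: float = 5.0,
    merge_gap: int = 1,
    min_codons: int = 20,
) -> pd.DataFrame:
    """Call collision peaks on one disome profile set.

    Candidate codons satisfy RPM >= k_fold x median nonzero RPM of the
    transcript and raw count >= min_count; candidates within ``merge_gap``
    codons are merged; the summit is the maximum codon. Transcripts with
    fewer than ``min_codons`` analyzed codons are skipped. Scaling the whole
    library by a constant leaves the calls unchanged.
    """
    per_count = ps.rpm_per_count() if ps.total_count else 1.0
    rows = []
    for tid, t in ps.transcripts.items():
        win = analysis_window(t)
        if win.stop - win.start < min_codons:
            continue
        vals = ps.profiles[tid][win]
        nz = vals[vals > 0]
        if not len(nz):
            continue
        med = np.median(nz)
        cand = np.flatnonzero((vals >= k_fold * med) & (vals / per_count >= min_count))
        if not len(cand):
            continue
        cand += win.start
        start = prev = int(cand[0])
        for c in list(cand[1:]) + [None]:
            if c is not None and c - prev <= merge_gap:
                prev = int(c)
                continue
            seg = ps.profiles[tid][start : prev + 1]
            rows.append(
                {
                    "transcript_id": tid,
                    "codon_start": start,
                    "codon_end": prev + 1,
                    "summit": start + int(np.argmax(seg)),
                    "intensity": float(ps.profiles[tid][start : prev + 1].sum()),
                }
            )
            if c is not None:
                start = prev = int(c)
    return pd.DataFrame(rows, columns=PEAK_COLUMNS)


def match_peaks(
    peaks_a: pd.DataFrame, peaks_b: pd.DataFrame, tolerance: int = 1
) -> dict:
    """Greedy nearest-summit matching of two peak sets within a codon
    tolerance, per transcript.

    Returns a dict with matched pair list and Venn counts (common, only_a,
    only_b, union).
    """
    pairs = []
    used_b: set[int] = set()
    b_by_tx = {tid: grp for tid, grp in peaks_b.groupby("transcript_id")}
    for ia, pa in peaks_a.iterrows():
        grp = b_by_tx.get(pa["transcript_id"])
        if grp is None:
            continue
        cand = grp[~grp.index.isin(used_b)]
        if not len(cand):
            continue
        dist = (cand["summit"] - pa["summit"]).abs()
        ib = dist.idxmin()
        if dist[ib] <= tolerance:
            pairs.append((ia, ib))
            used_b.add(ib)
    common = len(pairs)
    only_a = len(peaks_a) - common
    only_b = len(peaks_b) - common
    return {
        "pairs": pairs,
        "common": common,
        "only_a": only_a,
        "only_b": only_b,
        "union": common + only_a + only_b,
    }


def union_peaks(
    peaks_a: pd.DataFrame, peaks_b: pd.DataFrame, tolerance: int = 1
) -> pd.DataFrame:
    """Union peak set: matched pairs merged (interval union), unmatched
    peaks carried over from either side."""
    match = match_peaks(peaks_a, peaks_b, tolerance)
    rows = []
    matched_a = {ia for ia, _ in match["pairs"]}
    matched_b = {ib for _, ib in match["pairs"]}
    for ia, ib in match["pairs"]:
        pa, pb = peaks_a.loc[ia], peaks_b.loc[ib]
        rows.append(
            {
                "transcript_id": pa["transcript_id"],
                "codon_start": int(min(pa["codon_start"], pb["codon_start"])),
                "codon_end": int(max(pa["codon_end"], pb["codon_end"])),
                "summit": int(pa["summit"] if pa["intensity"] >= pb["intensity"] else pb["summit"]),
                "intensity": float(pa["intensity"] + pb["intensity"]) / 2,
            }
        )
    for df, matched in ((peaks_a, matched_a), (peaks_b, matched_b)):
        for i, p in df.iterrows():
            if i not in matched:
                rows.append(p[PEAK_COLUMNS].to_dict())
    return pd.DataFrame(rows, columns=PEAK_COLUMNS)


def peak_fold_change(
    peaks: pd.DataFrame,
    profiles_a: list[ProfileSet],
    profiles_b: list[ProfileSet],
    pseudocount: float = 0.5,
) -> pd.DataFrame:
    """log2 fold change of peak intensity (B over A) over a peak set.

    Intensity per condition is the replicate mean of summed RPM within the
    peak interval; the pseudocount (RPM) keeps condition-specific peaks
    finite.
    """
    if pseudocount <= 0:
        raise ValueError("pseudocount must be positive")
    rows = []
    for _, p in peaks.iterrows():
        tid = p["transcript_id"]
        s, e = int(p["codon_start"]), int(p["codon_end"])
        ia = float(np.mean([ps.profiles[tid][s:e].sum() for ps in profiles_a]))
        ib = float(np.mean([ps.profiles[tid][s:e].sum() for ps in profiles_b]))
        rows.append(
            {
                "transcript_id": tid,
                "codon_start": s,
                "codon_end": e,
                "intensity_a": ia,
                "intensity_b": ib,
                "log2fc": float(np.log2((ib + pseudocount) / (ia + pseudocount))),
            }
        )
    return pd.DataFrame(
        rows,
        columns=["transcript_id", "codon_start", "codon_end", "intensity_a", "intensity_b", "log2fc"],
    )


def codons_in_peaks(
    positions: list[tuple[str, int]], peaks: pd.DataFrame, tolerance: int = 1
) -> dict:
    """Count query codons lying within a peak interval +- tolerance."""
    by_tx = {tid: grp for tid, grp in peaks.groupby("transcript_id")}
    hits = []
    for tid, ci in positions:
        grp = by_tx.get(tid)
        if grp is None:
            continue
        inside = (grp["codon_start"] - tolerance <= ci) & (ci < grp["codon_end"] + tolerance)
        if inside.any():
            hits.append((tid, ci))
    return {
        "n_queries": len(positions),
        "n_in_peaks": len(hits),
        "n_outside": len(positions) - len(hits),
        "hits": hits,
    }


def write_peaks(peaks: pd.DataFrame, path) -> None:
    """BED-like TSV in transcript-codon coordinates."""
    peaks[PEAK_COLUMNS].to_csv(path, sep="\t", index=False)


def read_peaks(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"transcript_id": str})
    missing = [c for c in PEAK_COLUMNS if c not in df.columns]
    if missing:
        raise DataError(f"{path}: missing peak columns {missing}")
    return df
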