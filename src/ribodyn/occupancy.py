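"""Relative codon occupancy, RUST metafootprint ratios, CV, and TE.

Relative occupancy follows the mean-corrected RPM definition: mean density
at positions carrying a codon identity divided by the mean density over all
analyzed positions; a value above 1 at the A-site indicates slow decoding
(long dwell) of that codon. RUST provides a coverage-robust alternative by
binarizing each transcript's profile at its mean and comparing the codon
composition of above-mean positions with that of all positions.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .codons import CODON_TO_AA
from .io import DataError
from .calibration import ProfileSet


def _qualifying(
    ps: ProfileSet,
    site: str,
    min_mean_rpm: float | None,
    min_codons: int,
) -> list[str]:
    """Transcripts passing the coverage gate at the given site.

    ``min_mean_rpm=None`` gates at the RPM equivalent of a mean raw count of
    one read per codon for this library.
    """
    gate = ps.rpm_per_count() if min_mean_rpm is None else min_mean_rpm
    out = []
    for tid in ps.profiles:
        vals = ps.site_values(tid, site)
        if len(vals) >= min_codons and vals.mean() >= gate:
            out.append(tid)
    return out


def _pooled_positions(ps: ProfileSet, tids: list[str], site: str) -> pd.DataFrame:
    frames = []
    for tid in tids:
        frames.append(
            pd.DataFrame(
                {"codon": ps.window_codons(tid), "rpm": ps.site_values(tid, site)}
            )
        )
    return pd.concat(frames, ignore_index=True)


def relative_codon_occupancy(
    ps: ProfileSet,
    site: str = "A",
    min_mean_rpm: float | None = None,
    min_codons: int = 100,
    per_transcript: bool = False,
) -> pd.DataFrame:
    """Relative occupancy rho per codon identity for one library.

    Positions of qualifying transcripts are pooled; per identity, rho is the
    mean RPM over its positions divided by the mean RPM over all positions,
    so the occurrence-weighted mean of rho is exactly 1. ``per_transcript``
    averages rho within each transcript first (sensitivity variant).

    Returns a frame indexed by codon with columns n (position count),
    mean_rpm, rho, and aa.
    """
    tids = _qualifying(ps, site, min_mean_rpm, min_codons)
    if not tids:
        raise DataError(f"{ps.library_id}: no transcript passes the coverage gate")
    if per_transcript:
        per_tx = []
        for tid in tids:
            pos = _pooled_positions(ps, [tid], site)
            overall = pos["rpm"].mean()
            if overall <= 0:
                continue
            g = pos.groupby("codon")["rpm"].agg(["size", "mean"])
            g["rho"] = g["mean"] / overall
            per_tx.append(g)
        allpos = pd.concat(per_tx)
        out = allpos.groupby(level=0).apply(
            lambda g: pd.Series(
                {
                    "n": g["size"].sum(),
                    "mean_rpm": np.average(g["mean"], weights=g["size"]),
                    "rho": np.average(g["rho"], weights=g["size"]),
                }
            )
        )
    else:
        pos = _pooled_positions(ps, tids, site)
        overall = pos["rpm"].mean()
        g = pos.groupby("codon")["rpm"].agg(n="size", mean_rpm="mean")
        g["rho"] = g["mean_rpm"] / overall
        out = g
    out["n"] = out["n"].astype(int)
    out["aa"] = [CODON_TO_AA.get(c, "?") for c in out.index]
    out.index.name = "codon"
    out.attrs.update({"library_id": ps.library_id, "site": site})
    return out


def aggregate_amino_acid(table: pd.DataFrame) -> pd.DataFrame:
    """Occurrence-weighted mean of rho over synonymous codons, per amino acid."""
    def agg(g: pd.DataFrame) -> pd.Series:
        return pd.Series(
            {
                "n": g["n"].sum(),
                "rho": np.average(g["rho"], weights=g["n"]),
            }
        )

    out = table.groupby("aa")[["n", "rho"]].apply(agg)
    out["n"] = out["n"].astype(int)
    out.index.name = "aa"
    out.attrs.update(table.attrs)
    return out


def rust_metafootprint(
    ps: ProfileSet,
    site: str = "A",
    min_codons: int = 20,
) -> pd.DataFrame:
    """RUST observed/expected codon enrichment among above-mean positions.

    Each transcript's profile is binarized at its own mean (strictly above
    counts as 1, ties as 0); the codon-identity frequency among 1-positions,
    pooled across transcripts, is divided by the identity frequency among
    all analyzed positions. Constant (zero-variance) transcripts contribute
    no 1-positions.
    """
    obs: dict[str, float] = {}
    exp: dict[str, float] = {}
    n_obs = 0
    n_exp = 0
    for tid in ps.profiles:
        vals = ps.site_values(tid, site)
        if len(vals) < min_codons:
            continue
        codons = ps.window_codons(tid)[: len(vals)]
        above = vals > vals.mean()
        for c in codons:
            exp[c] = exp.get(c, 0) + 1
        n_exp += len(codons)
        for c in codons[above]:
            obs[c] = obs.get(c, 0) + 1
        n_obs += int(above.sum())
    if n_obs == 0 or n_exp == 0:
        raise DataError(f"{ps.library_id}: no above-mean positions for RUST")
    idx = sorted(exp)
    out = pd.DataFrame(
        {
            "observed_freq": [obs.get(c, 0) / n_obs for c in idx],
            "expected_freq": [exp[c] / n_exp for c in idx],
        },
        index=pd.Index(idx, name="codon"),
    )
    out["rust_ratio"] = out["observed_freq"] / out["expected_freq"]
    out["aa"] = [CODON_TO_AA.get(c, "?") for c in idx]
    out.attrs.update({"library_id": ps.library_id, "site": site})
    return out


def transcript_cv(
    ps: ProfileSet,
    site: str = "A",
    min_mean_rpm: float | None = None,
    min_codons: int = 100,
) -> pd.DataFrame:
    """Per-transcript coefficient of variation of codon-level density.

    cv = sample standard deviation (n-1 denominator) / mean of the A-site
    RPM over the analysis window; a summary of elongation-rate heterogeneity
    along the transcript. Transcripts failing the coverage gate or with zero
    mean are omitted.
    """
    rows = []
    for tid in _qualifying(ps, site, min_mean_rpm, min_codons):
        vals = ps.site_values(tid, site)
        mean = vals.mean()
        if mean <= 0:
            continue
        rows.append(
            {
                "transcript_id": tid,
                "n_codons": len(vals),
                "mean_rpm": mean,
                "cv": vals.std(ddof=1) / mean,
            }
        )
    out = pd.DataFrame(rows, columns=["transcript_id", "n_codons", "mean_rpm", "cv"])
    out.attrs.update({"library_id": ps.library_id, "site": site})
    return out


def translation_efficiency(
    ribo_counts: pd.Series,
    rna_counts: pd.Series,
    ts,
) -> pd.DataFrame:
    """TE = footprint density / mRNA density per transcript.

    Densities are reads per million library reads per CDS kilobase, so TE is
    invariant to the depth of either library. TE is NaN where the RNA
    density is zero.
    """
    shared = ribo_counts.index.intersection(rna_counts.index)
    cds_kb = pd.Series({tid: (ts[tid].cds_end - ts[tid].cds_start) / 1000 for tid in shared})
    ribo_dens = ribo_counts[shared] * 1e6 / ribo_counts.sum() / cds_kb
    rna_dens = rna_counts[shared] * 1e6 / rna_counts.sum() / cds_kb
    te = ribo_dens / rna_dens.where(rna_dens > 0)
    return pd.DataFrame(
        {"ribo_density": ribo_dens, "rna_density": rna_dens, "te": te}
    ).rename_axis("transcript_id")


def footprint_counts_per_transcript(fs) -> pd.Series:
    """Total footprint count per transcript for a library (TE numerator)."""
    return fs.records.groupby("transcript_id")["count"].sum().astype(float)
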