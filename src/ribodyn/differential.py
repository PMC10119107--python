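"""Between-condition comparisons of codon occupancy.

Covers codon- and amino-acid-level fold changes of relative occupancy,
per-position differential pause testing (pooled-variance t with BH
adjustment within each amino-acid codon family), Spearman correlation of
fold-change profiles across experiments, and metagene profiles around
anchor codons.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .codons import CODON_TO_AA
from .calibration import ProfileSet, analysis_window
from .occupancy import aggregate_amino_acid
from .stats import benjamini_hochberg, pooled_t_test, spearman


def codon_fold_change(
    tables_a: list[pd.DataFrame],
    tables_b: list[pd.DataFrame],
    by: str = "codon",
) -> pd.DataFrame:
    """log2 fold change of relative occupancy, condition B over A.

    Replicate occupancy tables are averaged per condition first; ``by='aa'``
    aggregates synonymous codons (occurrence-weighted) before the ratio.
    Identities missing or zero in either condition are omitted and listed in
    ``attrs['omitted']``.
    """
    if by == "aa":
        tables_a = [aggregate_amino_acid(t) for t in tables_a]
        tables_b = [aggregate_amino_acid(t) for t in tables_b]
    mean_a = pd.concat([t["rho"] for t in tables_a], axis=1).mean(axis=1)
    mean_b = pd.concat([t["rho"] for t in tables_b], axis=1).mean(axis=1)
    shared = mean_a.index.intersection(mean_b.index)
    valid = shared[(mean_a[shared] > 0) & (mean_b[shared] > 0)]
    omitted = sorted(set(mean_a.index).union(mean_b.index) - set(valid))
    out = pd.DataFrame(
        {
            "mean_rho_a": mean_a[valid],
            "mean_rho_b": mean_b[valid],
            "log2fc": np.log2(mean_b[valid] / mean_a[valid]),
        }
    )
    out.index.name = by
    if by == "codon":
        out["aa"] = [CODON_TO_AA.get(c, "?") for c in out.index]
    out.attrs["omitted"] = omitted
    return out


def _normalized_position_matrix(
    group: list[ProfileSet], site: str
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-position matrices across replicates.

    Returns (normalized, raw_counts): rows indexed by (transcript, codon
    index), one column per replicate. Normalized value = position RPM /
    transcript mean RPM over the window, which removes between-genotype
    transcript-abundance differences and isolates local occupancy.
    """
    norm_cols = []
    raw_cols = []
    for ps in group:
        norm_chunks = []
        raw_chunks = []
        for tid in ps.profiles:
            t = ps.transcripts[tid]
            win = analysis_window(t)
            vals = ps.site_values(tid, site)
            mean = vals.mean()
            idx = pd.MultiIndex.from_arrays(
                [[tid] * len(vals), np.arange(win.start, win.stop)],
                names=["transcript_id", "codon_index"],
            )
            norm_chunks.append(
                pd.Series(vals / mean if mean > 0 else np.nan, index=idx)
            )
            raw_chunks.append(pd.Series(vals / ps.rpm_per_count(), index=idx))
        norm_cols.append(pd.concat(norm_chunks))
        raw_cols.append(pd.concat(raw_chunks))
    return pd.concat(norm_cols, axis=1), pd.concat(raw_cols, axis=1)


def position_differential(
    group_a: list[ProfileSet],
    group_b: list[ProfileSet],
    codon_filter: set[str] | None = None,
    site: str = "A",
    min_mean_count: float = 5.0,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-codon-position differential occupancy between replicate groups.

    Per replicate, each position's RPM is divided by its transcript's mean
    RPM; positions whose codon identity is in ``codon_filter`` (all sense
    codons if None) and whose mean raw count reaches ``min_mean_count`` in
    at least one group are tested with a two-sided pooled-variance t test.
    BH adjustment is applied separately within each amino-acid family of
    tested codons, mirroring per-amino-acid volcano plots.
    """
    if len(group_a) < 2 or len(group_b) < 2:
        raise ValueError("need >= 2 replicates per group")
    ts = group_a[0].transcripts
    norm_a, raw_a = _normalized_position_matrix(group_a, site)
    norm_b, raw_b = _normalized_position_matrix(group_b, site)
    idx = norm_a.index  # same transcriptome => identical position universe
    identities = pd.Series(
        np.concatenate([ts[tid].codon_identities()[analysis_window(ts[tid])] for tid in group_a[0].profiles]),
        index=idx,
    )
    keep = identities.index[identities.isin(codon_filter)] if codon_filter is not None else idx
    covered = (raw_a.loc[keep].mean(axis=1) >= min_mean_count) | (
        raw_b.loc[keep].mean(axis=1) >= min_mean_count
    )
    keep = keep[covered]

    rows = []
    a_vals = norm_a.loc[keep].to_numpy()
    b_vals = norm_b.loc[keep].to_numpy()
    for i, (tid, ci) in enumerate(keep):
        xa, xb = a_vals[i], b_vals[i]
        if np.isnan(xa).any() or np.isnan(xb).any():
            continue
        t, _, p = pooled_t_test(xb, xa)
        ma, mb = xa.mean(), xb.mean()
        log2fc = np.log2(mb / ma) if ma > 0 and mb > 0 else np.nan
        rows.append(
            {
                "transcript_id": tid,
                "codon_index": int(ci),
                "codon": identities.loc[(tid, ci)],
                "t": t,
                "p": p,
                "log2fc": log2fc,
                "mean_a": ma,
                "mean_b": mb,
                "degenerate": not np.isfinite(t),
            }
        )
    out = pd.DataFrame(
        rows,
        columns=[
            "transcript_id", "codon_index", "codon", "t", "p", "log2fc",
            "mean_a", "mean_b", "degenerate",
        ],
    )
    if len(out):
        out["aa"] = out["codon"].map(CODON_TO_AA)
        out["q"] = np.nan
        for _, grp_idx in out.groupby("aa").groups.items():
            out.loc[grp_idx, "q"] = benjamini_hochberg(out.loc[grp_idx, "p"].to_numpy())
        out["significant"] = out["q"] < alpha
    return out


@dataclass
class CorrelationResult:
    site: str
    r: float
    p: float
    p_adjusted: float
    n: int


def spearman_fc_correlation(
    fc_1: pd.Series | pd.DataFrame,
    fc_2: pd.Series | pd.DataFrame,
    site: str = "A",
    family_size: int = 3,
) -> CorrelationResult:
    """Spearman correlation of two fold-change profiles over shared codons.

    p is two-sided; the Bonferroni adjustment multiplies by ``family_size``
    (default 3: the A-, P-, E-site family tested together).
    """
    if isinstance(fc_1, pd.DataFrame):
        fc_1 = fc_1["log2fc"]
    if isinstance(fc_2, pd.DataFrame):
        fc_2 = fc_2["log2fc"]
    shared = fc_1.index.intersection(fc_2.index)
    if len(shared) < 4:
        raise ValueError(f"only {len(shared)} shared identities; need >= 4")
    r, p = spearman(fc_1[shared].to_numpy(), fc_2[shared].to_numpy())
    return CorrelationResult(site, r, p, min(1.0, p * family_size), len(shared))


def metagene(
    profile_sets: list[ProfileSet],
    anchors: list[tuple[str, int]],
    window: int = 15,
) -> tuple[pd.Series, int]:
    """Mean locally-normalized density around anchor codons.

    Per replicate and anchor, the +-``window``-codon profile is divided by
    its own window mean, averaged over anchors, then over replicates.
    Anchors whose window leaves the analysis region are skipped; the count
    of anchors actually used (per replicate) is returned alongside.
    """
    offsets = np.arange(-window, window + 1)
    rep_profiles = []
    n_used = 0
    for ps in profile_sets:
        acc = np.zeros(len(offsets))
        n = 0
        for tid, ci in anchors:
            t = ps.transcripts[tid]
            win = analysis_window(t)
            if ci - window < win.start or ci + window >= win.stop:
                continue
            seg = ps.profiles[tid][ci - window : ci + window + 1]
            m = seg.mean()
            if m <= 0:
                continue
            acc += seg / m
            n += 1
        if n:
            rep_profiles.append(acc / n)
            n_used = n
    if not rep_profiles:
        raise ValueError("no usable anchor windows")
    mean_profile = np.mean(rep_profiles, axis=0)
    return pd.Series(mean_profile, index=pd.Index(offsets, name="offset")), n_used
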