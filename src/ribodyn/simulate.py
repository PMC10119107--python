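"""Synthetic transcriptomes and footprint libraries with known dwell times.

The generator emulates the statistical structure the downstream analysis
assumes: monosome footprints of 17-34 nt (dominant 28-30 nt, 3-nt periodic)
whose A-site codons are drawn multinomially in proportion to transcript
abundance times per-codon dwell time; disome footprints of 50-80 nt
concentrated at planted collision sites; replicate groups with log-normal
multiplicative depth noise; and matched RNA-seq counts. Every stochastic
operation takes an explicit integer seed; no global RNG state is used.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .codons import SENSE_CODONS, STOP_CODONS
from .io import FOOTPRINT_COLUMNS, FootprintSet, Transcript, TranscriptSet

A_SITE_OFFSET = 15  # nt from footprint 5' end to the A-site, 28-30-nt reads
EDGE_EXCLUDE = 5  # first/last codons excluded from analysis
DISOME_MIN_LEN, DISOME_MAX_LEN = 50, 80

#: Read-length mix: dominant 28-30 nt with light tails, mimicking a
#: size-selected monosome library.
DEFAULT_LENGTH_DISTRIBUTION: dict[int, float] = {
    27: 0.05,
    28: 0.30,
    29: 0.35,
    30: 0.25,
    31: 0.05,
}


class ConfigurationError(ValueError):
    """Invalid simulation configuration."""


@dataclass(frozen=True)
class DwellSpec:
    """Per-codon dwell times: base time scaled per codon identity and,
    optionally, per individual (transcript, codon index) site."""

    base_dwell: float = 1.0
    codon_multipliers: Mapping[str, float] = field(default_factory=dict)
    site_multipliers: Mapping[tuple[str, int], float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.base_dwell <= 0:
            raise ConfigurationError("base_dwell must be positive")
        for codon, m in self.codon_multipliers.items():
            if codon not in SENSE_CODONS:
                raise ConfigurationError(f"{codon!r} is not a sense codon")
            if m <= 0:
                raise ConfigurationError(f"multiplier for {codon} must be positive")
        if any(m <= 0 for m in self.site_multipliers.values()):
            raise ConfigurationError("site multipliers must be positive")

    def dwell(self, codon: str) -> float:
        return self.base_dwell * self.codon_multipliers.get(codon, 1.0)

    def with_codon_multipliers(self, extra: Mapping[str, float]) -> "DwellSpec":
        merged = {**self.codon_multipliers}
        for codon, m in extra.items():
            merged[codon] = merged.get(codon, 1.0) * m
        return replace(self, codon_multipliers=merged)


@dataclass(frozen=True)
class SimulationConfig:
    """Study-design parameters for one simulated experiment.

    Defaults mirror a size-selected mouse-heart style design: four
    replicates per genotype, ~1e6 footprints per library, mild log-normal
    depth dispersion, and a small off-frame read fraction.
    """

    n_transcripts: int = 50
    cds_length_range: tuple[int, int] = (150, 400)  # codons
    utr_length: int = 18  # nt each side; keeps 15-nt offsets in bounds
    length_distribution: Mapping[int, float] = field(
        default_factory=lambda: dict(DEFAULT_LENGTH_DISTRIBUTION)
    )
    offframe_noise: float = 0.05
    depth: int = 1_000_000
    n_replicates: int = 4
    dispersion: float = 0.1
    seed: int = 0
    codon_weights: Mapping[str, float] | None = None  # uniform over 61 if None

    def __post_init__(self) -> None:
        lo, hi = self.cds_length_range
        if lo < 30:
            raise ConfigurationError(
                "cds_length_range minimum must be >= 30 codons so that edge "
                "exclusion leaves >= 20 analyzable codons"
            )
        if lo > hi:
            raise ConfigurationError("inverted cds_length_range")
        if self.utr_length < 18:
            raise ConfigurationError("utr_length must be >= 18 nt")
        probs = np.array(list(self.length_distribution.values()), float)
        lengths = np.array(list(self.length_distribution.keys()))
        if abs(probs.sum() - 1.0) > 1e-9:
            raise ConfigurationError("length_distribution must sum to 1")
        if (probs < 0).any() or lengths.min() < 17 or lengths.max() > 34:
            raise ConfigurationError("monosome lengths must lie in 17-34 nt")
        if not 0 <= self.offframe_noise < 1:
            raise ConfigurationError("offframe_noise must be in [0, 1)")
        if self.depth <= 0:
            raise ConfigurationError("depth must be positive")


@dataclass
class SyntheticTruth:
    """Ground-truth ledger for one simulated library or condition pair."""

    codon_multipliers: dict[str, float]
    site_multipliers: dict[tuple[str, int], float]
    abundance: dict[str, float]  # normalized to sum 1
    stall_sites: list[tuple[str, int]] = field(default_factory=list)
    skipped_transcripts: list[str] = field(default_factory=list)
    planted_effects: pd.DataFrame | None = None  # condition-pair bookkeeping
    _position_weights: pd.DataFrame | None = None

    def expected_relative_occupancy(self) -> pd.Series:
        """Expected occupancy ratio per codon identity under the sampler.

        Mean sampling weight at positions of each identity divided by the
        mean weight over all analyzed positions; this is the quantity the
        occupancy module estimates.
        """
        if self._position_weights is None:
            raise ValueError("truth carries no position weights")
        w = self._position_weights
        overall = w["weight"].mean()
        return w.groupby("codon")["weight"].mean() / overall


def _rng(seed) -> np.random.Generator:
    return np.random.default_rng(seed)


def _spawn_seeds(seed: int, n: int) -> list[np.random.SeedSequence]:
    return np.random.SeedSequence(seed).spawn(n)


def generate_transcriptome(cfg: SimulationConfig, seed: int | None = None) -> TranscriptSet:
    """Random transcriptome: each CDS starts ATG, ends in a stop codon, and
    is flanked by UTRs long enough that 15-nt offsets never leave the
    transcript. Interior codons are drawn from ``cfg.codon_weights``
    (uniform over the 61 sense codons by default), so codon usage does not
    confound occupancy estimates in tests."""
    rng = _rng(cfg.seed if seed is None else seed)
    lo, hi = cfg.cds_length_range
    if cfg.codon_weights is None:
        codons = np.array(SENSE_CODONS)
        probs = np.full(len(codons), 1.0 / len(codons))
    else:
        codons = np.array(list(cfg.codon_weights.keys()))
        if set(codons) - set(SENSE_CODONS):
            raise ConfigurationError("codon_weights must cover sense codons only")
        probs = np.array(list(cfg.codon_weights.values()), float)
        probs = probs / probs.sum()
    stops = np.array(STOP_CODONS)
    bases = np.array(list("ACGT"))
    transcripts = []
    for i in range(cfg.n_transcripts):
        n_codons = int(rng.integers(lo, hi + 1))
        interior = rng.choice(codons, size=n_codons - 2, p=probs)
        cds = "ATG" + "".join(interior) + str(rng.choice(stops))
        utr5 = "".join(rng.choice(bases, size=cfg.utr_length))
        utr3 = "".join(rng.choice(bases, size=cfg.utr_length))
        transcripts.append(
            Transcript(
                id=f"tx{i:04d}",
                sequence=utr5 + cds + utr3,
                cds_start=cfg.utr_length,
                cds_end=cfg.utr_length + 3 * n_codons,
            )
        )
    return TranscriptSet(transcripts)


def sample_abundances(
    ts: TranscriptSet, seed: int, sigma: float = 1.0
) -> dict[str, float]:
    """Log-normal transcript abundances, normalized to sum to 1."""
    rng = _rng(seed)
    raw = rng.lognormal(mean=0.0, sigma=sigma, size=len(ts))
    raw /= raw.sum()
    return dict(zip(ts.keys(), raw))


def _position_table(
    ts: TranscriptSet,
    dwell: DwellSpec,
    abundance: Mapping[str, float] | None,
    min_codon: int | None = None,
) -> tuple[pd.DataFrame, list[str]]:
    """One row per analyzable (transcript, codon) cell with sampling weight."""
    rows = []
    skipped = []
    for tid, t in ts.items():
        first = EDGE_EXCLUDE if min_codon is None else max(EDGE_EXCLUDE, min_codon)
        last = t.n_codons - EDGE_EXCLUDE - 1  # inclusive
        if last < first:
            skipped.append(tid)
            continue
        idx = np.arange(first, last + 1)
        identities = t.codon_identities()[idx]
        ab = 1.0 if abundance is None else abundance[tid]
        w = ab * np.array([dwell.dwell(c) for c in identities])
        for j, (ci, cod) in enumerate(zip(idx, identities)):
            m = dwell.site_multipliers.get((tid, int(ci)))
            if m is not None:
                w[j] *= m
        rows.append(
            pd.DataFrame(
                {
                    "transcript_id": tid,
                    "codon_index": idx,
                    "codon": identities,
                    "a_nt": t.cds_start + 3 * idx,
                    "weight": w,
                }
            )
        )
    if not rows:
        raise ConfigurationError("no transcript long enough to simulate")
    return pd.concat(rows, ignore_index=True), skipped


def simulate_monosome_footprints(
    ts: TranscriptSet,
    dwell: DwellSpec,
    cfg: SimulationConfig,
    seed: int | None = None,
    depth: int | None = None,
    abundance: Mapping[str, float] | None = None,
    library_id: str = "mono",
) -> tuple[FootprintSet, SyntheticTruth]:
    """Draw A-site codons multinomially with probability proportional to
    abundance x dwell, then 5' end = A-site nt - 15 and a read length from
    the configured distribution; a fraction ``offframe_noise`` of reads is
    shifted by +-1 nt. Counts are aggregated per (transcript, position,
    length)."""
    rng = _rng(cfg.seed if seed is None else seed)
    depth = cfg.depth if depth is None else depth
    pos, skipped = _position_table(ts, dwell, abundance)
    p = pos["weight"].to_numpy() / pos["weight"].sum()
    cell_counts = rng.multinomial(depth, p)

    lengths = np.array(sorted(cfg.length_distribution))
    lprobs = np.array([cfg.length_distribution[l] for l in lengths], float)
    lprobs = lprobs / lprobs.sum()
    # (cells, lengths) count matrix, then split off-frame reads +-1 nt
    mat = rng.multinomial(cell_counts, lprobs)
    shifted = rng.binomial(mat, cfg.offframe_noise)
    plus = rng.binomial(shifted, 0.5)
    minus = shifted - plus
    inframe = mat - shifted

    a_nt = pos["a_nt"].to_numpy()
    tids = pos["transcript_id"].to_numpy()
    frames = []
    for counts, shift in ((inframe, 0), (plus, 1), (minus, -1)):
        cell_i, len_i = np.nonzero(counts)
        if not len(cell_i):
            continue
        frames.append(
            pd.DataFrame(
                {
                    "transcript_id": tids[cell_i],
                    "five_prime_pos": a_nt[cell_i] - A_SITE_OFFSET + shift,
                    "length": lengths[len_i],
                    "count": counts[cell_i, len_i],
                }
            )
        )
    records = (
        pd.concat(frames, ignore_index=True)
        if frames
        else pd.DataFrame(columns=FOOTPRINT_COLUMNS)
    )
    ab = (
        {tid: 1.0 / len(ts) for tid in ts}
        if abundance is None
        else {k: v / sum(abundance.values()) for k, v in abundance.items()}
    )
    truth = SyntheticTruth(
        codon_multipliers=dict(dwell.codon_multipliers),
        site_multipliers=dict(dwell.site_multipliers),
        abundance=ab,
        skipped_transcripts=skipped,
        _position_weights=pos,
    )
    return FootprintSet(library_id, records), truth


def disome_codon_range(t: Transcript) -> tuple[int, int]:
    """Inclusive codon range where an 80-nt disome fragment fits entirely
    within the transcript under the leading-ribosome convention."""
    first = max(
        EDGE_EXCLUDE,
        int(np.ceil((DISOME_MAX_LEN - A_SITE_OFFSET - t.cds_start) / 3)),
    )
    last = t.n_codons - EDGE_EXCLUDE - 1
    return first, last


def simulate_disome_footprints(
    ts: TranscriptSet,
    stall_sites: Sequence[tuple[str, int]],
    cfg: SimulationConfig,
    p_stall: float = 0.5,
    seed: int | None = None,
    depth: int = 100_000,
    abundance: Mapping[str, float] | None = None,
    library_id: str = "disome",
) -> FootprintSet:
    """50-80-nt fragments whose leading-ribosome A-site falls on a planted
    stall site with probability ``p_stall`` and is otherwise uniform over
    the codons where the fragment fits. 5' end = A-site nt - (length - 15),
    mirroring the monosome offset applied to the downstream ribosome."""
    if not 0 <= p_stall <= 1:
        raise ConfigurationError("p_stall must be in [0, 1]")
    rng = _rng(cfg.seed if seed is None else seed)
    cells = []
    for tid, t in ts.items():
        first, last = disome_codon_range(t)
        if last < first:
            continue
        idx = np.arange(first, last + 1)
        ab = 1.0 if abundance is None else abundance[tid]
        cells.append(
            pd.DataFrame(
                {
                    "transcript_id": tid,
                    "codon_index": idx,
                    "a_nt": t.cds_start + 3 * idx,
                    "weight": ab,
                }
            )
        )
    if not cells:
        raise ConfigurationError("no transcript can host a disome fragment")
    bg = pd.concat(cells, ignore_index=True)
    allowed = set(zip(bg["transcript_id"], bg["codon_index"]))
    for site in stall_sites:
        if (site[0], int(site[1])) not in allowed:
            raise ConfigurationError(f"stall site {site} outside disome range")

    n_stall = rng.binomial(depth, p_stall) if stall_sites else 0
    n_bg = depth - n_stall
    parts = []
    if n_stall:
        site_counts = rng.multinomial(n_stall, np.full(len(stall_sites), 1 / len(stall_sites)))
        for (tid, ci), c in zip(stall_sites, site_counts):
            if c:
                parts.append((tid, ts[tid].cds_start + 3 * int(ci), c))
    if n_bg:
        p = bg["weight"].to_numpy() / bg["weight"].sum()
        counts = rng.multinomial(n_bg, p)
        nz = np.nonzero(counts)[0]
        for i in nz:
            parts.append((bg["transcript_id"].iat[i], int(bg["a_nt"].iat[i]), int(counts[i])))

    lengths = np.arange(DISOME_MIN_LEN, DISOME_MAX_LEN + 1)
    lp = np.full(len(lengths), 1 / len(lengths))
    rows = []
    for tid, a_nt, c in parts:
        lc = rng.multinomial(c, lp)
        for l, n in zip(lengths[lc > 0], lc[lc > 0]):
            rows.append((tid, a_nt - (int(l) - A_SITE_OFFSET), int(l), int(n)))
    records = pd.DataFrame(rows, columns=FOOTPRINT_COLUMNS)
    return FootprintSet(library_id, records)


@dataclass
class ConditionPair:
    """Two replicate groups over one transcriptome, with ground truth."""

    transcripts: TranscriptSet
    libraries: dict[str, list[FootprintSet]]  # "A" and "B"
    rna_counts: dict[str, list[pd.Series]]
    truth: SyntheticTruth


def _planted_effects(
    ts: TranscriptSet, dwell_A: DwellSpec, dwell_B: DwellSpec
) -> pd.DataFrame:
    """Positions whose dwell ratio B/A differs from 1, with the true ratio."""
    rows = []
    changed_codons = {
        c: dwell_B.dwell(c) / dwell_A.dwell(c)
        for c in SENSE_CODONS
        if not np.isclose(dwell_B.dwell(c), dwell_A.dwell(c))
    }
    site_keys = set(dwell_A.site_multipliers) | set(dwell_B.site_multipliers)
    for tid, t in ts.items():
        idx = np.arange(EDGE_EXCLUDE, t.n_codons - EDGE_EXCLUDE)
        identities = t.codon_identities()[idx]
        for ci, cod in zip(idx, identities):
            ratio = changed_codons.get(cod, 1.0)
            if (tid, int(ci)) in site_keys:
                ratio *= dwell_B.site_multipliers.get(
                    (tid, int(ci)), 1.0
                ) / dwell_A.site_multipliers.get((tid, int(ci)), 1.0)
            if not np.isclose(ratio, 1.0):
                rows.append((tid, int(ci), cod, float(ratio)))
    return pd.DataFrame(
        rows, columns=["transcript_id", "codon_index", "codon", "true_ratio"]
    )


def simulate_condition_pair(
    cfg: SimulationConfig,
    dwell_A: DwellSpec,
    dwell_B: DwellSpec,
    seed: int | None = None,
    ts: TranscriptSet | None = None,
) -> ConditionPair:
    """Simulate n_replicates monosome libraries per condition on a shared
    transcriptome, replicate depths jittered log-normally with
    sigma = ``cfg.dispersion``, plus matched per-replicate RNA-seq counts
    drawn from the shared transcript abundances."""
    if cfg.n_replicates < 2:
        raise ConfigurationError("n_replicates must be >= 2 for differential testing")
    base = cfg.seed if seed is None else seed
    seeds = _spawn_seeds(base, 3 + 2 * 2 * cfg.n_replicates)
    if ts is None:
        ts = generate_transcriptome(cfg, seed=seeds[0])
    abundance = sample_abundances(ts, seed=seeds[1])
    depth_rng = _rng(seeds[2])

    libraries: dict[str, list[FootprintSet]] = {"A": [], "B": []}
    rna: dict[str, list[pd.Series]] = {"A": [], "B": []}
    truth = None
    tid_order = list(ts.keys())
    ab_vec = np.array([abundance[t] for t in tid_order])
    si = 3
    for cond, dwell in (("A", dwell_A), ("B", dwell_B)):
        for r in range(cfg.n_replicates):
            depth = max(1, int(round(cfg.depth * depth_rng.lognormal(0.0, cfg.dispersion)))) \
                if cfg.dispersion > 0 else cfg.depth
            fs, tr = simulate_monosome_footprints(
                ts,
                dwell,
                cfg,
                seed=seeds[si],
                depth=depth,
                abundance=abundance,
                library_id=f"{cond}{r + 1}",
            )
            si += 1
            libraries[cond].append(fs)
            if cond == "A" and truth is None:
                truth = tr
            rna_counts = _rng(seeds[si]).multinomial(depth, ab_vec / ab_vec.sum())
            si += 1
            rna[cond].append(pd.Series(rna_counts, index=tid_order, dtype=float))
    assert truth is not None
    truth.planted_effects = _planted_effects(ts, dwell_A, dwell_B)
    return ConditionPair(ts, libraries, rna, truth)


def write_truth(truth: SyntheticTruth, path) -> None:
    """Persist the ground-truth ledger as a TSV (one row per planted fact)."""
    rows = [("abundance", tid, "", f"{v:.8g}") for tid, v in truth.abundance.items()]
    rows += [
        ("codon_multiplier", c, "", f"{v:.8g}")
        for c, v in truth.codon_multipliers.items()
    ]
    rows += [
        ("site_multiplier", tid, str(ci), f"{v:.8g}")
        for (tid, ci), v in truth.site_multipliers.items()
    ]
    rows += [("stall_site", tid, str(ci), "") for tid, ci in truth.stall_sites]
    rows += [("skipped", tid, "", "") for tid in truth.skipped_transcripts]
    pd.DataFrame(rows, columns=["kind", "key", "index", "value"]).to_csv(
        path, sep="\t", index=False
    )
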