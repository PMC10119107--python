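"""Disome profile building, peak calling, matching, and overlap counting."""

import numpy as np
import pandas as pd
import pytest

from ribodyn import disome
from ribodyn import simulate as sim
from ribodyn.calibration import ProfileSet
from ribodyn.io import TranscriptSet
from conftest import make_footprints, make_transcript


@pytest.fixture
def long_tx():
    t = make_transcript(["GCT"] * 98, tid="t1")  # 100 codons
    return t, TranscriptSet([t])


def profile_from_values(t, ts, values, total=1_000_000, library_id="d"):
    prof = np.zeros(t.n_codons)
    prof[5 : 5 + len(values)] = values
    return ProfileSet(library_id, ts, {t.id: prof}, total)


class TestBuildProfiles:
    def test_leading_ribosome_arithmetic(self, long_tx):
        t, ts = long_tx
        # 60-nt record with 5' end at cds_start: leading A-site nt 45 -> codon 15
        fs = make_footprints([("t1", t.cds_start, 60, 3)])
        ps = disome.build_disome_profiles(fs, ts)
        assert ps.profiles["t1"][15] == pytest.approx(1e6)
        assert ps.profiles["t1"].sum() == pytest.approx(1e6)

    def test_trailing_convention(self, long_tx):
        t, ts = long_tx
        fs = make_footprints([("t1", t.cds_start, 60, 3)])
        ps = disome.build_disome_profiles(fs, ts, offset_rule="trailing")
        assert ps.profiles["t1"][5] == pytest.approx(1e6)

    def test_empty_library_empty_profiles(self, long_tx):
        t, ts = long_tx
        fs = make_footprints([])
        ps = disome.build_disome_profiles(fs, ts)
        assert ps.profiles["t1"].sum() == 0

    def test_planted_stall_all_mass_at_codon(self):
        cfg = sim.SimulationConfig(n_transcripts=3, cds_length_range=(120, 150), seed=71)
        ts = sim.generate_transcriptome(cfg)
        tid = next(iter(ts))
        fs = sim.simulate_disome_footprints(ts, [(tid, 50)], cfg, p_stall=1.0, depth=2000)
        ps = disome.build_disome_profiles(fs, ts)
        assert ps.profiles[tid][50] == pytest.approx(1e6)


class TestCallPeaks:
    def test_flat_profile_no_peaks(self, long_tx):
        t, ts = long_tx
        ps = profile_from_values(t, ts, np.full(90, 10.0))
        assert len(disome.call_peaks(ps)) == 0

    def test_single_spike_single_peak(self, long_tx):
        t, ts = long_tx
        vals = np.full(90, 1.0)
        vals[40] = 100.0
        ps = profile_from_values(t, ts, vals)
        peaks = disome.call_peaks(ps, k_fold=4, min_count=5)
        assert len(peaks) == 1
        assert peaks.iloc[0]["summit"] == 45  # window offset 40 + 5
        assert peaks.iloc[0]["intensity"] == pytest.approx(100.0)

    def test_adjacent_spikes_merge(self, long_tx):
        t, ts = long_tx
        vals = np.full(90, 1.0)
        vals[[40, 42]] = 100.0
        ps = profile_from_values(t, ts, vals)
        peaks = disome.call_peaks(ps, merge_gap=2)
        assert len(peaks) == 1
        assert peaks.iloc[0]["codon_start"] == 45
        assert peaks.iloc[0]["codon_end"] == 48

    def test_scaling_invariance(self, long_tx):
        t, ts = long_tx
        rng = np.random.default_rng(2)
        vals = rng.poisson(20, 90).astype(float)
        vals[[10, 60]] = 400.0
        p1 = disome.call_peaks(profile_from_values(t, ts, vals))
        p2 = disome.call_peaks(profile_from_values(t, ts, vals * 3.5, total=int(1e6 * 3.5)))
        pd.testing.assert_frame_equal(
            p1[["codon_start", "codon_end", "summit"]],
            p2[["codon_start", "codon_end", "summit"]],
        )

    def test_short_transcript_skipped(self):
        t = make_transcript(["GCT"] * 28, tid="t1")  # 20 analyzed codons boundary
        ts = TranscriptSet([t])
        vals = np.full(20, 1.0)
        vals[10] = 100.0
        ps = profile_from_values(t, ts, vals)
        assert len(disome.call_peaks(ps, min_codons=21)) == 0


class TestMatchPeaks:
    def _peaks(self, summits, tid="t1"):
        return pd.DataFrame(
            {
                "transcript_id": tid,
                "codon_start": [s - 1 for s in summits],
                "codon_end": [s + 2 for s in summits],
                "summit": summits,
                "intensity": 10.0,
            }
        )

    def test_identical_sets_fully_common(self):
        a = self._peaks([10, 30, 50])
        m = disome.match_peaks(a, a.copy())
        assert (m["common"], m["only_a"], m["only_b"]) == (3, 0, 0)

    def test_disjoint_transcripts_no_match(self):
        a = self._peaks([10], tid="t1")
        b = self._peaks([10], tid="t2")
        m = disome.match_peaks(a, b)
        assert m["common"] == 0
        assert m["union"] == 2

    def test_venn_identity(self):
        a = self._peaks([10, 30, 50, 70])
        b = self._peaks([11, 30, 90])
        m = disome.match_peaks(a, b, tolerance=1)
        assert m["common"] + m["only_a"] + m["only_b"] == m["union"]
        assert m["common"] == 2


class TestPeakFoldChange:
    def test_identical_conditions_zero(self, long_tx):
        t, ts = long_tx
        vals = np.full(90, 1.0)
        vals[40] = 100.0
        ps = profile_from_values(t, ts, vals)
        peaks = disome.call_peaks(ps)
        fc = disome.peak_fold_change(peaks, [ps], [ps])
        assert np.allclose(fc["log2fc"], 0.0)

    def test_doubled_intensity_log2fc_one(self, long_tx):
        t, ts = long_tx
        vals = np.full(90, 1.0)
        vals[40] = 1000.0
        ps_a = profile_from_values(t, ts, vals)
        ps_b = profile_from_values(t, ts, vals * 2)
        peaks = disome.call_peaks(ps_a)
        fc = disome.peak_fold_change(peaks, [ps_a], [ps_b], pseudocount=0.5)
        assert fc["log2fc"].iloc[0] == pytest.approx(1.0, abs=0.01)

    def test_zero_pseudocount_rejected(self, long_tx):
        t, ts = long_tx
        ps = profile_from_values(t, ts, np.ones(90))
        with pytest.raises(ValueError):
            disome.peak_fold_change(pd.DataFrame(columns=disome.PEAK_COLUMNS), [ps], [ps], 0)


class TestCodonsInPeaks:
    def test_no_peaks_no_overlap(self):
        res = disome.codons_in_peaks(
            [("t1", 5)], pd.DataFrame(columns=disome.PEAK_COLUMNS)
        )
        assert res["n_in_peaks"] == 0

    def test_queries_at_summits_all_hit(self):
        peaks = pd.DataFrame(
            {
                "transcript_id": ["t1", "t1"],
                "codon_start": [10, 40],
                "codon_end": [12, 43],
                "summit": [10, 41],
                "intensity": [5.0, 9.0],
            }
        )
        res = disome.codons_in_peaks([("t1", 10), ("t1", 41)], peaks)
        assert res["n_in_peaks"] == 2

    def test_matches_brute_force_on_random_sets(self):
        rng = np.random.default_rng(9)
        peaks = pd.DataFrame(
            {
                "transcript_id": rng.choice(["t1", "t2", "t3"], 30),
                "codon_start": rng.integers(5, 180, 30),
            }
        )
        peaks["codon_end"] = peaks["codon_start"] + rng.integers(1, 4, 30)
        peaks["summit"] = peaks["codon_start"]
        peaks["intensity"] = 1.0
        queries = [
            (tid, int(c))
            for tid, c in zip(rng.choice(["t1", "t2", "t3"], 50), rng.integers(5, 180, 50))
        ]
        tol = 1
        brute = sum(
            any(
                (tid == p.transcript_id)
                and (p.codon_start - tol <= c < p.codon_end + tol)
                for p in peaks.itertuples()
            )
            for tid, c in queries
        )
        assert disome.codons_in_peaks(queries, peaks, tol)["n_in_peaks"] == brute


class TestStallRecovery:
    def test_planted_stalls_recovered_with_high_precision(self):
        cfg = sim.SimulationConfig(n_transcripts=15, cds_length_range=(150, 250), seed=81)
        ts = sim.generate_transcriptome(cfg)
        rng = np.random.default_rng(5)
        sites = []
        tids = list(ts)
        while len(sites) < 20:
            tid = tids[int(rng.integers(len(tids)))]
            lo, hi = sim.disome_codon_range(ts[tid])
            site = (tid, int(rng.integers(lo, hi + 1)))
            if site not in sites:
                sites.append(site)
        fs = sim.simulate_disome_footprints(ts, sites, cfg, p_stall=0.5, depth=100_000, seed=7)
        ps = disome.build_disome_profiles(fs, ts)
        peaks = disome.call_peaks(ps)
        hits = disome.codons_in_peaks(sites, peaks, tolerance=1)
        sensitivity = hits["n_in_peaks"] / len(sites)
        matched_peaks = sum(
            any(
                tid == p.transcript_id and p.codon_start - 1 <= c < p.codon_end + 1
                for tid, c in sites
            )
            for p in peaks.itertuples()
        )
        precision = matched_peaks / len(peaks)
        assert sensitivity >= 0.9
        assert precision >= 0.9
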