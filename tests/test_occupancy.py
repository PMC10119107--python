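"""Relative occupancy, amino-acid aggregation, RUST, CV, and TE."""

import numpy as np
import pandas as pd
import pytest

from ribodyn import calibration as cal
from ribodyn import io as fio
from ribodyn import occupancy as occ
from ribodyn import simulate as sim
from conftest import make_profile_set, make_transcript


@pytest.fixture
def cca_toy():
    """10 analyzed codons: CCA at window positions 0 and 7 with RPM 4,
    eight other positions RPM 1."""
    window = ["CCA", "GCT", "AAA", "TTT", "GGG", "CAT", "GAT", "CCA", "TGC", "CGT"]
    pad = ["ATC"] * 4
    t = make_transcript(pad + window + pad, tid="toy")
    values = np.ones(10)
    values[[0, 7]] = 4.0
    return make_profile_set(t, values)


class TestRelativeOccupancy:
    def test_flat_profile_all_rho_one(self, toy_transcript):
        ps = make_profile_set(toy_transcript, np.full(10, 2.5))
        tab = occ.relative_codon_occupancy(ps, min_mean_rpm=0, min_codons=10)
        assert np.allclose(tab["rho"], 1.0)

    def test_hand_arithmetic(self, cca_toy):
        tab = occ.relative_codon_occupancy(cca_toy, min_mean_rpm=0, min_codons=10)
        # overall mean (2*4 + 8*1)/10 = 1.6
        assert tab.loc["CCA", "rho"] == pytest.approx(4 / 1.6)
        assert tab.loc["GCT", "rho"] == pytest.approx(1 / 1.6)
        assert tab.loc["CCA", "n"] == 2

    def test_normalization_identity(self, cca_toy):
        tab = occ.relative_codon_occupancy(cca_toy, min_mean_rpm=0, min_codons=10)
        assert (tab["n"] * tab["rho"]).sum() / tab["n"].sum() == pytest.approx(
            1.0, abs=1e-9
        )

    def test_scale_invariance(self, cca_toy):
        tab1 = occ.relative_codon_occupancy(cca_toy, min_mean_rpm=0, min_codons=10)
        scaled = make_profile_set(
            cca_toy.transcripts["toy"],
            cca_toy.site_values("toy") * 7.0,
        )
        tab2 = occ.relative_codon_occupancy(scaled, min_mean_rpm=0, min_codons=10)
        assert np.allclose(tab1["rho"], tab2["rho"])

    def test_planted_multiplier_recovered(self):
        cfg = sim.SimulationConfig(
            n_transcripts=20, cds_length_range=(150, 250), depth=1_000_000,
            offframe_noise=0.0, seed=31,
        )
        ts = sim.generate_transcriptome(cfg)
        fs, truth = sim.simulate_monosome_footprints(
            ts, sim.DwellSpec(codon_multipliers={"GCT": 2.0}), cfg
        )
        ps = cal.build_profiles(fio.filter_by_length(fs), ts)
        tab = occ.relative_codon_occupancy(ps, min_codons=20)
        expected = truth.expected_relative_occupancy()
        assert tab.loc["GCT", "rho"] == pytest.approx(expected["GCT"], rel=0.10)
        background = tab.drop(index="GCT")["rho"].median()
        assert tab.loc["GCT", "rho"] / background == pytest.approx(2.0, rel=0.10)

    def test_no_qualifying_transcript_errors(self, cca_toy):
        with pytest.raises(fio.DataError, match="coverage gate"):
            occ.relative_codon_occupancy(cca_toy, min_mean_rpm=1e9, min_codons=10)


class TestAminoAcidAggregation:
    def test_uniform_table(self, toy_transcript):
        ps = make_profile_set(toy_transcript, np.ones(10))
        tab = occ.relative_codon_occupancy(ps, min_mean_rpm=0, min_codons=10)
        agg = occ.aggregate_amino_acid(tab)
        assert np.allclose(agg["rho"], 1.0)

    def test_weighted_mean_over_synonymous_codons(self):
        tab = pd.DataFrame(
            {"n": [10, 5], "rho": [2.0, 4.0], "aa": ["P", "P"]},
            index=pd.Index(["CCA", "CCG"], name="codon"),
        )
        agg = occ.aggregate_amino_acid(tab)
        assert agg.loc["P", "rho"] == pytest.approx((10 * 2 + 5 * 4) / 15)
        assert agg.loc["P", "n"] == 15

    def test_single_codon_amino_acid_passthrough(self):
        tab = pd.DataFrame(
            {"n": [7], "rho": [1.3], "aa": ["M"]},
            index=pd.Index(["ATG"], name="codon"),
        )
        assert occ.aggregate_amino_acid(tab).loc["M", "rho"] == pytest.approx(1.3)


class TestRust:
    def test_hand_oracle_spike_ratio(self):
        # CAA at two of ten analyzed positions with RPM 10, others RPM 1:
        # above-mean set is exactly the CAA positions
        window = ["CAA", "GCT", "AAA", "TTT", "GGG", "CAT", "GAT", "CAA", "TGC", "CGT"]
        t = make_transcript(["ATC"] * 4 + window + ["ATC"] * 4, tid="t1")
        values = np.ones(10)
        values[[0, 7]] = 10.0
        ps = make_profile_set(t, values)
        tab = occ.rust_metafootprint(ps, min_codons=10)
        assert tab.loc["CAA", "observed_freq"] == pytest.approx(1.0)
        assert tab.loc["CAA", "expected_freq"] == pytest.approx(0.2)
        assert tab.loc["CAA", "rust_ratio"] == pytest.approx(5.0)

    def test_spiked_codon_enriched_others_depleted(self, cca_toy):
        tab = occ.rust_metafootprint(cca_toy, min_codons=10)
        assert tab.loc["CCA", "rust_ratio"] > 1
        assert (tab.drop(index="CCA")["rust_ratio"] < 1).all()

    def test_constant_profiles_rejected(self, toy_transcript):
        ps = make_profile_set(toy_transcript, np.ones(10))
        with pytest.raises(fio.DataError, match="RUST"):
            occ.rust_metafootprint(ps, min_codons=10)

    def test_dwell_multiplier_raises_all_synonymous_codons(self):
        cfg = sim.SimulationConfig(
            n_transcripts=30, cds_length_range=(150, 250), depth=1_000_000,
            offframe_noise=0.0, seed=37,
        )
        ts = sim.generate_transcriptome(cfg)
        ala = {c: 2.0 for c in ("GCT", "GCC", "GCA", "GCG")}
        fs, _ = sim.simulate_monosome_footprints(
            ts, sim.DwellSpec(codon_multipliers=ala), cfg
        )
        ps = cal.build_profiles(fio.filter_by_length(fs), ts)
        tab = occ.rust_metafootprint(ps)
        assert (tab.loc[list(ala), "rust_ratio"] > 1).all()


class TestCV:
    def test_constant_profile_zero_cv(self, toy_transcript):
        ps = make_profile_set(toy_transcript, np.full(10, 3.0))
        cv = occ.transcript_cv(ps, min_mean_rpm=0, min_codons=10)
        assert cv["cv"].iloc[0] == 0.0

    def test_hand_arithmetic(self, toy_transcript):
        vals = np.array([1.0, 3.0] * 5)
        ps = make_profile_set(toy_transcript, vals)
        cv = occ.transcript_cv(ps, min_mean_rpm=0, min_codons=10)
        expected = np.std(vals, ddof=1) / 2.0
        assert cv["cv"].iloc[0] == pytest.approx(expected)

    def test_two_point_formula(self):
        # values (1, 3): mean 2, sd sqrt(2), cv ~ 0.7071
        t = make_transcript(["ATC"] * 10, tid="short")  # window of 2 codons
        ps = make_profile_set(t, np.array([1.0, 3.0]))
        cv = occ.transcript_cv(ps, min_mean_rpm=0, min_codons=2)
        assert cv["cv"].iloc[0] == pytest.approx(np.sqrt(2) / 2, abs=1e-9)

    def test_cv_decreases_with_depth_under_uniform_dwell(self):
        medians = []
        for depth in (50_000, 200_000, 800_000):
            cfg = sim.SimulationConfig(
                n_transcripts=10, cds_length_range=(100, 150), depth=depth,
                offframe_noise=0.0, seed=41,
            )
            ts = sim.generate_transcriptome(cfg)
            fs, _ = sim.simulate_monosome_footprints(ts, sim.DwellSpec(), cfg)
            ps = cal.build_profiles(fio.filter_by_length(fs), ts)
            cv = occ.transcript_cv(ps, min_codons=20)
            medians.append(cv["cv"].median())
        assert medians[0] > medians[1] > medians[2]


class TestTE:
    @pytest.fixture
    def te_ts(self):
        return sim.generate_transcriptome(
            sim.SimulationConfig(n_transcripts=3, cds_length_range=(50, 50), seed=2)
        )

    def test_ratio_and_identity(self, te_ts):
        ids = list(te_ts)
        ribo = pd.Series([10.0, 10.0, 10.0], index=ids)
        rna = pd.Series([5.0, 10.0, 10.0], index=ids)
        te = occ.translation_efficiency(ribo, rna, te_ts)
        # equal CDS lengths: densities proportional to count shares
        assert te.loc[ids[0], "te"] == pytest.approx(
            (10 / 30) / (5 / 25), rel=1e-12
        )
        assert te.loc[ids[1], "te"] == pytest.approx((10 / 30) / (10 / 25))

    def test_depth_invariance(self, te_ts):
        ids = list(te_ts)
        ribo = pd.Series([4.0, 8.0, 12.0], index=ids)
        rna = pd.Series([6.0, 6.0, 6.0], index=ids)
        te1 = occ.translation_efficiency(ribo, rna, te_ts)
        te2 = occ.translation_efficiency(ribo * 2, rna, te_ts)
        assert np.allclose(te1["te"], te2["te"])

    def test_zero_rna_undefined(self, te_ts):
        ids = list(te_ts)
        ribo = pd.Series([1.0, 1.0, 1.0], index=ids)
        rna = pd.Series([0.0, 1.0, 1.0], index=ids)
        te = occ.translation_efficiency(ribo, rna, te_ts)
        assert np.isnan(te.loc[ids[0], "te"])
        assert np.isfinite(te.loc[ids[1], "te"])
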