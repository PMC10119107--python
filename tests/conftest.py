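import numpy as np
import pandas as pd
import pytest

from ribodyn.calibration import ProfileSet
from ribodyn.codons import SENSE_CODONS, STOP_CODONS
from ribodyn.io import FootprintSet, Transcript, TranscriptSet
from ribodyn import simulate as sim

UTR = 18


def make_transcript(codons, tid="t1", utr=UTR, rng=None):
    """Transcript from an explicit interior codon list (ATG/stop added)."""
    rng = rng or np.random.default_rng(0)
    for c in codons:
        assert c in SENSE_CODONS, c
    cds = "ATG" + "".join(codons) + "TAA"
    flank5 = "".join(rng.choice(list("ACGT"), size=utr))
    flank3 = "".join(rng.choice(list("ACGT"), size=utr))
    return Transcript(tid, flank5 + cds + flank3, utr, utr + len(cds))


def make_profile_set(transcript, window_values, total_count=1_000_000):
    """ProfileSet with given A-site RPM over the analysis window [5, n-6]."""
    prof = np.zeros(transcript.n_codons)
    prof[5 : 5 + len(window_values)] = window_values
    ts = TranscriptSet([transcript])
    return ProfileSet("toy", ts, {transcript.id: prof}, total_count)


def make_footprints(rows, library_id="lib"):
    return FootprintSet(
        library_id,
        pd.DataFrame(rows, columns=["transcript_id", "five_prime_pos", "length", "count"]),
    )


@pytest.fixture(scope="session")
def small_cfg():
    return sim.SimulationConfig(
        n_transcripts=12,
        cds_length_range=(80, 160),
        depth=200_000,
        offframe_noise=0.05,
        seed=11,
    )


@pytest.fixture(scope="session")
def small_sim(small_cfg):
    """Shared small simulation: CCG dwell tripled."""
    ts = sim.generate_transcriptome(small_cfg)
    dwell = sim.DwellSpec(codon_multipliers={"CCG": 3.0})
    fs, truth = sim.simulate_monosome_footprints(ts, dwell, small_cfg)
    return ts, dwell, fs, truth


@pytest.fixture
def toy_transcript():
    """20-codon transcript whose window codons are known and distinct."""
    window = [
        "CCA", "GCT", "AAA", "TTT", "GGG", "CAT", "GAT", "CCA", "TGC", "CGT",
    ]
    pad = ["ATC"] * 4  # codons 1-4 (excluded) and 15-17 (excluded)
    return make_transcript(pad + window + pad, tid="toy")


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def assert_no_stops(t):
    assert all(c not in STOP_CODONS for c in t.codon_identities()[:-1])
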