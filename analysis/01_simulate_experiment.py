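#!/usr/bin/env python
"""Simulate the full two-genotype footprint experiment used downstream.

Generates a shared transcriptome, four replicate monosome libraries per
genotype (control vs. a Pro/Ala-slow, Lys/Asn-fast mutant), matched RNA-seq
counts, and one disome library per genotype with planted collision sites
(more collision-prone in the mutant). All files land under
results/experiment/ and are re-read by the later drivers.
"""

from pathlib import Path

from ribodyn import pipeline

OUT = Path(__file__).resolve().parent.parent / "results" / "experiment"

CONFIG = {
    "seed": 20260923,
    "simulate": {
        "n_transcripts": 25,
        "cds_length_range": [150, 250],
        "depth": 600_000,
        "n_replicates": 4,
        "dwell_b_codon_multipliers": {
            **{c: 1.5 for c in ("CCT", "CCC", "CCA", "CCG", "GCT", "GCC", "GCA", "GCG")},
            **{c: 0.8 for c in ("AAA", "AAG", "AAT", "AAC")},
        },
        "disome": {"depth": 80_000, "p_stall_a": 0.3, "p_stall_b": 0.6, "n_stall_sites": 20},
    },
    "occupancy": {"min_codons": 50},
    "differential": {"codon_filter_aa": "PA", "min_mean_count": 5},
    "disome": {"k_fold": 4, "min_count": 5, "merge_gap": 1},
}


def main() -> None:
    manifest = pipeline.run(CONFIG, OUT)
    print(f"wrote experiment to {OUT}")
    print(f"config fingerprint {manifest['config_fingerprint']}")
    for stage, secs in manifest["stages"].items():
        print(f"  {stage:12s} {secs:6.2f} s")


if __name__ == "__main__":
    main()
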