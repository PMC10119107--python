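#!/usr/bin/env python
"""Per-codon fold changes and per-position differential pause testing.

On the simulated experiment: amino-acid and codon-level occupancy fold
changes (mutant over control), the Pro/Ala position-level volcano table
with BH-adjusted q-values, and a metagene profile around the significant
positions.
"""

from pathlib import Path

import pandas as pd

from ribodyn import differential as diff
from ribodyn.codons import codons_for

import importlib.util

BASE = Path(__file__).resolve().parent.parent / "results"
EXP = BASE / "experiment"

spec = importlib.util.spec_from_file_location(
    "occ_driver", Path(__file__).with_name("02_occupancy_and_cv.py")
)
occ_driver = importlib.util.module_from_spec(spec)
spec.loader.exec_module(occ_driver)


def main() -> None:
    fc = pd.read_csv(EXP / "fold_change_aa.tsv", sep="\t").set_index("aa")
    print("amino-acid log2 fold changes (mutant / control):")
    print(fc.loc[["P", "A", "K", "N"], "log2fc"].round(3))

    groups = {c: occ_driver.load_profiles(c) for c in ("A", "B")}
    tests = diff.position_differential(
        groups["A"], groups["B"], codon_filter=set(codons_for("PA"))
    )
    sig = tests[tests["significant"]]
    print(
        f"{len(sig)} of {len(tests)} tested Pro/Ala positions significant at q<0.05 "
        f"({(sig['aa'] == 'P').sum()} Pro, {(sig['aa'] == 'A').sum()} Ala)"
    )
    tests.to_csv(BASE / "pause_position_tests.tsv", sep="\t", index=False)

    anchors = list(sig[["transcript_id", "codon_index"]].itertuples(index=False, name=None))
    if anchors:
        mg = {}
        for cond, profiles in groups.items():
            prof, n_used = diff.metagene(profiles, anchors, window=15)
            mg[cond] = prof
        table = pd.DataFrame(mg).rename_axis("offset")
        table.to_csv(BASE / "pause_metagene.tsv", sep="\t")
        peak = table["B"].idxmax()
        print(
            f"metagene over {n_used} anchors peaks at offset {peak} "
            f"(mutant height {table['B'].max():.2f} vs control {table['A'].loc[peak]:.2f})"
        )


if __name__ == "__main__":
    main()
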