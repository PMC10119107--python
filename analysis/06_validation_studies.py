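#!/usr/bin/env python
"""Run the designed validation studies and tabulate their headline numbers.

These are the same studies the acceptance script reports: dwell recovery,
inverted-perturbation anti-correlation, CV vs heterogeneity, differential
calibration and power, disome recovery, and the two worked examples.
"""

from pathlib import Path

import pandas as pd

from ribodyn import scenarios as sc

BASE = Path(__file__).resolve().parent.parent / "results"
SEED = 20260923


def main() -> None:
    rows = []

    venn = sc.peak_venn_worked_example(652, 25, 45)
    rows.append(("disome peak Venn total (652+25+45)", venn["total"]))

    codons = sc.significant_codon_count_example()
    rows.append(("Pro+Ala significant codon total (41+51)", codons["total"]))

    sign = sc.sign_pattern_study(SEED)
    rows.append(("sign-concordant perturbed codons", f"{sign['n_concordant']}/{sign['n_affected']}"))

    rec = sc.dwell_recovery_study(SEED)
    rows.append(("dwell recovery Spearman (5 seeds)", round(rec["spearman_mean"], 4)))

    anti = sc.anticorrelation_study(SEED)
    rows.append(("inverted-perturbation r (A-site)", round(anti["r_a"], 3)))
    rows.append(("inverted-perturbation r (E-site)", round(anti["r_e"], 3)))

    cv = sc.cv_heterogeneity_study(SEED)
    rows.append(("median CV by heterogeneity level", [round(v, 3) for v in cv["median_cv_per_level"]]))
    rows.append(("CV MWU p (high vs none)", f"{cv['mwu_p']:.3g}"))

    null = sc.null_calibration_study(SEED)
    rows.append(("null raw p<0.05 fraction", round(null["raw_p_lt_05_fraction"], 4)))

    power = sc.planted_power_study(SEED)
    rows.append(("planted stall sensitivity (q<0.05)", power["sensitivity"]))
    rows.append(("false-flag rate among significant", power["false_flag_rate"]))

    dis = sc.disome_recovery_study(SEED)
    rows.append(("disome peak sensitivity", dis["sensitivity"]))
    rows.append(("disome peak precision", dis["precision"]))

    table = pd.DataFrame(rows, columns=["quantity", "value"])
    BASE.mkdir(exist_ok=True)
    table.to_csv(BASE / "validation_summary.tsv", sep="\t", index=False)
    print(table.to_string(index=False))


if __name__ == "__main__":
    main()
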