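"""Configuration-driven orchestration of the full analysis.

A run executes simulate (optional) -> calibrate -> occupancy -> differential
-> disome -> integrate, writing every stage table as TSV plus a run manifest
(config content hash, stage timings, dropped-read tallies, version). All
stochastic behaviour flows through the config seed, so a rerun with the same
config reproduces the deterministic stages bit for bit.
"""

from __future__ import annotations

import hashlib
import json
import time
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__, calibration, differential, disome, integration, occupancy
from . import io as fio
from . import simulate as sim
from .codons import codons_for


class ConfigError(ValueError):
    """Invalid pipeline configuration."""


def load_config(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ConfigError(f"{path}: config must be a mapping")
    return cfg


def config_fingerprint(cfg: dict) -> str:
    """Stable content hash of a config (key order independent)."""
    return hashlib.sha256(
        json.dumps(cfg, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]


def _check_paths(cfg: dict) -> None:
    for key in ("transcriptome_fasta", "annotation", "protein_fc"):
        p = cfg.get(key)
        if p is not None and not Path(p).exists():
            raise ConfigError(f"missing input path for {key}: {p}")
    for key in ("libraries", "rna", "disome_libraries"):
        group = cfg.get(key) or {}
        for cond, paths in group.items():
            for p in paths if isinstance(paths, list) else [paths]:
                if not Path(p).exists():
                    raise ConfigError(f"missing {key}[{cond}] path: {p}")


def _simulate_stage(cfg: dict, out: Path, seed: int) -> dict:
    scfg_dict = dict(cfg.get("simulate") or {})
    disome_cfg = scfg_dict.pop("disome", {}) or {}
    mult_b = scfg_dict.pop("dwell_b_codon_multipliers", {}) or {}
    mult_a = scfg_dict.pop("dwell_a_codon_multipliers", {}) or {}
    if "cds_length_range" in scfg_dict:
        scfg_dict["cds_length_range"] = tuple(scfg_dict["cds_length_range"])
    scfg = sim.SimulationConfig(seed=seed, **scfg_dict)
    pair = sim.simulate_condition_pair(
        scfg,
        sim.DwellSpec(codon_multipliers=mult_a),
        sim.DwellSpec(codon_multipliers=mult_b),
    )
    fio.write_transcriptome(pair.transcripts, out / "transcriptome.fa", out / "annotation.tsv")
    for cond, libs in pair.libraries.items():
        for fs in libs:
            fio.write_footprints(fs, out / f"mono_{fs.library_id}.tsv")
    for cond, tabs in pair.rna_counts.items():
        for i, counts in enumerate(tabs, 1):
            fio.write_counts_table(counts, out / f"rna_{cond}{i}.tsv")
    result = {"pair": pair, "disome": None}
    if disome_cfg:
        rng = np.random.default_rng(seed + 1)
        n_sites = int(disome_cfg.get("n_stall_sites", 20))
        sites = []
        tids = list(pair.transcripts)
        while len(sites) < n_sites:
            tid = tids[int(rng.integers(len(tids)))]
            lo, hi = sim.disome_codon_range(pair.transcripts[tid])
            if hi < lo:
                continue
            site = (tid, int(rng.integers(lo, hi + 1)))
            if site not in sites:
                sites.append(site)
        pair.truth.stall_sites = sites
        d_sets = {}
        for cond, p_stall in (
            ("A", float(disome_cfg.get("p_stall_a", disome_cfg.get("p_stall", 0.5)))),
            ("B", float(disome_cfg.get("p_stall_b", disome_cfg.get("p_stall", 0.5)))),
        ):
            fs = sim.simulate_disome_footprints(
                pair.transcripts,
                sites,
                scfg,
                p_stall=p_stall,
                seed=seed + 10 + ord(cond),
                depth=int(disome_cfg.get("depth", 100_000)),
                abundance=pair.truth.abundance,
                library_id=f"disome_{cond}",
            )
            fio.write_footprints(fs, out / f"disome_{cond}.tsv")
            d_sets[cond] = fs
        result["disome"] = d_sets
    sim.write_truth(pair.truth, out / "truth.tsv")
    return result


def run(config: dict, out_dir) -> dict:
    """Execute all configured stages; returns the run manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    _check_paths(config)
    seed = int(config.get("seed", 0))
    manifest: dict = {
        "config_fingerprint": config_fingerprint(config),
        "version": __version__,
        "stages": {},
        "tallies": {},
    }
    stage = "simulate"
    try:
        t0 = time.time()
        if config.get("simulate"):
            simulated = _simulate_stage(config, out, seed)
            pair = simulated["pair"]
            ts = pair.transcripts
            mono = pair.libraries
            rna = pair.rna_counts
            disome_sets = simulated["disome"]
        else:
            ts = fio.read_transcriptome(config["transcriptome_fasta"], config["annotation"])
            mono = {
                cond: [fio.read_footprints(p) for p in paths]
                for cond, paths in (config.get("libraries") or {}).items()
            }
            rna = {
                cond: [fio.read_counts_table(p) for p in paths]
                for cond, paths in (config.get("rna") or {}).items()
            }
            disome_sets = {
                cond: fio.read_footprints(p)
                for cond, p in (config.get("disome_libraries") or {}).items()
            } or None
            pair = None
        manifest["stages"][stage] = round(time.time() - t0, 3)

        stage = "calibrate"
        t0 = time.time()
        cal_cfg = config.get("calibration") or {}
        threshold = float(cal_cfg.get("threshold", 0.5))
        exclude = tuple(cal_cfg.get("exclude", (20, 22)))
        profile_groups: dict[str, list[calibration.ProfileSet]] = {}
        reports = []
        for cond, libs in mono.items():
            profile_groups[cond] = []
            for fs in libs:
                filtered = fio.filter_by_length(fs, exclude_range=exclude)
                scores = calibration.frame_score_by_length(filtered, ts)
                lengths = calibration.select_lengths(scores, threshold, exclude)
                rep = calibration.calibration_report(scores, lengths)
                rep.insert(0, "library_id", fs.library_id)
                reports.append(rep.reset_index())
                ps = calibration.build_profiles(filtered, ts, usable_lengths=lengths)
                manifest["tallies"][fs.library_id] = ps.dropped
                profile_groups[cond].append(ps)
        pd.concat(reports, ignore_index=True).to_csv(
            out / "calibration_report.tsv", sep="\t", index=False
        )
        manifest["stages"][stage] = round(time.time() - t0, 3)

        stage = "occupancy"
        t0 = time.time()
        occ_cfg = config.get("occupancy") or {}
        gate = occ_cfg.get("min_mean_rpm")
        min_codons = int(occ_cfg.get("min_codons", 100))
        occ_tables: dict[str, list[pd.DataFrame]] = {}
        for cond, group in profile_groups.items():
            occ_tables[cond] = []
            for ps in group:
                tab = occupancy.relative_codon_occupancy(
                    ps, min_mean_rpm=gate, min_codons=min_codons
                )
                tab.reset_index().assign(library_id=ps.library_id).to_csv(
                    out / f"occupancy_{ps.library_id}.tsv", sep="\t", index=False
                )
                occ_tables[cond].append(tab)
            cv = pd.concat(
                [
                    occupancy.transcript_cv(ps, min_mean_rpm=gate, min_codons=min_codons)
                    .assign(library_id=ps.library_id)
                    for ps in group
                ],
                ignore_index=True,
            )
            cv.to_csv(out / f"cv_{cond}.tsv", sep="\t", index=False)
        if rna:
            te_rows = []
            for cond in rna:
                for fs, counts in zip(mono.get(cond, []), rna[cond]):
                    te = occupancy.translation_efficiency(
                        occupancy.footprint_counts_per_transcript(fs), counts, ts
                    )
                    te_rows.append(te.assign(library_id=fs.library_id))
            if te_rows:
                pd.concat(te_rows).reset_index().to_csv(out / "te.tsv", sep="\t", index=False)
        manifest["stages"][stage] = round(time.time() - t0, 3)

        stage = "differential"
        t0 = time.time()
        diff_cfg = config.get("differential") or {}
        if set(occ_tables) >= {"A", "B"}:
            fc_codon = differential.codon_fold_change(occ_tables["A"], occ_tables["B"])
            fc_codon.reset_index().to_csv(out / "fold_change_codon.tsv", sep="\t", index=False)
            differential.codon_fold_change(
                occ_tables["A"], occ_tables["B"], by="aa"
            ).reset_index().to_csv(out / "fold_change_aa.tsv", sep="\t", index=False)
            aa_filter = diff_cfg.get("codon_filter_aa")
            codon_filter = set(codons_for(aa_filter)) if aa_filter else None
            tests = differential.position_differential(
                profile_groups["A"],
                profile_groups["B"],
                codon_filter=codon_filter,
                min_mean_count=float(diff_cfg.get("min_mean_count", 5)),
                alpha=float(diff_cfg.get("alpha", 0.05)),
            )
            tests.to_csv(out / "position_tests.tsv", sep="\t", index=False)
            hits = (
                list(
                    tests.loc[tests["significant"], ["transcript_id", "codon_index"]]
                    .itertuples(index=False, name=None)
                )
                if len(tests)
                else []
            )
            if hits:
                mg = {}
                for cond, group in profile_groups.items():
                    prof, n_used = differential.metagene(group, hits, window=int(diff_cfg.get("window", 15)))
                    mg[cond] = prof
                pd.DataFrame(mg).rename_axis("offset").reset_index().to_csv(
                    out / "metagene.tsv", sep="\t", index=False
                )
        else:
            hits = []
        manifest["stages"][stage] = round(time.time() - t0, 3)

        stage = "disome"
        t0 = time.time()
        peak_sets = {}
        if disome_sets:
            dcfg = config.get("disome") or {}
            dprofiles = {
                cond: disome.build_disome_profiles(fs, ts)
                for cond, fs in disome_sets.items()
            }
            for cond, ps in dprofiles.items():
                peaks = disome.call_peaks(
                    ps,
                    k_fold=float(dcfg.get("k_fold", 4)),
                    min_count=float(dcfg.get("min_count", 5)),
                    merge_gap=int(dcfg.get("merge_gap", 1)),
                )
                disome.write_peaks(peaks, out / f"disome_peaks_{cond}.tsv")
                peak_sets[cond] = peaks
            if set(peak_sets) >= {"A", "B"}:
                tol = int(dcfg.get("tolerance", 1))
                match = disome.match_peaks(peak_sets["A"], peak_sets["B"], tol)
                pd.DataFrame(
                    [{k: match[k] for k in ("common", "only_a", "only_b", "union")}]
                ).to_csv(out / "disome_venn.tsv", sep="\t", index=False)
                union = disome.union_peaks(peak_sets["A"], peak_sets["B"], tol)
                disome.peak_fold_change(
                    union, [dprofiles["A"]], [dprofiles["B"]]
                ).to_csv(out / "disome_peak_fc.tsv", sep="\t", index=False)
                if hits:
                    overlap = disome.codons_in_peaks(hits, union, tol)
                    pd.DataFrame(
                        [{k: overlap[k] for k in ("n_queries", "n_in_peaks", "n_outside")}]
                    ).to_csv(out / "pause_codons_in_peaks.tsv", sep="\t", index=False)
        manifest["stages"][stage] = round(time.time() - t0, 3)

        stage = "integrate"
        t0 = time.time()
        if config.get("protein_fc"):
            fc = integration.read_protein_fold_changes(config["protein_fc"])
            gene_sets = {
                "pause": sorted({tid for tid, _ in hits}),
                "disome": sorted(
                    set(peak_sets.get("A", pd.DataFrame(columns=["transcript_id"]))["transcript_id"])
                    | set(peak_sets.get("B", pd.DataFrame(columns=["transcript_id"]))["transcript_id"])
                ),
            }
            extra = config.get("gene_sets") or {}
            gene_sets.update({k: list(v) for k, v in extra.items()})
            gene_sets = {k: v for k, v in gene_sets.items() if v}
            if len(gene_sets) >= 2:
                integration.venn_regions(dict(list(gene_sets.items())[:4])).to_csv(
                    out / "gene_set_venn.tsv", sep="\t", index=False
                )
            for label, ids in gene_sets.items():
                try:
                    comp = integration.cumulative_fraction_compare(fc, ids)
                except ValueError:
                    continue
                comp.table().to_csv(out / f"ecdf_{label}.tsv", sep="\t", index=False)
                pd.DataFrame(
                    [
                        {
                            "set": label,
                            "n_subset": len(comp.subset),
                            "n_background": len(comp.background),
                            "n_missing": len(comp.missing_ids),
                            "mwu_p": comp.p,
                            "median_difference": comp.median_difference,
                        }
                    ]
                ).to_csv(out / f"ecdf_{label}_summary.tsv", sep="\t", index=False)
        manifest["stages"][stage] = round(time.time() - t0, 3)
    except Exception as exc:
        (out / "FAILED").write_text(f"stage: {stage}\n{exc}\n")
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
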