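"""End-to-end evaluation: io -> qc -> concordance -> relatedness -> downsample.

A single :class:`EvaluationConfig` drives the whole comparison and every
threshold defaults to the evaluation protocol's value (MI > 5% site
removal, 90% sample call rate, 90%/0.8 low-agreement flags, <=50%
problematic concordance, 1.5x IQR fences, MQ < 50 regions, DP >= 100 /
QUAL > 20 site annotation, tau = 0.01 parentage, 5% X-heterozygosity sex
boundary, 30X down-sampling).  Reports are plain TSV/BED plus a JSON run
manifest with seeds, effective thresholds, input checksums and the count
accounting of every filter step.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import concord, downsample, qc, relatedness
from .containers import GenotypeMatrix
from .matrixio import (
    intersect_common_sites,
    read_array_matrix,
    read_probe_table,
    read_trios,
    read_vcf_genotypes,
    resolve_duplicate_sites,
)
from .simulate import PAR_START, site_classes

log = logging.getLogger(__name__)


@dataclass
class EvaluationConfig:
    """Paths, thresholds and the root seed of one evaluation run."""

    vcf: str = ""
    array: str = ""
    trios: str = ""
    probes: str = ""
    outdir: str = "evaluation"

    mi_threshold: float = 0.05
    sample_call_rate: float = 0.90
    conc_flag: float = 0.90
    r2_flag: float = 0.8
    conc_problem: float = 0.50
    iqr_k: float = 1.5
    mq_threshold: float = 50.0
    min_run: int = 3
    dp_min: float = 100.0
    qual_min: float = 20.0
    tau: float = 0.01
    het_max: float = 0.05
    y_min_frac: float = 0.5

    downsample_target: float = 30.0
    caller_e: float = 0.01
    caller_min_depth: int = 4
    par_start: int = PAR_START
    seed: int = 0

    @classmethod
    def from_file(cls, path: str | Path) -> "EvaluationConfig":
        path = Path(path)
        if path.suffix == ".toml":
            import tomllib

            with open(path, "rb") as fh:
                data = tomllib.load(fh)
        else:
            with open(path) as fh:
                data = json.load(fh)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"{path}: unknown config keys {sorted(unknown)}")
        return cls(**data)


def _child_seeds(seed: int, n: int = 4) -> list[int]:
    state = np.random.SeedSequence(seed).generate_state(n)
    return [int(s % (2**31)) for s in state]


def _md5(path: str | Path) -> str:
    h = hashlib.md5()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _sex_site_indexes(g: GenotypeMatrix, par_start: int):
    cls = site_classes(g.sites, par_start)
    y = np.where((cls == "y").to_numpy())[0]
    x_np = np.where((cls == "x_nonpar").to_numpy())[0]
    return y, x_np


def summarize_per_chromosome(
    sites: pd.DataFrame,
    stats: pd.DataFrame,
    flagged: np.ndarray | None = None,
) -> pd.DataFrame:
    """Per-chromosome site count, mean MAF, inter-site spacing, depth, MQ.

    Spacing is the mean of successive position differences; NA for a
    chromosome with a single site.  MAF is averaged over defined entries
    only.  Counts sum to the global site count.
    """
    flagged = (
        np.zeros(len(sites), dtype=bool) if flagged is None else np.asarray(flagged)
    )
    rows = []
    for chrom in dict.fromkeys(sites["chrom"]):
        mask = (sites["chrom"] == chrom).to_numpy()
        pos = np.sort(sites.loc[mask, "pos"].to_numpy())
        spacing = float(np.diff(pos).mean()) if len(pos) > 1 else np.nan
        maf = stats.loc[mask, "maf"].to_numpy(dtype=float)
        maf = maf[~np.isnan(maf)]
        rows.append(
            (
                chrom,
                int(mask.sum()),
                float(maf.mean()) if len(maf) else np.nan,
                spacing,
                float(stats.loc[mask, "depth_snp"].mean()),
                float(stats.loc[mask, "mq"].mean()),
                int(flagged[mask].sum()),
            )
        )
    return pd.DataFrame(
        rows,
        columns=[
            "chrom",
            "n_sites",
            "mean_maf",
            "mean_spacing",
            "mean_depth",
            "mean_mq",
            "n_flagged",
        ],
    )


def _write_grm(grm: relatedness.GRM, path: Path) -> None:
    pd.DataFrame(grm.values, index=grm.samples, columns=grm.samples).to_csv(
        path, sep="\t", index_label="sample"
    )


def run_evaluation(cfg: EvaluationConfig) -> dict:
    """Execute the full cross-platform evaluation and write all reports."""
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seeds = _child_seeds(cfg.seed)
    manifest: dict = {
        "seed": cfg.seed,
        "child_seeds": seeds,
        "config": dataclasses.asdict(cfg),
        "inputs": {},
        "counts": {},
    }

    def stage(name: str):
        log.info("run_evaluation: stage %s", name)
        return name

    # ---- io ----------------------------------------------------------
    current = stage("io")
    try:
        vcf_res = read_vcf_genotypes(cfg.vcf)
        arr = read_array_matrix(cfg.array)
        trios = read_trios(cfg.trios)
        probe_table = read_probe_table(cfg.probes) if cfg.probes else None
        for key in ("vcf", "array", "trios", "probes"):
            p = getattr(cfg, key)
            if p:
                manifest["inputs"][key] = {"path": str(p), "md5": _md5(p)}

        seq = vcf_res.genotypes
        stats = vcf_res.site_stats
        counts = manifest["counts"]
        counts["vcf_records_used"] = seq.n_sites
        counts["vcf_records_skipped"] = vcf_res.n_skipped
        counts["array_sites_in"] = arr.n_sites
        counts["array_samples_in"] = arr.n_samples

        # ---- qc: duplicates -> MI -> sample call rate ----------------
        current = stage("qc")
        arr_dedup = resolve_duplicate_sites(arr, seed=seeds[0])
        seq_dedup_idx = resolve_duplicate_sites(seq, seed=seeds[1])
        keep_mask = seq.sites["snp_id"].isin(seq_dedup_idx.sites["snp_id"])
        seq = seq_dedup_idx
        stats = stats.loc[keep_mask.to_numpy()].reset_index(drop=True)
        ad = vcf_res.allele_depth
        ad_idx = np.where(keep_mask.to_numpy())[0]
        ad = type(ad)(ref=ad.ref[:, ad_idx], alt=ad.alt[:, ad_idx])
        counts["array_dup_dropped"] = counts["array_sites_in"] - arr_dedup.n_sites
        counts["seq_dup_dropped"] = counts["vcf_records_used"] - seq.n_sites

        arr_mi, mi_table = qc.mi_filter(arr_dedup, trios, threshold=cfg.mi_threshold)
        counts["mi_removed"] = arr_dedup.n_sites - arr_mi.n_sites
        arr_qc, dropped_samples = qc.sample_call_rate_filter(
            arr_mi, threshold=cfg.sample_call_rate
        )
        counts["samples_dropped_call_rate"] = len(dropped_samples)
        manifest["dropped_samples"] = dropped_samples

        # ---- alignment -----------------------------------------------
        current = stage("intersect")
        pair = intersect_common_sites(seq, arr_qc)
        counts["common_sites"] = pair.seq.n_sites
        counts["common_samples"] = pair.seq.n_samples
        counts["alleles_swapped"] = pair.n_swapped
        counts["allele_mismatch_dropped"] = pair.n_allele_mismatch

        # ---- concordance ---------------------------------------------
        current = stage("concordance")
        samp_rep = concord.sample_report(pair.seq.calls, pair.arr.calls)
        samp_rep.insert(0, "sample", pair.seq.samples)
        site_rep = concord.site_report(pair.seq.calls, pair.arr.calls)
        site_rep = pd.concat(
            [pair.seq.sites[["snp_id", "chrom", "pos"]], site_rep], axis=1
        )
        flags = concord.flag_low_agreement(
            site_rep, conc_min=cfg.conc_flag, r2_min=cfg.r2_flag
        )
        summary = concord.summarize(samp_rep)
        summary["pooled_kappa"] = concord.pooled_kappa(
            pair.seq.calls, pair.arr.calls
        )
        manifest["concordance_summary"] = {
            k: (None if isinstance(v, float) and np.isnan(v) else v)
            for k, v in summary.items()
        }
        manifest["low_agreement"] = {
            "n_low_concordance": len(flags["low_concordance"]),
            "n_low_r2": len(flags["low_r2"]),
            "n_union": len(flags["union"]),
            "n_undefined_r2": flags["n_undefined_r2"],
        }

        # ---- site QC flags and problematic table ---------------------
        current = stage("site_flags")
        depth_flag = qc.iqr_depth_outliers(
            stats["depth_snp"].to_numpy(), k=cfg.iqr_k
        )
        central = qc.central_capture_flags(stats)
        site_pass = qc.site_pass_flags(stats, dp_min=cfg.dp_min, qual_min=cfg.qual_min)
        regions = qc.detect_low_mq_regions(
            pd.DataFrame(
                {
                    "chrom": seq.sites["chrom"],
                    "pos": seq.sites["pos"],
                    "mq": stats["mq"],
                }
            ),
            mq_threshold=cfg.mq_threshold,
            min_run=cfg.min_run,
        )
        # map per-common-site concordance back onto the full seq site table
        conc_by_key = dict(
            zip(
                zip(site_rep["chrom"], site_rep["pos"]),
                site_rep["concordance"],
            )
        )
        conc_full = np.array(
            [
                conc_by_key.get((c, p), np.nan)
                for c, p in zip(seq.sites["chrom"], seq.sites["pos"])
            ]
        )
        mi_by_key = dict(
            zip(
                zip(arr_dedup.sites["chrom"], arr_dedup.sites["pos"]),
                mi_table["mi_rate"],
            )
        )
        mi_full = np.array(
            [
                mi_by_key.get((c, p), np.nan)
                for c, p in zip(seq.sites["chrom"], seq.sites["pos"])
            ]
        )
        problematic = qc.build_problematic_table(
            seq.sites,
            depth_flag,
            central,
            concordance=conc_full,
            conc_threshold=cfg.conc_problem,
            mi_rate=mi_full,
            maf=stats["maf"].to_numpy(),
            depth_snp=stats["depth_snp"].to_numpy(),
            depth_ave=stats["depth_ave"].to_numpy(),
        )
        counts["problematic_sites"] = len(problematic)
        counts["low_mq_regions"] = len(regions)
        counts["site_pass"] = int(site_pass.sum())

        # ---- relatedness ---------------------------------------------
        current = stage("relatedness")
        grm_seq = relatedness.compute_grm(pair.seq)
        grm_arr = relatedness.compute_grm(pair.arr)
        manifest["grm"] = {
            "correlation_with_diagonal": relatedness.grm_correlation(
                grm_seq, grm_arr, include_diagonal=True
            ),
            "correlation_off_diagonal": relatedness.grm_correlation(
                grm_seq, grm_arr, include_diagonal=False
            ),
            "n_sites_seq": grm_seq.n_sites_used,
            "n_sites_arr": grm_arr.n_sites_used,
        }

        current = stage("sex_parentage")
        sex_tables = {}
        for name, gm in (("seq", seq), ("array", arr_dedup)):
            y_idx, x_idx = _sex_site_indexes(gm, cfg.par_start)
            if len(y_idx) >= 1 and len(x_idx) >= 10:
                sex_tables[name] = relatedness.assign_sex(
                    gm, y_idx, x_idx, het_max=cfg.het_max, y_min_frac=cfg.y_min_frac
                )
            else:
                log.info("sex assignment skipped for %s: too few sex-chromosome sites", name)
        if len(sex_tables) == 2:
            merged = sex_tables["seq"].merge(
                sex_tables["array"], on="sample", suffixes=("_seq", "_arr")
            )
            agree = (
                merged["assigned_sex_seq"] == merged["assigned_sex_arr"]
            ).mean()
            manifest["sex_agreement"] = float(agree)

        offspring = [t.offspring for t in trios if t.offspring in pair.seq.samples]
        parentage = {}
        for name, gm in (("seq", pair.seq), ("array", pair.arr)):
            if offspring:
                sexes = (
                    sex_tables.get(name, pd.DataFrame())
                    .set_index("sample")["assigned_sex"]
                    if name in sex_tables
                    else None
                )
                parentage[name] = relatedness.assign_parents(
                    gm, offspring, list(gm.samples), tau=cfg.tau, sexes=sexes
                )
        if len(parentage) == 2:
            acc = {
                name: set(
                    map(
                        tuple,
                        df.loc[df["accepted"], ["offspring", "candidate"]].to_numpy(),
                    )
                )
                for name, df in parentage.items()
            }
            both = acc["seq"] & acc["array"]
            union = acc["seq"] | acc["array"]
            manifest["parentage_agreement"] = (
                float(len(both) / len(union)) if union else 1.0
            )

        # ---- downsample ----------------------------------------------
        current = stage("downsample")
        ds = downsample.reevaluate_at_coverage(
            seq,
            ad,
            arr_qc,
            target=cfg.downsample_target,
            params=downsample.CallerParams(e=cfg.caller_e, min_depth=cfg.caller_min_depth),
            seed=seeds[2],
        )
        manifest["downsample"] = {
            "target": cfg.downsample_target,
            "mean_concordance_full": ds["summary_full"]["mean_concordance"],
            "mean_concordance_thinned": ds["summary_thinned"]["mean_concordance"],
            "delta_concordance": ds["delta_concordance"],
            "grm_corr_full_thinned": ds["grm_corr_full_thinned"],
            "mean_depth_full": ds["mean_depth_full"],
            "mean_depth_thinned": ds["mean_depth_thinned"],
        }

        # ---- reports -------------------------------------------------
        current = stage("report")
        flag_idx = seq.sites["snp_id"].isin(problematic["snp_id"]).to_numpy()
        chrom_summary = summarize_per_chromosome(seq.sites, stats, flagged=flag_idx)

        samp_rep.to_csv(outdir / "per_sample.tsv", sep="\t", index=False)
        site_rep.to_csv(outdir / "per_site.tsv", sep="\t", index=False)
        problematic.to_csv(outdir / "problematic_snps.tsv", sep="\t", index=False)
        qc.regions_to_bed(regions, outdir / "low_mq_regions.bed")
        _write_grm(grm_seq, outdir / "grm_seq.tsv")
        _write_grm(grm_arr, outdir / "grm_array.tsv")
        for name, tbl in sex_tables.items():
            tbl.to_csv(outdir / f"sex_{name}.tsv", sep="\t", index=False)
        for name, tbl in parentage.items():
            tbl.to_csv(outdir / f"parentage_{name}.tsv", sep="\t", index=False)
        ds["thinned"].to_csv(outdir / "downsample_per_sample.tsv", sep="\t", index=True)
        chrom_summary.to_csv(outdir / "per_chromosome.tsv", sep="\t", index=False)
        with open(outdir / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True, default=float)
    except Exception as exc:  # noqa: BLE001 - annotate stage then re-raise
        raise RuntimeError(f"evaluation failed at stage '{current}': {exc}") from exc

    return {
        "manifest": manifest,
        "per_sample": samp_rep,
        "per_site": site_rep,
        "problematic": problematic,
        "regions": regions,
        "grm_seq": grm_seq,
        "grm_array": grm_arr,
        "sex": sex_tables,
        "parentage": parentage,
        "downsample": ds,
        "per_chromosome": chrom_summary,
        "flags": flags,
        "mi_table": mi_table,
        "probe_table": probe_table,
    }
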