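"""Reading, writing and aligning the two platforms' genotype data.

The array platform arrives as a TSV sample x SNP matrix of B-allele counts;
the sequencing platform as a VCF with per-sample GT/AD/DP and per-site
MQ/QUAL.  Both are converted to :class:`~capconcord.containers.GenotypeMatrix`
and aligned on shared (chrom, pos) keys before any comparison.

Coordinates are 1-based (VCF convention) everywhere; region spans are closed
intervals.  Strand flips between platforms are NOT resolved (both simulated
platforms emit plus-strand alleles); only ref/alt swaps are recoded.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from cyvcf2 import VCF

from .containers import (
    MISSING,
    SITE_COLUMNS,
    AlleleDepthMatrix,
    GenotypeMatrix,
    Trio,
)

log = logging.getLogger(__name__)

_ARRAY_META_COLS = ["snp_id", "chrom", "pos", "alleles"]
_VALID_CALLS = {"0", "1", "2", "NA"}


# ----------------------------------------------------------------------
# Array TSV
# ----------------------------------------------------------------------

def read_array_matrix(path: str | Path) -> GenotypeMatrix:
    """Read an array-platform genotype matrix TSV.

    Expected layout: one row per SNP with columns ``snp_id, chrom, pos,
    alleles`` (``REF/ALT``) followed by one column per sample; calls are
    ``0/1/2`` B-allele counts or ``NA`` for a no-call.

    Raises
    ------
    ValueError
        Naming the offending line for malformed rows or calls outside
        ``{0, 1, 2, NA}``.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing_cols = [c for c in _ARRAY_META_COLS if c not in df.columns]
    if missing_cols:
        raise ValueError(f"{path}: missing columns {missing_cols}")
    sample_cols = [c for c in df.columns if c not in _ARRAY_META_COLS]
    if not sample_cols:
        raise ValueError(f"{path}: no sample columns found")

    for i, row in enumerate(df.itertuples(index=False), start=2):  # 1 header line
        d = row._asdict()
        if any(d[c] == "" for c in _ARRAY_META_COLS):
            raise ValueError(f"{path}: malformed row at line {i}: empty metadata field")
        if "/" not in d["alleles"]:
            raise ValueError(
                f"{path}: malformed alleles {d['alleles']!r} at line {i}"
            )
        for c in sample_cols:
            if d[c] not in _VALID_CALLS:
                raise ValueError(
                    f"{path}: invalid call {d[c]!r} for sample {c} at line {i}"
                )

    alleles = df["alleles"].str.split("/", expand=True)
    sites = pd.DataFrame(
        {
            "snp_id": df["snp_id"],
            "chrom": df["chrom"],
            "pos": df["pos"].astype(np.int64),
            "ref": alleles[0],
            "alt": alleles[1],
        }
    )
    calls = (
        df[sample_cols]
        .replace("NA", str(MISSING))
        .to_numpy(dtype=np.int8)
        .T  # rows were sites; matrix is samples x sites
    )
    return GenotypeMatrix(samples=sample_cols, sites=sites, calls=calls)


def write_array_matrix(g: GenotypeMatrix, path: str | Path) -> None:
    """Write a GenotypeMatrix in the array TSV layout (``NA`` for missing)."""
    df = g.sites[["snp_id", "chrom", "pos"]].copy()
    df["alleles"] = g.sites["ref"] + "/" + g.sites["alt"]
    calls = g.calls.T.astype(object)
    for j, s in enumerate(g.samples):
        col = calls[:, j]
        df[s] = ["NA" if c == MISSING else str(int(c)) for c in col]
    df.to_csv(path, sep="\t", index=False)


# ----------------------------------------------------------------------
# VCF
# ----------------------------------------------------------------------

@dataclass
class VcfReadResult:
    """Genotypes plus per-site stats and allele depths parsed from a VCF."""

    genotypes: GenotypeMatrix
    site_stats: pd.DataFrame
    allele_depth: AlleleDepthMatrix
    n_skipped: int = 0
    skip_reasons: dict = field(default_factory=dict)


def read_vcf_genotypes(path: str | Path) -> VcfReadResult:
    """Read biallelic SNP genotypes, AD counts and site stats from a VCF.

    GT is mapped 0/0 -> 0, 0/1 -> 1, 1/1 -> 2, ./. -> MISSING.  Multiallelic
    or symbolic records are skipped and counted, as are non-diploid records
    on autosomes.  Missing AD yields (0, 0) read counts.

    ``depth_snp`` is taken from the ``SNPDP`` INFO tag when present (the
    simulator's expected depth at the targeted base), else the mean of the
    per-sample DP values; ``depth_ave`` from ``AVEDP`` when present.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    vcf = VCF(str(path))
    samples = list(vcf.samples)
    m = len(samples)

    rows = []
    call_rows = []
    ad_ref_rows = []
    ad_alt_rows = []
    stats_rows = []
    skip_reasons: dict[str, int] = {}

    def _skip(reason: str) -> None:
        skip_reasons[reason] = skip_reasons.get(reason, 0) + 1

    for var in vcf:
        if len(var.ALT) != 1:
            _skip("multiallelic")
            continue
        alt = var.ALT[0]
        if not alt or not alt.isalpha() or alt.startswith("<"):
            _skip("symbolic")
            continue
        gts = var.genotypes  # [a0, a1, phased] per sample
        calls = np.full(m, MISSING, dtype=np.int8)
        sexchrom = var.CHROM in ("X", "Y")
        ploidy_bad = False
        for k, gt in enumerate(gts):
            alleles = gt[:-1]
            if len(alleles) == 2:
                a0, a1 = alleles
                if a0 >= 0 and a1 >= 0:
                    calls[k] = a0 + a1
            elif len(alleles) == 1 and sexchrom:
                if alleles[0] >= 0:
                    calls[k] = 2 * alleles[0]  # hemizygous coded 0/2
            else:
                ploidy_bad = True
                break
        if ploidy_bad:
            _skip("ploidy")
            continue

        try:
            ad = var.format("AD")
        except KeyError:
            ad = None
        if ad is None:
            ref_counts = np.zeros(m, dtype=np.int32)
            alt_counts = np.zeros(m, dtype=np.int32)
        else:
            ad = np.asarray(ad)
            ref_counts = np.maximum(ad[:, 0], 0).astype(np.int32)
            alt_counts = np.maximum(ad[:, 1], 0).astype(np.int32)

        try:
            dp = var.format("DP")
        except KeyError:
            dp = None
        if dp is not None:
            depth_snp = float(np.maximum(np.asarray(dp).ravel(), 0).mean())
        else:
            depth_snp = float((ref_counts + alt_counts).mean())
        snpdp = var.INFO.get("SNPDP")
        if snpdp is not None:
            depth_snp = float(snpdp)
        avedp = var.INFO.get("AVEDP")
        mq = var.INFO.get("MQ")

        rows.append(
            (var.ID or f"{var.CHROM}:{var.POS}", var.CHROM, var.POS, var.REF, alt)
        )
        call_rows.append(calls)
        ad_ref_rows.append(ref_counts)
        ad_alt_rows.append(alt_counts)
        stats_rows.append(
            (
                depth_snp,
                float(avedp) if avedp is not None else np.nan,
                float(mq) if mq is not None else np.nan,
                float(var.QUAL) if var.QUAL is not None else np.nan,
            )
        )
    vcf.close()

    if not rows:
        raise ValueError(f"{path}: no usable biallelic records")
    sites = pd.DataFrame(rows, columns=SITE_COLUMNS)
    g = GenotypeMatrix(
        samples=samples, sites=sites, calls=np.column_stack(call_rows)
    )
    stats = pd.DataFrame(
        stats_rows, columns=["depth_snp", "depth_ave", "mq", "qual"]
    )
    stats["maf"] = g.maf()
    stats["call_rate"] = g.site_call_rates()
    n_skipped = int(sum(skip_reasons.values()))
    if n_skipped:
        log.info("read_vcf_genotypes: skipped %d records: %s", n_skipped, skip_reasons)
    ad_matrix = AlleleDepthMatrix(
        ref=np.column_stack(ad_ref_rows), alt=np.column_stack(ad_alt_rows)
    )
    return VcfReadResult(g, stats, ad_matrix, n_skipped, skip_reasons)


_VCF_HEADER = """\
##fileformat=VCFv4.2
##source=capconcord
##INFO=<ID=DP,Number=1,Type=Integer,Description="Total read depth across samples">
##INFO=<ID=MQ,Number=1,Type=Float,Description="RMS mapping quality">
##INFO=<ID=AVEDP,Number=1,Type=Float,Description="Mean read depth over the target region">
##INFO=<ID=SNPDP,Number=1,Type=Float,Description="Expected read depth at the targeted base">
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths (ref,alt)">
##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">
"""

_GT_STR = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}


def write_vcf(
    g: GenotypeMatrix,
    ad: AlleleDepthMatrix,
    stats: pd.DataFrame,
    path: str | Path,
) -> None:
    """Write genotypes + allele depths + site stats as a plain-text VCF."""
    if ad.shape != g.calls.shape:
        raise ValueError("allele-depth shape does not match genotype matrix")
    path = Path(path)
    depth = ad.depth
    chrom_order = list(dict.fromkeys(g.sites["chrom"]))
    with open(path, "w") as fh:
        fh.write(_VCF_HEADER)
        for c in chrom_order:
            fh.write(f"##contig=<ID={c}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(g.samples)
            + "\n"
        )
        sites = g.sites
        for i in range(g.n_sites):
            qual = stats["qual"].iat[i]
            mq = stats["mq"].iat[i]
            info = [f"DP={int(depth[:, i].sum())}"]
            if not np.isnan(mq):
                info.append(f"MQ={mq:g}")
            avedp = stats["depth_ave"].iat[i]
            if not np.isnan(avedp):
                info.append(f"AVEDP={avedp:.4f}")
            snpdp = stats["depth_snp"].iat[i]
            if not np.isnan(snpdp):
                info.append(f"SNPDP={snpdp:.4f}")
            fields = [
                str(sites["chrom"].iat[i]),
                str(int(sites["pos"].iat[i])),
                str(sites["snp_id"].iat[i]),
                str(sites["ref"].iat[i]),
                str(sites["alt"].iat[i]),
                "." if np.isnan(qual) else f"{qual:.2f}",
                "PASS",
                ";".join(info),
                "GT:AD:DP",
            ]
            col = [
                f"{_GT_STR[int(g.calls[k, i])]}:"
                f"{int(ad.ref[k, i])},{int(ad.alt[k, i])}:{int(depth[k, i])}"
                for k in range(g.n_samples)
            ]
            fh.write("\t".join(fields + col) + "\n")


# ----------------------------------------------------------------------
# Pedigree and probe tables
# ----------------------------------------------------------------------

def read_trios(path: str | Path) -> list[Trio]:
    """Read a trio TSV with columns ``offspring, sire, dam``."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    for col in ("offspring", "sire", "dam"):
        if col not in df.columns:
            raise ValueError(f"{path}: trio file lacks column {col!r}")
    return [Trio(r.offspring, r.sire, r.dam) for r in df.itertuples(index=False)]


def write_trios(trios: list[Trio], path: str | Path) -> None:
    pd.DataFrame(
        [(t.offspring, t.sire, t.dam) for t in trios],
        columns=["offspring", "sire", "dam"],
    ).to_csv(path, sep="\t", index=False)


def read_probe_table(path: str | Path) -> pd.DataFrame:
    """Read a target-region table: ``chrom, pos, region_start, region_end``."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    needed = ["chrom", "pos", "region_start", "region_end"]
    missing = [c for c in needed if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: probe table lacks columns {missing}")
    if (df["region_start"] > df["region_end"]).any():
        raise ValueError(f"{path}: region_start > region_end")
    return df


# ----------------------------------------------------------------------
# Duplicate resolution and cross-platform alignment
# ----------------------------------------------------------------------

def resolve_duplicate_sites(g: GenotypeMatrix, seed: int = 0) -> GenotypeMatrix:
    """Keep one site per (chrom, pos): the one with the highest call rate.

    Ties are broken by a seeded uniform draw so runs are reproducible;
    dropped snp_ids are logged.  Idempotent on duplicate-free input.
    """
    rates = g.site_call_rates()
    order = pd.Series(range(g.n_sites))
    groups = order.groupby(
        [g.sites["chrom"].to_numpy(), g.sites["pos"].to_numpy()], sort=False
    )
    rng = np.random.default_rng(seed)
    keep: list[int] = []
    dropped: list[str] = []
    for _, idx in groups:
        idx = idx.to_numpy()
        if len(idx) == 1:
            keep.append(int(idx[0]))
            continue
        r = rates[idx]
        best = idx[r == r.max()]
        chosen = int(best[0]) if len(best) == 1 else int(rng.choice(best))
        keep.append(chosen)
        dropped.extend(g.sites["snp_id"].iloc[i] for i in idx if i != chosen)
    if dropped:
        log.info(
            "resolve_duplicate_sites: dropped %d duplicate sites: %s%s",
            len(dropped),
            dropped[:10],
            "..." if len(dropped) > 10 else "",
        )
    keep.sort()  # preserve input order
    return g.take_sites(keep)


@dataclass
class IntersectResult:
    """Two matrices aligned on shared samples and (chrom, pos) sites."""

    seq: GenotypeMatrix
    arr: GenotypeMatrix
    n_swapped: int = 0
    n_allele_mismatch: int = 0


def intersect_common_sites(
    g_seq: GenotypeMatrix, g_arr: GenotypeMatrix
) -> IntersectResult:
    """Restrict both platforms to shared samples and shared (chrom, pos).

    Sites whose ref/alt are swapped between platforms have the array calls
    recoded 0 <-> 2 (logged); sites whose allele pairs are neither equal nor
    swapped are dropped and counted.  Output order follows the sequencing
    matrix; both outputs share identical indexes.
    """
    shared_samples = [s for s in g_seq.samples if s in set(g_arr.samples)]
    if not shared_samples:
        raise ValueError("no shared samples between platforms")

    arr_key = {
        (c, p): j
        for j, (c, p) in enumerate(zip(g_arr.sites["chrom"], g_arr.sites["pos"]))
    }
    seq_idx: list[int] = []
    arr_idx: list[int] = []
    swap_mask: list[bool] = []
    n_mismatch = 0
    for i, (c, p) in enumerate(zip(g_seq.sites["chrom"], g_seq.sites["pos"])):
        j = arr_key.get((c, p))
        if j is None:
            continue
        ra_seq = (g_seq.sites["ref"].iat[i], g_seq.sites["alt"].iat[i])
        ra_arr = (g_arr.sites["ref"].iat[j], g_arr.sites["alt"].iat[j])
        if ra_seq == ra_arr:
            swap = False
        elif ra_seq == (ra_arr[1], ra_arr[0]):
            swap = True
        else:
            n_mismatch += 1
            continue
        seq_idx.append(i)
        arr_idx.append(j)
        swap_mask.append(swap)
    if not seq_idx:
        raise ValueError("no shared (chrom, pos) sites between platforms")

    seq_out = g_seq.take_samples(
        [g_seq.sample_index(s) for s in shared_samples]
    ).take_sites(seq_idx)
    arr_out = g_arr.take_samples(
        [g_arr.sample_index(s) for s in shared_samples]
    ).take_sites(arr_idx)

    swap_arr = np.asarray(swap_mask)
    n_swapped = int(swap_arr.sum())
    if n_swapped:
        cols = np.where(swap_arr)[0]
        sub = arr_out.calls[:, cols]
        nonmiss = sub != MISSING
        sub[nonmiss] = 2 - sub[nonmiss]
        arr_out.calls[:, cols] = sub
        # adopt the sequencing platform's ref/alt orientation
        arr_out.sites.loc[cols, ["ref", "alt"]] = (
            seq_out.sites.loc[cols, ["ref", "alt"]].to_numpy()
        )
        log.info("intersect_common_sites: recoded %d ref/alt-swapped sites", n_swapped)
    if n_mismatch:
        log.info(
            "intersect_common_sites: dropped %d allele-incompatible sites", n_mismatch
        )
    return IntersectResult(seq_out, arr_out, n_swapped, n_mismatch)
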