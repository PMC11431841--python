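"""Genotype and capture-depth quality control.

Implements trio Mendelian-inconsistency screening, sample call-rate
exclusion, per-site depth/QUAL annotation, IQR depth-outlier and
non-central-capture flags, low-MQ region detection, and assembly of the
problematic-SNP table.  QC steps are applied in the order duplicates ->
Mendelian inconsistency -> sample call rate.
"""

from __future__ import annotations

import logging
from itertools import product

import numpy as np
import pandas as pd

from .containers import MISSING, GenotypeMatrix, RegionInterval, Trio

log = logging.getLogger(__name__)

_GAMETES = {0: (0,), 1: (0, 1), 2: (1,)}


def mendelian_consistent(f: int, m: int, c: int) -> bool:
    """True iff child genotype c can be formed from one allele of each parent.

    All three genotypes must be non-missing B-allele counts in {0, 1, 2};
    callers skip trios with any missing member (uninformative).
    """
    for g in (f, m, c):
        if g not in (0, 1, 2):
            raise ValueError(f"genotypes must be in {{0,1,2}}, got ({f},{m},{c})")
    return any(gf + gm == c for gf, gm in product(_GAMETES[f], _GAMETES[m]))


#: CONSISTENT[f, m, c] lookup over all 27 trio combinations.
CONSISTENT = np.array(
    [
        [[mendelian_consistent(f, m, c) for c in range(3)] for m in range(3)]
        for f in range(3)
    ],
    dtype=bool,
)


def mi_rates(
    g: GenotypeMatrix,
    trios: list[Trio],
    sex_chroms: tuple[str, ...] = ("X", "Y"),
) -> pd.DataFrame:
    """Per-site Mendelian-inconsistency rate over informative trios.

    A trio is informative at a site when offspring, sire and dam are all
    non-missing.  Sex-chromosome sites are excluded from testing (NaN).
    Returns a frame with ``mi_rate``, ``n_informative``, ``n_inconsistent``.
    """
    usable = [
        t
        for t in trios
        if all(s in g.samples for s in (t.offspring, t.sire, t.dam))
    ]
    if not usable:
        raise ValueError("no trio with all three members present in the matrix")
    n = g.n_sites
    n_inf = np.zeros(n, dtype=np.int64)
    n_bad = np.zeros(n, dtype=np.int64)
    testable = ~g.sites["chrom"].isin(sex_chroms).to_numpy()
    for t in usable:
        fc = g.calls[g.sample_index(t.sire)]
        mc = g.calls[g.sample_index(t.dam)]
        cc = g.calls[g.sample_index(t.offspring)]
        inf = testable & (fc != MISSING) & (mc != MISSING) & (cc != MISSING)
        n_inf += inf
        bad = np.zeros(n, dtype=bool)
        bad[inf] = ~CONSISTENT[fc[inf], mc[inf], cc[inf]]
        n_bad += bad
    with np.errstate(invalid="ignore", divide="ignore"):
        rate = np.where(n_inf > 0, n_bad / np.maximum(n_inf, 1), np.nan)
    rate[~testable] = np.nan
    return pd.DataFrame(
        {"mi_rate": rate, "n_informative": n_inf, "n_inconsistent": n_bad}
    )


def mi_filter(
    g: GenotypeMatrix,
    trios: list[Trio],
    threshold: float = 0.05,
    sex_chroms: tuple[str, ...] = ("X", "Y"),
) -> tuple[GenotypeMatrix, pd.DataFrame]:
    """Remove sites whose Mendelian-inconsistency rate exceeds ``threshold``.

    Sites with zero informative trios (or on sex chromosomes) have an
    undefined rate and are kept; the count is logged.  Returns the filtered
    matrix and the per-site MI table with a ``kept`` column (indexed like
    the *input* sites).
    """
    table = mi_rates(g, trios, sex_chroms=sex_chroms)
    rate = table["mi_rate"].to_numpy()
    with np.errstate(invalid="ignore"):
        remove = rate > threshold  # NaN compares False -> kept
    table["kept"] = ~remove
    n_undef = int(np.isnan(rate).sum())
    if n_undef:
        log.info("mi_filter: %d sites with undefined MI rate kept", n_undef)
    if remove.any():
        log.info(
            "mi_filter: removed %d sites with MI > %g", int(remove.sum()), threshold
        )
    return g.take_sites(np.where(~remove)[0]), table


def sample_call_rate_filter(
    g: GenotypeMatrix, threshold: float = 0.90
) -> tuple[GenotypeMatrix, list[str]]:
    """Drop samples whose call rate is below ``threshold``."""
    rates = g.sample_call_rates()
    keep = rates >= threshold
    dropped = [s for s, k in zip(g.samples, keep) if not k]
    if not keep.any():
        raise ValueError("sample call-rate filter removed every sample")
    if dropped:
        log.info(
            "sample_call_rate_filter: dropped %d samples below %.2f: %s",
            len(dropped),
            threshold,
            dropped,
        )
    return g.take_samples(np.where(keep)[0]), dropped


def site_pass_flags(
    stats: pd.DataFrame, dp_min: float = 100.0, qual_min: float = 20.0
) -> pd.Series:
    """Annotation flag: depth_snp >= dp_min AND qual strictly > qual_min.

    Annotates only; no site is removed by this flag.
    """
    return (stats["depth_snp"] >= dp_min) & (stats["qual"] > qual_min)


def iqr_depth_outliers(depths: np.ndarray, k: float = 1.5) -> np.ndarray:
    """Flag per-site depths outside the Tukey fences Q1 - k*IQR, Q3 + k*IQR.

    Quartiles use linear interpolation (quantile type 7).  Returns an
    object array of ``{"low", "high", "none"}``; order-invariant.
    """
    depths = np.asarray(depths, dtype=float)
    if depths.size < 4:
        raise ValueError("IQR outlier detection needs at least 4 sites")
    q1, q3 = np.quantile(depths, [0.25, 0.75])  # numpy default = type 7
    iqr = q3 - q1
    lo, hi = q1 - k * iqr, q3 + k * iqr
    flags = np.full(depths.shape, "none", dtype=object)
    flags[depths < lo] = "low"
    flags[depths > hi] = "high"
    return flags


def central_capture_flags(stats: pd.DataFrame) -> pd.Series:
    """True where the SNP base is at least as deep as its region average.

    ``depth_snp < depth_ave`` marks capture off the region centre.  Sites
    with ``depth_ave == 0`` are undefined (NA) and logged.
    """
    depth_snp = stats["depth_snp"].to_numpy(dtype=float)
    depth_ave = stats["depth_ave"].to_numpy(dtype=float)
    central = pd.array(depth_snp >= depth_ave, dtype="boolean")
    undef = (depth_ave == 0) | np.isnan(depth_ave)
    if undef.any():
        central[undef] = pd.NA
        log.info("central_capture_flags: %d sites with depth_ave == 0", int(undef.sum()))
    return pd.Series(central, index=stats.index, name="central")


def detect_low_mq_regions(
    sites: pd.DataFrame,
    mq_threshold: float = 50.0,
    min_run: int = 3,
) -> list[RegionInterval]:
    """Maximal runs of >= min_run consecutive low-MQ sites per chromosome.

    ``sites`` must carry ``chrom, pos, mq`` and be position-sorted within
    chromosome.  Each interval starts at the position of the first SNP with
    MQ below the threshold and ends at the last.
    """
    out: list[RegionInterval] = []
    for chrom, sub in sites.groupby("chrom", sort=False):
        pos = sub["pos"].to_numpy()
        if not (np.diff(pos) >= 0).all():
            raise ValueError(f"sites on chromosome {chrom} are not position-sorted")
        low = (sub["mq"] < mq_threshold).to_numpy()
        mq = sub["mq"].to_numpy(dtype=float)
        i = 0
        n = len(low)
        while i < n:
            if not low[i]:
                i += 1
                continue
            j = i
            while j < n and low[j]:
                j += 1
            if j - i >= min_run:
                out.append(
                    RegionInterval(
                        chrom=str(chrom),
                        start=int(pos[i]),
                        end=int(pos[j - 1]),
                        mean_mq=float(mq[i:j].mean()),
                        n_sites=j - i,
                    )
                )
            i = j
    return out


def regions_to_bed(regions: list[RegionInterval], path) -> None:
    """Write regions as BED (0-based half-open, converted from 1-based closed)."""
    with open(path, "w") as fh:
        fh.write("# BED intervals: 0-based half-open, from 1-based closed input\n")
        for r in regions:
            fh.write(
                f"{r.chrom}\t{r.start - 1}\t{r.end}\tlow_mq\t{r.mean_mq:.1f}\n"
            )


def build_problematic_table(
    sites: pd.DataFrame,
    depth_flag: np.ndarray,
    central: pd.Series,
    concordance: pd.Series | np.ndarray | None = None,
    conc_threshold: float = 0.50,
    mi_rate: np.ndarray | None = None,
    maf: np.ndarray | None = None,
    depth_snp: np.ndarray | None = None,
    depth_ave: np.ndarray | None = None,
    both_callers: np.ndarray | None = None,
) -> pd.DataFrame:
    """Union of sites flagged for low concordance, depth outliers or off-centre capture.

    One row per problematic site; ``reasons`` is the comma-joined subset of
    ``{low_concordance, depth_outlier_low, depth_outlier_high, non_central}``.
    Sites with undefined concordance contribute no low_concordance reason.
    """
    n = len(sites)
    conc = (
        np.full(n, np.nan)
        if concordance is None
        else np.asarray(concordance, dtype=float)
    )
    depth_flag = np.asarray(depth_flag, dtype=object)
    central_arr = pd.array(central, dtype="boolean")

    with np.errstate(invalid="ignore"):
        low_conc = ~np.isnan(conc) & (conc <= conc_threshold)
    non_central = (central_arr == False).to_numpy(dtype=bool)  # noqa: E712  NA -> False

    reasons = []
    for i in range(n):
        r = []
        if low_conc[i]:
            r.append("low_concordance")
        if depth_flag[i] == "low":
            r.append("depth_outlier_low")
        if depth_flag[i] == "high":
            r.append("depth_outlier_high")
        if non_central[i]:
            r.append("non_central")
        reasons.append(",".join(r))
    reasons = np.array(reasons, dtype=object)
    mask = reasons != ""

    table = sites.loc[mask, ["chrom", "pos", "snp_id"]].copy()
    table["reasons"] = reasons[mask]
    table["concordance"] = conc[mask]
    table["mi_rate"] = (
        np.asarray(mi_rate, dtype=float)[mask] if mi_rate is not None else np.nan
    )
    table["maf"] = np.asarray(maf, dtype=float)[mask] if maf is not None else np.nan
    table["depth_snp"] = (
        np.asarray(depth_snp, dtype=float)[mask] if depth_snp is not None else np.nan
    )
    table["depth_ave"] = (
        np.asarray(depth_ave, dtype=float)[mask] if depth_ave is not None else np.nan
    )
    table["central"] = pd.Series(central_arr[mask]).to_numpy()
    if both_callers is not None:
        table["both_callers"] = np.asarray(both_callers)[mask]
    return table.reset_index(drop=True)
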