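"""Synthetic dual-platform genotyping data.

Simulates a cattle-style cohort — Hardy-Weinberg founder genotypes at
independent sites across 29 autosomes, X (with a pseudoautosomal tail), and
Y — plus trio inheritance, male X hemizygosity, and both platforms'
observation processes:

* array: per-call adjacent-state errors (0<->1, 2<->1) and no-calls;
* sequencing: a capture-depth model (gamma site intensity, planted IQR
  outliers, off-centre capture, low-MQ blocks), Poisson per-sample depths,
  binomial read sampling with per-read error e, and genotypes re-called from
  the reads by the likelihood caller — so sequencing genotype errors emerge
  mechanistically from depth.

Defaults state the study design being emulated: 56 samples (8 males), mean
capture depth 260X over ~250 bp target regions, array call rate ~0.98, and
the reported fractions of depth outliers and off-centre sites.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import MISSING, AlleleDepthMatrix, GenotypeMatrix, Trio
from .downsample import CallerParams, call_genotypes
from . import matrixio

log = logging.getLogger(__name__)

#: Autosome labels and approximate lengths (bp), longest to shortest.
AUTOSOME_LENGTHS = {
    str(i + 1): int(L)
    for i, L in enumerate(np.linspace(158e6, 52e6, 29))
}
X_LENGTH = 139_000_000
Y_LENGTH = 43_300_000
#: Default start of the X pseudoautosomal region (distal tail of the q-arm).
PAR_START = 133_300_000

#: Low-MQ blocks emulating the observed mapping-quality declines in the
#: middle of chromosomes 2, 12 and 27.
DEFAULT_LOWMQ_REGIONS = (
    ("2", 104_825_968, 105_006_704, 30.0),
    ("12", 70_670_517, 75_924_170, 30.0),
    ("27", 5_194_237, 5_919_047, 30.0),
)

_CALLED_SNPS = 71_553  # denominator behind the default artifact fractions


@dataclass(frozen=True)
class SimConfig:
    """Stated world of the simulation; every probability in [0, 1]."""

    n_samples: int = 56
    n_males: int = 8
    n_trios: int = 10
    n_autosomal_sites: int = 10_000
    n_x_nonpar_sites: int = 2_500
    n_y_sites: int = 5
    n_par_sites: int = 66
    maf_low: float = 0.05
    maf_high: float = 0.5
    arr_error: float = 0.005
    arr_missing: float = 0.02
    seq_read_error: float = 0.01
    mean_depth: float = 260.0
    depth_shape: float = 25.0
    frac_offcentre: float = 156 / _CALLED_SNPS
    frac_low_outlier: float = 2_381 / _CALLED_SNPS
    frac_high_outlier: float = 96 / _CALLED_SNPS
    #: ratio of depth at the targeted base to the region average for
    #: centrally captured sites (coverage peaks at the probe centre)
    central_ratio: float = 1.05
    lowmq_regions: tuple = DEFAULT_LOWMQ_REGIONS
    default_mq: float = 60.0
    par_start: int = PAR_START
    caller_min_depth: int = 4
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "arr_error",
            "arr_missing",
            "seq_read_error",
            "frac_offcentre",
            "frac_low_outlier",
            "frac_high_outlier",
        ):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name}={v} outside [0, 1]")
        if self.mean_depth <= 0:
            raise ValueError("mean_depth must be > 0")
        if not (0.0 < self.maf_low <= self.maf_high <= 0.5):
            raise ValueError("maf bounds must satisfy 0 < low <= high <= 0.5")

    @property
    def caller_params(self) -> CallerParams:
        """Caller settings used when turning simulated reads into genotypes."""
        return CallerParams(
            e=max(self.seq_read_error, 1e-4), min_depth=self.caller_min_depth
        )

    def clean(self) -> "SimConfig":
        """A zero-error, artifact-free, constant-depth version of this world.

        Both platforms then reproduce the truth exactly (at saturating
        depth) and every QC flag list is empty.
        """
        return replace(
            self,
            arr_error=0.0,
            arr_missing=0.0,
            seq_read_error=0.0,
            frac_offcentre=0.0,
            frac_low_outlier=0.0,
            frac_high_outlier=0.0,
            depth_shape=np.inf,  # exactly constant capture intensity
            lowmq_regions=(),
        )


@dataclass
class TruthSet:
    """Simulated ground truth: genotypes, sexes, pedigree and frequencies."""

    genotypes: GenotypeMatrix
    sexes: pd.Series  # sample id -> "male" | "female"
    trios: list[Trio]
    p_alt: np.ndarray  # per-site true alternate-allele frequency
    config: SimConfig

    @property
    def samples(self) -> list[str]:
        return self.genotypes.samples

    @property
    def sites(self) -> pd.DataFrame:
        return self.genotypes.sites


@dataclass
class SeqObservation:
    """Sequencing-platform observation: called genotypes, stats, reads.

    ``planted`` records the site indices where the simulator injected
    capture artifacts (keys ``low``, ``high``, ``offcentre``) so recovery
    tests can compare QC flags against the ground truth.
    """

    genotypes: GenotypeMatrix
    site_stats: pd.DataFrame
    allele_depth: AlleleDepthMatrix
    planted: dict = field(default_factory=dict)


def _rngs(seed: int, n: int = 4) -> list[np.random.Generator]:
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]


def _draw_sites(cfg: SimConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Site table: autosomes, non-PAR X, PAR X (distal tail), then Y."""
    chroms: list[str] = []
    positions: list[np.ndarray] = []

    lengths = np.array(list(AUTOSOME_LENGTHS.values()), dtype=float)
    alloc = rng.multinomial(cfg.n_autosomal_sites, lengths / lengths.sum())
    for (chrom, length), k in zip(AUTOSOME_LENGTHS.items(), alloc):
        pos = np.sort(_unique_positions(rng, int(k), 1, length))
        chroms.extend([chrom] * len(pos))
        positions.append(pos)
    x_np = np.sort(
        _unique_positions(rng, cfg.n_x_nonpar_sites, 1, cfg.par_start - 1)
    )
    x_par = np.sort(
        _unique_positions(rng, cfg.n_par_sites, cfg.par_start, X_LENGTH)
    )
    x_all = np.concatenate([x_np, x_par])
    x_all.sort()
    chroms.extend(["X"] * len(x_all))
    positions.append(x_all)
    y = np.sort(_unique_positions(rng, cfg.n_y_sites, 1, Y_LENGTH))
    chroms.extend(["Y"] * len(y))
    positions.append(y)

    pos = np.concatenate(positions)
    n = len(pos)
    bases = np.array(list("ACGT"))
    ref_i = rng.integers(0, 4, n)
    alt_i = (ref_i + rng.integers(1, 4, n)) % 4
    return pd.DataFrame(
        {
            "snp_id": [f"snp{i:06d}" for i in range(n)],
            "chrom": chroms,
            "pos": pos,
            "ref": bases[ref_i],
            "alt": bases[alt_i],
        }
    )


def _unique_positions(
    rng: np.random.Generator, k: int, lo: int, hi: int
) -> np.ndarray:
    if k == 0:
        return np.array([], dtype=np.int64)
    draw = rng.integers(lo, hi + 1, size=max(2 * k, k + 16))
    uniq = np.unique(draw)
    while len(uniq) < k:  # vanishingly rare at genome scale
        extra = rng.integers(lo, hi + 1, size=k)
        uniq = np.unique(np.concatenate([uniq, extra]))
    return rng.permutation(uniq)[:k].astype(np.int64)


def _gamete(g: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """One transmitted allele per site from a diploid genotype vector."""
    het = g == 1
    allele = (g == 2).astype(np.int8)
    allele[het] = (rng.random(int(het.sum())) < 0.5).astype(np.int8)
    return allele


def site_classes(sites: pd.DataFrame, par_start: int = PAR_START) -> pd.Series:
    """Classify sites as autosomal / x_nonpar / x_par / y."""
    cls = pd.Series("autosomal", index=sites.index, dtype=object)
    on_x = sites["chrom"] == "X"
    cls[on_x & (sites["pos"] < par_start)] = "x_nonpar"
    cls[on_x & (sites["pos"] >= par_start)] = "x_par"
    cls[sites["chrom"] == "Y"] = "y"
    return cls


def simulate_truth(cfg: SimConfig) -> TruthSet:
    """Draw founder genotypes under HWE and propagate trios.

    Founders are in Hardy-Weinberg proportions at per-site frequencies
    p ~ Uniform(maf_low, maf_high); each trio offspring receives one
    uniformly chosen allele per parent; male non-PAR X and Y are hemizygous
    (coded 0/2); females are MISSING on Y.  Deterministic under cfg.seed.
    """
    n_founders = cfg.n_samples - cfg.n_trios
    n_female_founders = n_founders - cfg.n_males
    if cfg.n_males > n_founders:
        raise ValueError("n_males exceeds the number of founder samples")
    if cfg.n_trios > 0 and cfg.n_males < 1:
        raise ValueError("trios require at least one male (sire)")
    if cfg.n_trios > n_female_founders:
        raise ValueError(
            f"cannot place {cfg.n_trios} trios: only {n_female_founders} "
            "female founders available as distinct dams"
        )

    rng = _rngs(cfg.seed)[0]
    sites = _draw_sites(cfg, rng)
    n = len(sites)
    cls = site_classes(sites, cfg.par_start)
    diploid_like = (cls == "autosomal") | (cls == "x_par")
    x_np = (cls == "x_nonpar").to_numpy()
    y = (cls == "y").to_numpy()

    p = rng.uniform(cfg.maf_low, cfg.maf_high, n)

    samples = [f"Wagyu_{i + 1:03d}" for i in range(cfg.n_samples)]
    sexes = pd.Series("female", index=samples, dtype=object)
    sexes.iloc[: cfg.n_males] = "male"

    calls = np.full((cfg.n_samples, n), MISSING, dtype=np.int8)
    male_mask = (sexes == "male").to_numpy()

    # founders (first n_founders samples)
    for k in range(n_founders):
        g = rng.binomial(2, p).astype(np.int8)
        if male_mask[k]:
            g[x_np] = 2 * rng.binomial(1, p[x_np]).astype(np.int8)
            g[y] = 2 * rng.binomial(1, p[y]).astype(np.int8)
        else:
            g[y] = MISSING
        calls[k] = g

    # pedigree: sires drawn from the male pool (with replacement; the
    # livestock norm), dams distinct female founders, offspring female
    male_ids = [s for s in samples[:n_founders] if sexes[s] == "male"]
    female_ids = [s for s in samples[:n_founders] if sexes[s] == "female"]
    sires = rng.choice(male_ids, size=cfg.n_trios, replace=True)
    dams = rng.choice(female_ids, size=cfg.n_trios, replace=False)
    trios: list[Trio] = []
    for t in range(cfg.n_trios):
        child = samples[n_founders + t]
        sire, dam = str(sires[t]), str(dams[t])
        trios.append(Trio(offspring=child, sire=sire, dam=dam))
        gs = calls[samples.index(sire)]
        gd = calls[samples.index(dam)]
        g = np.full(n, MISSING, dtype=np.int8)
        dip = diploid_like.to_numpy()
        g[dip] = _gamete(gs[dip], rng) + _gamete(gd[dip], rng)
        # daughter X: the sire's single X allele plus a dam gamete
        g[x_np] = (gs[x_np] // 2).astype(np.int8) + _gamete(gd[x_np], rng)
        calls[samples.index(child)] = g

    gm = GenotypeMatrix(samples=samples, sites=sites, calls=calls)
    return TruthSet(genotypes=gm, sexes=sexes, trios=trios, p_alt=p, config=cfg)


def observe_array(truth: TruthSet, cfg: SimConfig | None = None) -> GenotypeMatrix:
    """Array-platform observation of the truth.

    Each true call is independently a no-call with probability
    ``arr_missing``, else erroneous with probability ``arr_error`` — the
    error moving to an adjacent genotype (0<->1, 2<->1; from 1 to 0 or 2
    equiprobably) — else correct.  Error events are coupled across
    configurations sharing a seed (threshold on a common uniform draw).
    """
    cfg = cfg or truth.config
    rng = _rngs(cfg.seed)[1]
    shape = truth.genotypes.calls.shape
    u_miss = rng.random(shape)
    u_err = rng.random(shape)
    u_dir = rng.random(shape)

    true = truth.genotypes.calls
    obs = true.copy()
    valid = true != MISSING

    err = valid & (u_err < cfg.arr_error)
    from_het = err & (true == 1)
    obs[err & (true == 0)] = 1
    obs[err & (true == 2)] = 1
    obs[from_het] = np.where(u_dir[from_het] < 0.5, 0, 2)
    obs[valid & (u_miss < cfg.arr_missing)] = MISSING

    return GenotypeMatrix(
        samples=list(truth.samples),
        sites=truth.sites.copy(),
        calls=obs,
    )


def observe_sequencing(truth: TruthSet, cfg: SimConfig | None = None) -> SeqObservation:
    """Sequencing-platform observation: capture depths, reads, called genotypes.

    Site capture intensity is Gamma(depth_shape) with mean ``mean_depth``,
    multiplied by 0.1 / 4 at planted low/high depth-outlier sites; at
    off-centre sites the depth at the SNP base is u * depth_ave with
    u ~ Uniform(0.2, 0.9), else ``central_ratio`` * depth_ave.  Per-sample
    depths are Poisson around the site intensity (zero on Y for females);
    alternate-read counts are Binomial(depth, mu_g) with mu = e, 1/2, 1-e by
    true genotype; genotypes and QUAL come from the likelihood caller.

    The reported ``depth_snp``/``depth_ave`` are the capture model's
    expected depths (deterministic per site); realized per-sample depths
    live in the returned AD matrix.
    """
    cfg = cfg or truth.config
    rng = _rngs(cfg.seed)[2]
    sites = truth.sites
    n = len(sites)
    m = len(truth.samples)

    if np.isfinite(cfg.depth_shape):
        peak = cfg.mean_depth / cfg.depth_shape * rng.gamma(cfg.depth_shape, 1.0, n)
    else:  # degenerate: constant capture intensity
        peak = np.full(n, float(cfg.mean_depth))
        rng.gamma(1.0, 1.0, n)  # keep the draw stream aligned across configs
    n_low = int(round(cfg.frac_low_outlier * n))
    n_high = int(round(cfg.frac_high_outlier * n))
    n_off = int(round(cfg.frac_offcentre * n))
    perm = rng.permutation(n)
    low_idx = perm[:n_low]
    high_idx = perm[n_low : n_low + n_high]
    off_idx = perm[n_low + n_high : n_low + n_high + n_off]
    peak[low_idx] *= 0.1
    peak[high_idx] *= 4.0

    depth_ave = peak / cfg.central_ratio
    depth_snp = peak.copy()
    depth_snp[off_idx] = rng.uniform(0.2, 0.9, n_off) * depth_ave[off_idx]

    lam = np.broadcast_to(depth_snp, (m, n)).copy()
    female = (truth.sexes == "female").to_numpy()
    y_sites = (sites["chrom"] == "Y").to_numpy()
    lam[np.ix_(female, y_sites)] = 0.0
    d = rng.poisson(lam).astype(np.int32)

    e = cfg.seq_read_error
    mu = np.empty((m, n))
    true = truth.genotypes.calls
    mu[true == 0] = e
    mu[true == 1] = 0.5
    mu[true == 2] = 1.0 - e
    mu[true == MISSING] = 0.0  # female Y; depth is 0 there anyway
    alt = rng.binomial(d, mu).astype(np.int32)
    ad = AlleleDepthMatrix(ref=d - alt, alt=alt)

    calls, quals = call_genotypes(ad, cfg.caller_params)
    gm = GenotypeMatrix(
        samples=list(truth.samples), sites=sites.copy(), calls=calls
    )

    mq = np.full(n, cfg.default_mq)
    for chrom, start, end, block_mq in cfg.lowmq_regions:
        inside = (
            (sites["chrom"] == str(chrom))
            & (sites["pos"] >= start)
            & (sites["pos"] <= end)
        ).to_numpy()
        mq[inside] = block_mq

    with np.errstate(invalid="ignore"):
        site_qual = np.nanmean(quals, axis=0)
    site_qual = np.nan_to_num(site_qual, nan=0.0)

    stats = pd.DataFrame(
        {
            "depth_snp": depth_snp,
            "depth_ave": depth_ave,
            "mq": mq,
            "qual": site_qual,
            "maf": gm.maf(),
            "call_rate": gm.site_call_rates(),
        }
    )
    return SeqObservation(
        genotypes=gm,
        site_stats=stats,
        allele_depth=ad,
        planted={
            "low": np.sort(low_idx),
            "high": np.sort(high_idx),
            "offcentre": np.sort(off_idx),
        },
    )


def simulate_platforms(
    cfg: SimConfig,
) -> tuple[TruthSet, GenotypeMatrix, SeqObservation]:
    """Convenience: truth plus both platform observations."""
    truth = simulate_truth(cfg)
    return truth, observe_array(truth, cfg), observe_sequencing(truth, cfg)


def write_simulation(
    truth: TruthSet,
    arr: GenotypeMatrix,
    seq: SeqObservation,
    outdir: str | Path,
) -> dict[str, Path]:
    """Write the simulated bundle as plain-text files.

    Emits the sequencing VCF (GT/AD/DP, MQ/QUAL/AVEDP/SNPDP), the array
    TSV, trio and probe tables, sample sexes, and truth tables for oracles.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "vcf": outdir / "seq.vcf",
        "array": outdir / "array.tsv",
        "trios": outdir / "trios.tsv",
        "probes": outdir / "probes.tsv",
        "samples": outdir / "samples.tsv",
        "truth_genotypes": outdir / "truth_genotypes.tsv",
        "truth_sites": outdir / "truth_sites.tsv",
    }
    matrixio.write_vcf(seq.genotypes, seq.allele_depth, seq.site_stats, paths["vcf"])
    matrixio.write_array_matrix(arr, paths["array"])
    matrixio.write_trios(truth.trios, paths["trios"])

    sites = truth.sites
    probes = pd.DataFrame(
        {
            "chrom": sites["chrom"],
            "pos": sites["pos"],
            "region_start": np.maximum(sites["pos"] - 125, 1),
            "region_end": sites["pos"] + 124,
        }
    )
    probes.to_csv(paths["probes"], sep="\t", index=False)

    pd.DataFrame(
        {"sample": truth.samples, "sex": truth.sexes.to_numpy()}
    ).to_csv(paths["samples"], sep="\t", index=False)

    matrixio.write_array_matrix(truth.genotypes, paths["truth_genotypes"])
    pd.DataFrame(
        {
            "snp_id": sites["snp_id"],
            "chrom": sites["chrom"],
            "pos": sites["pos"],
            "p_alt": truth.p_alt,
        }
    ).to_csv(paths["truth_sites"], sep="\t", index=False)
    log.info("write_simulation: wrote %d files to %s", len(paths), outdir)
    return paths
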