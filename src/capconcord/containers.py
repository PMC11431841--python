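"""Core in-memory containers shared by every stage of the evaluation.

Genotypes are stored as B-allele counts: 0 (hom reference, AA), 1 (het, AB)
and 2 (hom alternate, BB), with :data:`MISSING` (-1) as a distinct no-call
sentinel that is never conflated with 0.  Matrices are oriented samples x
sites throughout the package.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Sentinel for a missing genotype call (stored in int8 call matrices).
MISSING: int = -1

#: Columns every site table carries, in order.
SITE_COLUMNS = ["snp_id", "chrom", "pos", "ref", "alt"]


def _as_site_frame(sites: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in SITE_COLUMNS if c not in sites.columns]
    if missing:
        raise ValueError(f"site table lacks required columns: {missing}")
    out = sites.reset_index(drop=True).copy()
    out["pos"] = out["pos"].astype(np.int64)
    if (out["pos"] < 1).any():
        raise ValueError("site positions must be 1-based (pos >= 1)")
    if (out["ref"] == out["alt"]).any():
        bad = out.loc[out["ref"] == out["alt"], "snp_id"].tolist()[:5]
        raise ValueError(f"ref == alt at sites {bad}")
    return out


@dataclass
class GenotypeMatrix:
    """A samples x sites B-allele-count matrix with its indexes.

    Parameters
    ----------
    samples
        Ordered sample identifiers (length m).
    sites
        Site table with columns ``snp_id, chrom, pos, ref, alt`` (length n),
        1-based positions.
    calls
        ``(m, n)`` int8 array with values in ``{0, 1, 2, MISSING}``.
    """

    samples: list[str]
    sites: pd.DataFrame
    calls: np.ndarray

    def __post_init__(self) -> None:
        self.samples = list(self.samples)
        self.sites = _as_site_frame(self.sites)
        self.calls = np.asarray(self.calls, dtype=np.int8)
        m, n = len(self.samples), len(self.sites)
        if self.calls.shape != (m, n):
            raise ValueError(
                f"calls shape {self.calls.shape} != (n_samples={m}, n_sites={n})"
            )
        bad = ~np.isin(self.calls, (0, 1, 2, MISSING))
        if bad.any():
            raise ValueError(
                f"{int(bad.sum())} genotype calls outside {{0,1,2,MISSING}}"
            )
        if len(set(self.samples)) != m:
            raise ValueError("duplicate sample ids")

    # -- shapes ---------------------------------------------------------
    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    # -- call rates -----------------------------------------------------
    def site_call_rates(self) -> np.ndarray:
        """Fraction of non-missing calls per site (length n)."""
        if self.n_samples == 0:
            return np.zeros(self.n_sites)
        return (self.calls != MISSING).mean(axis=0)

    def sample_call_rates(self) -> np.ndarray:
        """Fraction of non-missing calls per sample (length m)."""
        if self.n_sites == 0:
            return np.zeros(self.n_samples)
        return (self.calls != MISSING).mean(axis=1)

    # -- subsetting -----------------------------------------------------
    def take_sites(self, idx) -> "GenotypeMatrix":
        idx = np.asarray(idx)
        return GenotypeMatrix(
            samples=self.samples,
            sites=self.sites.iloc[idx].reset_index(drop=True),
            calls=self.calls[:, idx],
        )

    def take_samples(self, idx) -> "GenotypeMatrix":
        idx = np.asarray(idx)
        return GenotypeMatrix(
            samples=[self.samples[i] for i in idx],
            sites=self.sites,
            calls=self.calls[idx, :],
        )

    def sample_index(self, sample_id: str) -> int:
        return self.samples.index(sample_id)

    def site_positions(self) -> pd.MultiIndex:
        """(chrom, pos) index of the sites, in matrix order."""
        return pd.MultiIndex.from_arrays(
            [self.sites["chrom"], self.sites["pos"]], names=["chrom", "pos"]
        )

    def copy(self) -> "GenotypeMatrix":
        return GenotypeMatrix(
            samples=list(self.samples),
            sites=self.sites.copy(),
            calls=self.calls.copy(),
        )

    def alt_allele_freq(self) -> np.ndarray:
        """Per-site alternate (B) allele frequency over non-missing calls; NaN if all missing."""
        calls = self.calls.astype(float)
        calls[self.calls == MISSING] = np.nan
        with np.errstate(invalid="ignore"):
            return np.nanmean(calls, axis=0) / 2.0

    def maf(self) -> np.ndarray:
        """Per-site minor-allele frequency in [0, 0.5]."""
        p = self.alt_allele_freq()
        return np.minimum(p, 1.0 - p)


@dataclass
class AlleleDepthMatrix:
    """Per-sample, per-site (ref_count, alt_count) sequencing read counts."""

    ref: np.ndarray  # (m, n) int32
    alt: np.ndarray  # (m, n) int32

    def __post_init__(self) -> None:
        self.ref = np.asarray(self.ref, dtype=np.int32)
        self.alt = np.asarray(self.alt, dtype=np.int32)
        if self.ref.shape != self.alt.shape:
            raise ValueError("ref/alt count shapes differ")
        if (self.ref < 0).any() or (self.alt < 0).any():
            raise ValueError("read counts must be non-negative")

    @property
    def depth(self) -> np.ndarray:
        """Total read depth per entry (ref + alt)."""
        return self.ref + self.alt

    @property
    def shape(self) -> tuple[int, int]:
        return self.ref.shape

    def copy(self) -> "AlleleDepthMatrix":
        return AlleleDepthMatrix(self.ref.copy(), self.alt.copy())


#: Columns of a per-site statistics table.
SITESTATS_COLUMNS = ["depth_snp", "depth_ave", "mq", "qual", "maf", "call_rate"]


def validate_site_stats(stats: pd.DataFrame) -> pd.DataFrame:
    """Check a SiteStats table: depths >= 0, MAF in [0, 0.5] (NaN allowed)."""
    missing = [c for c in SITESTATS_COLUMNS if c not in stats.columns]
    if missing:
        raise ValueError(f"site stats table lacks columns: {missing}")
    for col in ("depth_snp", "depth_ave"):
        v = stats[col].to_numpy(dtype=float)
        if np.nanmin(v, initial=0.0) < 0:
            raise ValueError(f"{col} contains negative depths")
    maf = stats["maf"].to_numpy(dtype=float)
    ok = np.isnan(maf) | ((maf >= 0.0) & (maf <= 0.5))
    if not ok.all():
        raise ValueError("maf outside [0, 0.5]")
    return stats


@dataclass(frozen=True)
class Trio:
    """A pedigree trio: offspring with its sire (father) and dam (mother)."""

    offspring: str
    sire: str
    dam: str

    def __post_init__(self) -> None:
        if len({self.offspring, self.sire, self.dam}) != 3:
            raise ValueError(f"trio ids must be distinct: {self}")


@dataclass(frozen=True)
class RegionInterval:
    """A 1-based closed interval of consecutive low-MQ sites."""

    chrom: str
    start: int
    end: int
    mean_mq: float
    n_sites: int = 0

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"start > end in {self}")
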