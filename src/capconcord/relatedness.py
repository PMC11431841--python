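"""Genomic relationships, parentage verification and sex assignment.

The genomic relationship matrix follows VanRaden's first method:
``G = Z Z' / (2 * sum_i p_i (1 - p_i))`` with ``Z = M - 2p`` the centred
samples x sites genotype matrix.  Allele frequencies are estimated from the
analysed cohort itself and missing calls are mean-imputed (replaced by
``2 p_i``); monomorphic sites are dropped.

Parentage uses the opposing-homozygote test: a true parent-offspring pair
cannot be homozygous for different alleles at the same autosomal site
barring genotyping error, so candidates whose opposing-homozygote rate
falls below a small threshold tau are accepted.

Sex is assigned from the presence of Y-marker calls together with the
heterozygosity of the non-pseudoautosomal X: males carry Y calls and are
(hemizygously) homozygous on X; conflicting evidence yields "ambiguous",
never a silent male call.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import MISSING, GenotypeMatrix

log = logging.getLogger(__name__)


@dataclass
class GRM:
    """A symmetric samples x samples VanRaden genomic relationship matrix."""

    samples: list[str]
    values: np.ndarray
    n_sites_used: int = 0
    n_monomorphic_dropped: int = 0

    def __post_init__(self) -> None:
        m = len(self.samples)
        if self.values.shape != (m, m):
            raise ValueError("GRM must be square over its samples")


def compute_grm(g: GenotypeMatrix, freq_eps: float = 1e-12) -> GRM:
    """VanRaden method-1 GRM from a genotype matrix.

    Frequencies come from the matrix itself; missing calls are replaced by
    ``2 p_i`` (mean imputation); monomorphic sites are dropped and logged.
    """
    if g.n_samples < 2:
        raise ValueError("GRM needs at least 2 samples")
    p = g.alt_allele_freq()
    poly = ~np.isnan(p) & (p > freq_eps) & (p < 1.0 - freq_eps)
    n_mono = int((~poly).sum())
    if poly.sum() < 2:
        raise ValueError("GRM needs at least 2 polymorphic sites")
    if n_mono:
        log.info("compute_grm: dropped %d monomorphic sites", n_mono)

    calls = g.calls[:, poly].astype(float)
    p = p[poly]
    calls[calls == MISSING] = np.nan
    Z = calls - 2.0 * p
    Z[np.isnan(Z)] = 0.0  # missing -> 2p, i.e. centred to zero
    denom = 2.0 * float(np.sum(p * (1.0 - p)))
    G = Z @ Z.T / denom
    return GRM(
        samples=list(g.samples),
        values=G,
        n_sites_used=int(poly.sum()),
        n_monomorphic_dropped=n_mono,
    )


def grm_correlation(g1: GRM, g2: GRM, include_diagonal: bool = True) -> float:
    """Pearson correlation between corresponding GRM elements.

    Uses the upper triangle, including the diagonal by default; the
    diagonal can inflate r, so the off-diagonal-only variant is also
    reported by the pipeline.
    """
    if g1.samples != g2.samples:
        raise ValueError("GRMs must be over the identical sample list")
    m = len(g1.samples)
    iu = np.triu_indices(m, k=0 if include_diagonal else 1)
    a, b = g1.values[iu], g2.values[iu]
    if np.array_equal(a, b):  # exact 1.0 for identical matrices
        return 1.0
    return float(np.corrcoef(a, b)[0, 1])


def opposing_homozygote_rate(
    child: np.ndarray, candidate: np.ndarray
) -> tuple[float, int]:
    """Fraction of pairwise-complete sites with opposing homozygotes.

    Returns ``(rate, n_compared)``; rate is NaN when no site is comparable.
    """
    child = np.asarray(child)
    candidate = np.asarray(candidate)
    valid = (child != MISSING) & (candidate != MISSING)
    n = int(valid.sum())
    if n == 0:
        return np.nan, 0
    opp = ((child == 0) & (candidate == 2)) | ((child == 2) & (candidate == 0))
    return float((opp & valid).sum() / n), n


def assign_parents(
    g: GenotypeMatrix,
    offspring_ids: list[str],
    candidate_ids: list[str],
    tau: float = 0.01,
    sexes: pd.Series | None = None,
    autosomes_only: bool = True,
) -> pd.DataFrame:
    """Rank candidate parents per offspring by opposing-homozygote rate.

    Candidates with rate < tau are accepted, ranked ascending; when sexes
    are supplied the best male (sire) and best female (dam) candidates are
    marked.  The offspring itself is never its own candidate.
    """
    if autosomes_only:
        auto = ~g.sites["chrom"].isin(("X", "Y")).to_numpy()
        calls = g.calls[:, auto]
    else:
        calls = g.calls
    rows = []
    for child in offspring_ids:
        ci = g.sample_index(child)
        for cand in candidate_ids:
            if cand == child:
                continue
            rate, n = opposing_homozygote_rate(calls[ci], calls[g.sample_index(cand)])
            rows.append((child, cand, rate, n, bool(rate < tau)))
    df = pd.DataFrame(
        rows, columns=["offspring", "candidate", "rate", "n_compared", "accepted"]
    )
    df["rank"] = df.groupby("offspring")["rate"].rank(method="first")
    if sexes is not None:
        df["candidate_sex"] = df["candidate"].map(sexes)
        df["best_of_sex"] = False
        for (_, _), sub in df.groupby(["offspring", "candidate_sex"], sort=False):
            best = sub["rate"].idxmin()
            df.loc[best, "best_of_sex"] = True
    return df


def assign_sex(
    g: GenotypeMatrix,
    y_sites: np.ndarray,
    x_nonpar_sites: np.ndarray,
    het_max: float = 0.05,
    y_min_frac: float = 0.5,
) -> pd.DataFrame:
    """Per-sample sex call from Y-marker presence and non-PAR X heterozygosity.

    ``y_present`` is true when at least ``y_min_frac`` of the Y sites have a
    non-missing call.  male iff y_present and X het rate < het_max; female
    iff not y_present and X het rate >= het_max; anything else (including
    conflicting evidence) is "ambiguous".
    """
    y_sites = np.asarray(y_sites)
    x_nonpar_sites = np.asarray(x_nonpar_sites)
    if len(y_sites) < 1:
        raise ValueError("sex assignment needs at least one Y site")
    if len(x_nonpar_sites) < 10:
        raise ValueError("sex assignment needs at least 10 non-PAR X sites")
    y_calls = g.calls[:, y_sites]
    x_calls = g.calls[:, x_nonpar_sites]
    y_frac = (y_calls != MISSING).mean(axis=1)
    x_valid = x_calls != MISSING
    n_x = x_valid.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        x_het = np.where(
            n_x > 0, ((x_calls == 1) & x_valid).sum(axis=1) / np.maximum(n_x, 1), np.nan
        )
    rows = []
    for k, sample in enumerate(g.samples):
        y_present = bool(y_frac[k] >= y_min_frac)
        het = x_het[k]
        if np.isnan(het):
            sex = "ambiguous"
        elif y_present and het < het_max:
            sex = "male"
        elif not y_present and het >= het_max:
            sex = "female"
        else:
            sex = "ambiguous"
        rows.append((sample, float(y_frac[k]), y_present, float(het), sex))
    return pd.DataFrame(
        rows,
        columns=["sample", "y_call_frac", "y_present", "x_het_rate", "assigned_sex"],
    )
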