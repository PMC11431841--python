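"""Coverage down-sampling and a minimal biallelic genotype likelihood caller.

The down-sampling experiment emulates cheaper sequencing: allele depths are
binomially thinned to a target mean coverage and genotypes are re-called
from the thinned counts, so the depth-accuracy relationship is mechanistic
(errors emerge from read sampling, not from an injected error rate).

Caller model: reads at a site are independent draws with alternate-allele
probability e (hom ref), 0.5 (het) or 1 - e (hom alt), where e is the
per-read miscall probability.  With a flat prior over {0, 1, 2} the call is
the maximum-likelihood genotype; QUAL is the phred-scaled posterior odds of
the best genotype against the rest, capped at 99.  Likelihood ties resolve
to the heterozygote.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .containers import MISSING, AlleleDepthMatrix


@dataclass(frozen=True)
class CallerParams:
    """Parameters of the likelihood caller.

    e : per-read error probability, in (0, 0.5).
    min_depth : entries with total depth below this are reported MISSING.
    """

    e: float = 0.01
    min_depth: int = 4

    def __post_init__(self) -> None:
        if not (0.0 < self.e < 0.5):
            raise ValueError(f"caller error rate must be in (0, 0.5), got {self.e}")
        if self.min_depth < 0:
            raise ValueError("min_depth must be >= 0")


def thin_depths(
    ad: AlleleDepthMatrix, target: float, seed: int | np.random.Generator = 0
) -> AlleleDepthMatrix:
    """Binomially thin read counts toward a target mean depth.

    Entries with total depth d > target keep each read independently with
    probability target / d (ref and alt counts thinned separately); entries
    with d <= target are unchanged.  Deterministic under ``seed``.
    """
    if target <= 0:
        raise ValueError("target depth must be > 0")
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    d = ad.depth
    with np.errstate(divide="ignore", invalid="ignore"):
        p = np.where(d > target, target / np.maximum(d, 1), 1.0)
    ref = rng.binomial(ad.ref, p).astype(np.int32)
    alt = rng.binomial(ad.alt, p).astype(np.int32)
    return AlleleDepthMatrix(ref=ref, alt=alt)


def _log_likelihoods(
    ref: np.ndarray, alt: np.ndarray, e: float
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-genotype read log-likelihoods, binomial coefficient omitted.

    The C(d, a) factor is common to all three genotypes and cancels in both
    the argmax and the posterior.
    """
    r = ref.astype(float)
    a = alt.astype(float)
    ll0 = a * np.log(e) + r * np.log1p(-e)
    ll1 = (r + a) * np.log(0.5)
    ll2 = r * np.log(e) + a * np.log1p(-e)
    return ll0, ll1, ll2


def call_genotypes(
    ad: AlleleDepthMatrix, params: CallerParams = CallerParams()
) -> tuple[np.ndarray, np.ndarray]:
    """Call genotypes for every (sample, site) entry of an AD matrix.

    Returns
    -------
    calls : int8 array, values in {0, 1, 2, MISSING}
    quals : float array, phred-scaled posterior odds of the call (capped at
        99); NaN where the call is MISSING.
    """
    ll0, ll1, ll2 = _log_likelihoods(ad.ref, ad.alt, params.e)
    # het first so that argmax's first-max tie rule prefers the heterozygote
    stack = np.stack([ll1, ll0, ll2])
    idx = np.argmax(stack, axis=0)
    calls = np.choose(idx, [1, 0, 2]).astype(np.int8)

    best = np.take_along_axis(stack, idx[None], axis=0)[0]
    with np.errstate(over="ignore"):
        total = np.exp(ll0 - best) + np.exp(ll1 - best) + np.exp(ll2 - best)
    post = 1.0 / total  # posterior of the best genotype under a flat prior
    post = np.clip(post, None, 1.0 - 1e-12)
    quals = np.minimum(10.0 * np.log10(post / (1.0 - post)), 99.0)
    quals = np.maximum(quals, 0.0)

    low = ad.depth < params.min_depth
    calls = np.where(low, np.int8(MISSING), calls).astype(np.int8)
    quals = np.where(low, np.nan, quals)
    return calls, quals


def call_genotype_from_ad(
    r: int, a: int, params: CallerParams = CallerParams()
) -> tuple[int, float]:
    """Call a single genotype from (ref_count, alt_count) read counts."""
    ad = AlleleDepthMatrix(
        ref=np.array([[r]], dtype=np.int32), alt=np.array([[a]], dtype=np.int32)
    )
    calls, quals = call_genotypes(ad, params)
    return int(calls[0, 0]), float(quals[0, 0])


def reevaluate_at_coverage(
    seq_gm,
    ad: AlleleDepthMatrix,
    arr_gm,
    target: float,
    params: CallerParams = CallerParams(),
    seed: int = 0,
) -> dict:
    """Thin to a target coverage, re-call, and re-run the comparison.

    Runs thin_depths -> call_genotypes -> concordance and GRM comparison
    against the array platform, side by side for the full-coverage and
    thinned sequencing calls.  Returns a dict with both per-sample reports,
    the mean-concordance delta (full - thinned), and the Pearson
    correlation between the full- and thinned-coverage sequencing GRMs.
    """
    from .containers import GenotypeMatrix
    from . import concord, relatedness
    from .matrixio import intersect_common_sites

    thinned_ad = thin_depths(ad, target, seed)
    thin_calls, _ = call_genotypes(thinned_ad, params)
    thin_gm = GenotypeMatrix(
        samples=list(seq_gm.samples), sites=seq_gm.sites.copy(), calls=thin_calls
    )

    pair_full = intersect_common_sites(seq_gm, arr_gm)
    pair_thin = intersect_common_sites(thin_gm, arr_gm)
    rep_full = concord.sample_report(pair_full.seq.calls, pair_full.arr.calls)
    rep_thin = concord.sample_report(pair_thin.seq.calls, pair_thin.arr.calls)
    sum_full = concord.summarize(rep_full)
    sum_thin = concord.summarize(rep_thin)

    grm_full = relatedness.compute_grm(seq_gm)
    grm_thin = relatedness.compute_grm(thin_gm)
    grm_corr = relatedness.grm_correlation(grm_full, grm_thin)

    return {
        "full": rep_full,
        "thinned": rep_thin,
        "summary_full": sum_full,
        "summary_thinned": sum_thin,
        "delta_concordance": sum_full["mean_concordance"]
        - sum_thin["mean_concordance"],
        "grm_corr_full_thinned": grm_corr,
        "thinned_gm": thin_gm,
        "thinned_ad": thinned_ad,
        "mean_depth_full": float(ad.depth.mean()),
        "mean_depth_thinned": float(thinned_ad.depth.mean()),
    }


def het_miscall_probability(depth: int, params: CallerParams = CallerParams()) -> float:
    """Closed-form probability that a true heterozygote at fixed depth is miscalled.

    Enumerates the caller's decision over all alt-read counts a = 0..depth
    and sums the Binomial(depth, 1/2) tail mass over the region where the
    decision is not heterozygous (including a MISSING decision when depth is
    below the caller's gate).
    """
    from scipy.stats import binom

    if depth < params.min_depth:
        return 1.0
    a = np.arange(depth + 1)
    ad = AlleleDepthMatrix(
        ref=(depth - a)[None, :].astype(np.int32), alt=a[None, :].astype(np.int32)
    )
    calls, _ = call_genotypes(ad, params)
    wrong = calls[0] != 1
    return float(binom.pmf(a[wrong], depth, 0.5).sum())
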