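"""Agreement statistics between the two genotyping platforms.

All statistics operate on a pair of identically indexed samples x sites
B-allele-count matrices (``tg`` = sequencing platform, ``cg`` = array) and
use pairwise-complete deletion: a (sample, site) cell enters a statistic
only when both platforms made a call there.

* concordance: fraction of matching calls, with the mismatches decomposed
  into one-allele (|tg - cg| = 1) and two-allele (= 2) differences;
* R^2: squared Pearson correlation of the two genotype vectors, per sample
  (over sites) and per SNP (over samples);
* Cohen's kappa with squared disagreement weights ((i - j)^2 / (K - 1)^2,
  K = 3 ordered genotype categories), per sample and pooled.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .containers import MISSING

log = logging.getLogger(__name__)


def _check_pair(tg: np.ndarray, cg: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    tg = np.asarray(tg)
    cg = np.asarray(cg)
    if tg.shape != cg.shape:
        raise ValueError(f"paired call shapes differ: {tg.shape} vs {cg.shape}")
    return tg, cg


def concordance_counts(
    tg: np.ndarray, cg: np.ndarray, axis: str = "sample"
) -> pd.DataFrame:
    """Match / one-allele / two-allele difference counts per sample or site.

    ``axis="sample"`` aggregates over sites for each sample (matrix rows);
    ``axis="site"`` over samples for each site.  Units with zero
    pairwise-complete cells get NaN concordance.
    """
    tg, cg = _check_pair(tg, cg)
    if axis not in ("sample", "site"):
        raise ValueError("axis must be 'sample' or 'site'")
    ax = 1 if axis == "sample" else 0
    valid = (tg != MISSING) & (cg != MISSING)
    diff = np.abs(tg.astype(np.int16) - cg.astype(np.int16))
    n_compared = valid.sum(axis=ax)
    n_match = (valid & (diff == 0)).sum(axis=ax)
    n_diff1 = (valid & (diff == 1)).sum(axis=ax)
    n_diff2 = (valid & (diff == 2)).sum(axis=ax)
    with np.errstate(invalid="ignore", divide="ignore"):
        conc = np.where(n_compared > 0, n_match / np.maximum(n_compared, 1), np.nan)
    return pd.DataFrame(
        {
            "n_compared": n_compared,
            "n_match": n_match,
            "n_diff1": n_diff1,
            "n_diff2": n_diff2,
            "concordance": conc,
        }
    )


def _r2_vectors(x: np.ndarray, y: np.ndarray) -> float:
    """Squared Pearson correlation over pairwise-complete entries; NaN if undefined."""
    valid = (x != MISSING) & (y != MISSING)
    if valid.sum() < 2:
        return np.nan
    xv = x[valid].astype(float)
    yv = y[valid].astype(float)
    if np.ptp(xv) == 0 or np.ptp(yv) == 0:
        return np.nan
    r = np.corrcoef(xv, yv)[0, 1]
    return float(r * r)


def r2_per_sample(tg: np.ndarray, cg: np.ndarray) -> np.ndarray:
    """Per-sample squared correlation of the two platforms over sites.

    Undefined (NaN) when fewer than two pairwise-complete sites remain or
    either vector is constant; undefined entries are excluded from summary
    means.
    """
    tg, cg = _check_pair(tg, cg)
    return np.array([_r2_vectors(tg[k], cg[k]) for k in range(tg.shape[0])])


def r2_per_snp(tg: np.ndarray, cg: np.ndarray) -> np.ndarray:
    """Per-SNP squared correlation over samples (roles of axes exchanged)."""
    tg, cg = _check_pair(tg, cg)
    return np.array([_r2_vectors(tg[:, i], cg[:, i]) for i in range(tg.shape[1])])


#: Squared disagreement weights for K = 3 ordered categories.
_KAPPA_W = np.array(
    [[(i - j) ** 2 for j in range(3)] for i in range(3)], dtype=float
) / 4.0


def weighted_kappa(x: np.ndarray, y: np.ndarray) -> float:
    """Cohen's kappa with squared weights between two genotype vectors.

    kappa = 1 - (observed weighted disagreement) / (expected weighted
    disagreement under marginal independence).  When the expected
    disagreement is zero (both raters constant and equal) kappa is 1 by
    convention (logged).  NaN when no pairwise-complete cell exists.
    """
    x, y = _check_pair(np.asarray(x).ravel(), np.asarray(y).ravel())
    valid = (x != MISSING) & (y != MISSING)
    if not valid.any():
        return np.nan
    xv = x[valid].astype(int)
    yv = y[valid].astype(int)
    n = len(xv)
    joint = np.zeros((3, 3))
    np.add.at(joint, (xv, yv), 1.0)
    joint /= n
    po = float((joint * _KAPPA_W).sum())  # observed weighted disagreement
    pe = float((np.outer(joint.sum(axis=1), joint.sum(axis=0)) * _KAPPA_W).sum())
    if pe == 0.0:
        log.info("weighted_kappa: zero expected disagreement; kappa = 1 by convention")
        return 1.0
    return 1.0 - po / pe


def kappa_per_sample(tg: np.ndarray, cg: np.ndarray) -> np.ndarray:
    """Squared-weight kappa for each sample across its sites."""
    tg, cg = _check_pair(tg, cg)
    return np.array([weighted_kappa(tg[k], cg[k]) for k in range(tg.shape[0])])


def pooled_kappa(tg: np.ndarray, cg: np.ndarray) -> float:
    """Squared-weight kappa pooled over every pairwise-complete call."""
    return weighted_kappa(np.asarray(tg).ravel(), np.asarray(cg).ravel())


def sample_report(tg: np.ndarray, cg: np.ndarray) -> pd.DataFrame:
    """Per-sample agreement table: counts, concordance, R^2, kappa."""
    rep = concordance_counts(tg, cg, axis="sample")
    rep["r2"] = r2_per_sample(tg, cg)
    rep["kappa"] = kappa_per_sample(tg, cg)
    return rep


def site_report(tg: np.ndarray, cg: np.ndarray) -> pd.DataFrame:
    """Per-site agreement table: counts, concordance, R^2."""
    rep = concordance_counts(tg, cg, axis="site")
    rep["r2"] = r2_per_snp(tg, cg)
    return rep


def summarize(report: pd.DataFrame) -> dict:
    """Means over defined entries plus the exclusion count per statistic."""
    out: dict[str, float | int] = {}
    for col in ("concordance", "r2", "kappa"):
        if col not in report.columns:
            continue
        v = report[col].to_numpy(dtype=float)
        defined = ~np.isnan(v)
        out[f"mean_{col}"] = float(v[defined].mean()) if defined.any() else np.nan
        out[f"n_undefined_{col}"] = int((~defined).sum())
    out["n_units"] = int(len(report))
    return out


def flag_low_agreement(
    site_rep: pd.DataFrame, conc_min: float = 0.90, r2_min: float = 0.8
) -> dict:
    """Site index lists with concordance < conc_min or R^2 < r2_min.

    Sites with undefined R^2 join neither list; they are counted
    separately.  The union of both lists is also returned.
    """
    conc = site_rep["concordance"].to_numpy(dtype=float)
    r2 = site_rep["r2"].to_numpy(dtype=float)
    with np.errstate(invalid="ignore"):
        low_conc = np.where(~np.isnan(conc) & (conc < conc_min))[0]
        low_r2 = np.where(~np.isnan(r2) & (r2 < r2_min))[0]
    return {
        "low_concordance": low_conc.tolist(),
        "low_r2": low_r2.tolist(),
        "union": sorted(set(low_conc.tolist()) | set(low_r2.tolist())),
        "n_undefined_r2": int(np.isnan(r2).sum()),
    }
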