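"""Group-level inference across participants.

Per-subject statistic maps (voxelwise r values, or ITC t values) are tested
against zero with one-sample t-tests; voxelwise familywise error is
controlled by sign-flip permutation of subject maps with the max-statistic
("omnibus") correction, exhaustively enumerated for up to 12 subjects (4096
sign patterns); families of p-values across frequencies, time bins, ROIs and
regressor types are controlled with the Benjamini-Hochberg false discovery
rate.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "GroupMapResult",
    "FDRResult",
    "one_sample_group_test",
    "permutation_omnibus",
    "fdr_correct",
]

#: subjects up to which all 2^n sign flips are enumerated
EXHAUSTIVE_MAX_SUBJECTS = 12


def one_sample_group_test(values: np.ndarray, fisher_z: bool = False):
    """One-sample t-test of per-subject statistics against zero, per cell.

    ``values`` is (subjects, ...).  Returns ``(t, p, zero_variance_mask)``
    with two-sided p.  r values enter untransformed by default; pass
    ``fisher_z=True`` to test arctanh(r) instead.
    """
    values = np.atleast_2d(np.asarray(values, float))
    n = values.shape[0]
    if n < 2:
        raise ValueError("need at least 2 subjects")
    if fisher_z:
        values = np.arctanh(np.clip(values, -1 + 1e-12, 1 - 1e-12))
    mean = values.mean(0)
    sd = values.std(0, ddof=1)
    zero_var = sd == 0
    # identical values that are zero to numerical precision count as null
    null_mean = np.abs(mean) < 1e-12
    with np.errstate(invalid="ignore", divide="ignore"):
        t = mean / (sd / np.sqrt(n))
        t = np.where(zero_var & null_mean, 0.0, t)
        t = np.where(zero_var & ~null_mean, np.inf * np.sign(mean), t)
    p = 2 * stats.t.sf(np.abs(t), df=n - 1)
    p = np.where(np.isinf(t), 0.0, p)
    p = np.where(zero_var & null_mean, 1.0, p)
    return t, p, zero_var


@dataclass
class GroupMapResult:
    mean_map: np.ndarray
    t_map: np.ndarray
    p_corrected: np.ndarray  # omnibus (max-|t|) corrected p per voxel
    n_subjects: int
    n_permutations: int
    exhaustive: bool
    seed: int | None = None


def _sign_matrix(n_subjects: int, n_perm: int | None, seed):
    """(P, n_subjects) matrix of +-1 sign patterns; exhaustive when feasible."""
    if n_subjects <= EXHAUSTIVE_MAX_SUBJECTS and (
        n_perm is None or n_perm >= 2**n_subjects
    ):
        codes = np.arange(2**n_subjects)[:, None] >> np.arange(n_subjects)
        return 1 - 2 * (codes & 1), True
    if n_perm is None:
        n_perm = 4096
    rng = np.random.default_rng(seed)
    signs = rng.choice([-1, 1], size=(n_perm - 1, n_subjects))
    # the identity permutation is always included
    return np.vstack([np.ones((1, n_subjects), int), signs]), False


def permutation_omnibus(
    maps: np.ndarray,
    n_perm: int | None = None,
    seed: int | None = None,
) -> GroupMapResult:
    """Sign-flip permutation test with max-statistic multiple-comparison
    correction across voxels.

    ``maps`` is (subjects, voxels).  For each sign pattern the one-sample t
    is computed per voxel and the maximum |t| across voxels recorded; the
    corrected p of a voxel is the fraction of patterns whose maximum reaches
    its observed |t|.  With <= 12 subjects all 2^n patterns are enumerated
    (exact, seed free); otherwise Monte Carlo patterns are drawn, always
    including the identity.
    """
    maps = np.atleast_2d(np.asarray(maps, float))
    n_sub, n_vox = maps.shape
    if n_sub < 2:
        raise ValueError("need at least 2 subjects")
    if n_perm is not None and n_perm < 10:
        raise ValueError("need at least 10 permutations")
    signs, exhaustive = _sign_matrix(n_sub, n_perm, seed)
    sums = signs @ maps  # (P, V)
    sumsq = np.sum(maps**2, axis=0)  # invariant under sign flips
    mean = sums / n_sub
    var = (sumsq[None, :] - n_sub * mean**2) / (n_sub - 1)
    with np.errstate(invalid="ignore", divide="ignore"):
        t = mean / np.sqrt(var / n_sub)
    t = np.nan_to_num(t, nan=0.0, posinf=np.inf, neginf=-np.inf)
    max_null = np.max(np.abs(t), axis=1)
    t_obs = t[0]  # row 0 is the identity (all +1) pattern in both modes
    p_corr = np.mean(max_null[:, None] >= np.abs(t_obs)[None, :] - 1e-12, axis=0)
    return GroupMapResult(
        mean_map=maps.mean(0),
        t_map=t_obs,
        p_corrected=p_corr,
        n_subjects=n_sub,
        n_permutations=signs.shape[0],
        exhaustive=exhaustive,
        seed=None if exhaustive else seed,
    )


@dataclass
class FDRResult:
    pvals: np.ndarray
    p_adjusted: np.ndarray
    reject: np.ndarray
    q: float
    context: pd.DataFrame | None = field(default=None, repr=False)


def fdr_correct(pvals, q: float = 0.05, context: pd.DataFrame | None = None) -> FDRResult:
    """Benjamini-Hochberg step-up over a declared family of p-values.

    ``context`` optionally carries one row per p-value (frequency, time bin,
    ROI, regressor type, ...) and is returned with ``p_adjusted``/``reject``
    columns added.
    """
    pvals = np.asarray(pvals, float).ravel()
    if pvals.size == 0:
        raise ValueError("empty p-value family")
    if np.any((pvals <= 0) | (pvals > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    reject, p_adj, _, _ = multipletests(pvals, alpha=q, method="fdr_bh")
    if context is not None:
        context = context.copy()
        context["p"] = pvals
        context["p_adjusted"] = p_adj
        context["reject"] = reject
    return FDRResult(pvals=pvals, p_adjusted=p_adj, reject=reject, q=q, context=context)
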