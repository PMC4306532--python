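"""Reaction-time correction cascade and variance accounting.

Builds the regressor variants used throughout the analysis:

* ``raw_rt`` — measured saccade latency;
* ``rt_corrected`` — linear inter-trial-interval effect removed, then all
  nine (current x previous) condition cells renormalized to the grand mean,
  isolating variance not attributable to the experimental design;
* ``rt_detrended`` — additionally, blockwise offsets and linear trends over
  trial order removed (fatigue/practice at the block time scale);
* ``rt_v1corrected`` — latency residualized for its linear association with
  mean V1 band amplitude, to expose contributions independent of V1.

Every correction is a renormalization (the grand mean is preserved), applied
sequentially in the order above; the ledger records each step's share of the
raw variance.  Corrections are estimated per dataset (per participant),
never pooled, since the underlying effects are subject specific.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd

from .synthetic import CONDITIONS

__all__ = [
    "VarianceLedger",
    "RegressorSet",
    "correct_iti",
    "renormalize_conditions",
    "detrend_blocks",
    "correct_v1_power",
    "variance_explained",
    "build_regressors",
]

#: minimal trials per (current x previous) cell before falling back to
#: marginal current-condition means
MIN_CELL = 5


@dataclass
class VarianceLedger:
    """Sequential shares of the raw RT variance removed by each correction."""

    fraction_iti: float = 0.0
    fraction_condition: float = 0.0
    fraction_block_trends: float = 0.0
    fraction_v1: float = 0.0
    fraction_residual: float = 1.0

    def as_dict(self):
        return asdict(self)


@dataclass
class RegressorSet:
    raw_rt: np.ndarray
    rt_corrected: np.ndarray
    rt_detrended: np.ndarray
    ledger: VarianceLedger
    rt_v1corrected: np.ndarray | None = None

    def to_frame(self, table: pd.DataFrame | None = None) -> pd.DataFrame:
        out = pd.DataFrame(
            {
                "raw_rt": self.raw_rt,
                "rt_corrected": self.rt_corrected,
                "rt_detrended": self.rt_detrended,
            }
        )
        if self.rt_v1corrected is not None:
            out["rt_v1corrected"] = self.rt_v1corrected
        if table is not None:
            out.index = table.index
            out.insert(0, "trial_id", table["trial_id"].to_numpy())
        return out


def _residualize_linear(y: np.ndarray, x: np.ndarray, what: str) -> np.ndarray:
    """Remove the least-squares linear effect of ``x``, preserving the mean."""
    y = np.asarray(y, float)
    x = np.asarray(x, float)
    if y.size < 3:
        raise ValueError("need at least 3 trials")
    xc = x - x.mean()
    vx = xc @ xc
    if vx == 0:
        warnings.warn(f"{what} is constant; returning input unchanged")
        return y.copy()
    b = (xc @ (y - y.mean())) / vx
    return y - b * xc


def correct_iti(rt: np.ndarray, iti: np.ndarray) -> np.ndarray:
    """Remove the linear inter-trial-interval effect (mean preserved)."""
    return _residualize_linear(rt, iti, "iti")


def correct_v1_power(rt: np.ndarray, v1_amp: np.ndarray) -> np.ndarray:
    """Residualize RT for its linear trend on mean V1 band amplitude."""
    return _residualize_linear(rt, v1_amp, "v1 amplitude")


def renormalize_conditions(
    rt: np.ndarray,
    current: np.ndarray,
    previous: np.ndarray,
    min_cell: int = MIN_CELL,
) -> np.ndarray:
    """Equalize the mean RT of all nine (current x previous) condition cells.

    Each trial's cell mean is replaced by the grand mean.  Trials whose cell
    is under-filled (< ``min_cell``) or whose previous condition is the
    session-start placeholder fall back to a marginal current-condition
    grouping (flagged with a warning): they are renormalized by the mean of
    the fallback trials sharing their current condition, which keeps the
    grand mean exact and never increases variance.
    """
    rt = np.asarray(rt, float)
    current = np.asarray(current, object)
    previous = np.asarray(previous, object)
    grand = rt.mean()
    out = rt.copy()
    fallback = ~np.isin(previous, CONDITIONS)
    for c in CONDITIONS:
        for p in CONDITIONS:
            sel = (current == c) & (previous == p)
            k = int(sel.sum())
            if k == 0:
                continue
            if k >= min_cell:
                out[sel] = rt[sel] - rt[sel].mean() + grand
            else:
                fallback |= sel
    if fallback.any():
        if (fallback & np.isin(previous, CONDITIONS)).any():
            warnings.warn(
                f"cells with fewer than {min_cell} trials renormalized with "
                "marginal current-condition means"
            )
        for c in CONDITIONS:
            sel = fallback & (current == c)
            if sel.any():
                out[sel] = rt[sel] - rt[sel].mean() + grand
    return out


def detrend_blocks(
    rt: np.ndarray, block: np.ndarray, time_in_block: np.ndarray
) -> np.ndarray:
    """Remove each block's offset and linear trend over trial order.

    Within every block the OLS line of RT on trial index is subtracted and
    the grand mean re-added, so output blockwise slopes are exactly zero and
    all block means equal the grand mean.  Blocks with fewer than 3 trials
    are left unchanged (warned).
    """
    rt = np.asarray(rt, float)
    block = np.asarray(block)
    tib = np.asarray(time_in_block, float)
    grand = rt.mean()
    out = rt.copy()
    for b in np.unique(block):
        sel = block == b
        if sel.sum() < 3:
            warnings.warn(f"block {b} has fewer than 3 trials; skipped")
            continue
        x = tib[sel] - tib[sel].mean()
        y = rt[sel]
        slope = (x @ (y - y.mean())) / (x @ x) if (x @ x) > 0 else 0.0
        out[sel] = y - y.mean() - slope * x + grand
    return out


def variance_explained(r: float) -> float:
    """Convert a Pearson correlation into percent of variance (100 r^2)."""
    r = np.asarray(r, float)
    if np.any(np.abs(r) > 1):
        raise ValueError("|r| must be <= 1")
    return 100.0 * r**2


def build_regressors(
    table: pd.DataFrame,
    rt_col: str = "rt",
    v1_amp: np.ndarray | None = None,
    min_cell: int = MIN_CELL,
) -> RegressorSet:
    """Run the full correction cascade on a trial table.

    Expects columns ``rt`` (or ``rt_col``), ``iti``, ``condition``,
    ``prev_condition``, ``block`` and ``time_in_block``.  If ``v1_amp`` is
    given, ``rt_v1corrected`` residualizes the *raw* RT for V1 amplitude
    (the V1 correction is an alternative regressor, not a cascade stage).
    """
    raw = table[rt_col].to_numpy(float)
    var_raw = raw.var()
    after_iti = correct_iti(raw, table["iti"].to_numpy(float))
    after_cond = renormalize_conditions(
        after_iti,
        table["condition"].to_numpy(object),
        table["prev_condition"].to_numpy(object),
        min_cell=min_cell,
    )
    after_block = detrend_blocks(
        after_cond, table["block"].to_numpy(), table["time_in_block"].to_numpy()
    )
    ledger = VarianceLedger(
        fraction_iti=float((var_raw - after_iti.var()) / var_raw),
        fraction_condition=float((after_iti.var() - after_cond.var()) / var_raw),
        fraction_block_trends=float((after_cond.var() - after_block.var()) / var_raw),
        fraction_residual=float(after_block.var() / var_raw),
    )
    rt_v1 = None
    if v1_amp is not None:
        rt_v1 = correct_v1_power(raw, np.asarray(v1_amp, float))
        ledger.fraction_v1 = float((var_raw - rt_v1.var()) / var_raw)
    return RegressorSet(
        raw_rt=raw,
        rt_corrected=after_cond,
        rt_detrended=after_block,
        rt_v1corrected=rt_v1,
        ledger=ledger,
    )
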