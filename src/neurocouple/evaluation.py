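"""Reconstruction-error metrics and band-wise statistical comparison.

The reconstruction error of a predicted fNIRS block against its target is
the per-timepoint sum of absolute per-dimension differences,

    eps_t = sum_l |xhat_{t,l} - x_{t,l}|,   t in T,

with channels folded into the dimension index l; the scalar RE of a block
is the mean of eps_t over T (mean rather than sum so values are
duration-invariant; a ``agg="sum"`` option exists).  Band-wise comparison
collects per-subject mean RE for each EEG band and tests the hypothesis
"gamma reconstructs better" with one-tailed paired t-tests on the four
contrasts [delta, gamma], [theta, gamma], [alpha, gamma], [beta, gamma],
Bonferroni-corrected by the factor 4.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "REResult",
    "BandComparison",
    "reconstruction_error",
    "evaluate_bands",
    "paired_band_tests",
    "CONTRAST_PAIRS",
]

CONTRAST_PAIRS = (
    ("delta", "gamma"),
    ("theta", "gamma"),
    ("alpha", "gamma"),
    ("beta", "gamma"),
)


@dataclass
class REResult:
    """Reconstruction error of one prediction/target block pair."""

    per_timepoint: np.ndarray
    total: float
    band: str = "full"
    channels: str = "all"


@dataclass
class BandComparison:
    """Per-subject x per-band mean RE table plus the paired contrasts."""

    table: pd.DataFrame
    contrasts: list[dict] = field(default_factory=list)


def reconstruction_error(
    pred: np.ndarray,
    target: np.ndarray,
    band: str = "full",
    agg: str = "mean",
) -> REResult:
    """Per-timepoint L1 reconstruction error between two fNIRS blocks.

    ``pred`` and ``target`` must share a shape of the form
    (..., points, channels); all leading axes plus the points axis are
    flattened into the timepoint index t and channels form the dimensions
    l summed inside eps_t.
    """
    pred = np.asarray(pred, dtype=float)
    target = np.asarray(target, dtype=float)
    if pred.shape != target.shape:
        raise ValueError(f"shape mismatch {pred.shape} vs {target.shape}")
    if np.isnan(pred).any() or np.isnan(target).any():
        raise ValueError("NaN in inputs")
    if agg not in ("mean", "sum"):
        raise ValueError("agg must be 'mean' or 'sum'")
    L = pred.shape[-1]
    diff = np.abs(pred.reshape(-1, L) - target.reshape(-1, L))
    eps_t = diff.sum(axis=1)
    total = float(eps_t.mean() if agg == "mean" else eps_t.sum())
    return REResult(per_timepoint=eps_t, total=total, band=band)


def evaluate_bands(
    runs: dict[str, dict[str, tuple[np.ndarray, np.ndarray]]],
    require_all: bool = True,
) -> BandComparison:
    """Assemble the per-subject x per-band mean RE table.

    ``runs`` maps subject id -> band name -> (pred, target).  Every
    subject must provide the five canonical bands (plus optionally
    "full") unless ``require_all`` is disabled.
    """
    from .preprocessing import BAND_NAMES

    rows = {}
    for subject, bands in runs.items():
        missing = set(BAND_NAMES) - set(bands)
        if missing and require_all:
            raise ValueError(
                f"subject {subject!r} missing band(s): {sorted(missing)}"
            )
        rows[subject] = {
            band: reconstruction_error(pred, target, band=band).total
            for band, (pred, target) in bands.items()
        }
    table = pd.DataFrame.from_dict(rows, orient="index").sort_index()
    return BandComparison(table=table)


def paired_band_tests(
    cmp: BandComparison, alpha: float = 0.05
) -> BandComparison:
    """One-tailed paired t-tests of each band's RE against gamma.

    The alternative is "other band reconstructs worse than gamma"
    (mean difference other - gamma > 0).  Raw one-tailed p-values are
    Bonferroni-adjusted by the fixed factor 4 (the size of the contrast
    family); zero-variance difference vectors are flagged degenerate,
    with p = 0.5 at t = 0 and p ~ 0 for a strictly positive mean.
    """
    table = cmp.table
    if len(table) < 2:
        raise ValueError("need at least 2 subjects for paired tests")
    contrasts = []
    for other, gamma in CONTRAST_PAIRS:
        if other not in table.columns or gamma not in table.columns:
            continue
        diff = (table[other] - table[gamma]).to_numpy(dtype=float)
        degenerate = bool(np.allclose(diff.std(ddof=1), 0.0))
        if degenerate:
            if np.allclose(diff.mean(), 0.0):
                t_stat, p = 0.0, 0.5
            else:
                t_stat = np.inf if diff.mean() > 0 else -np.inf
                p = 0.0 if diff.mean() > 0 else 1.0
        else:
            res = stats.ttest_rel(
                table[other], table[gamma], alternative="greater"
            )
            t_stat, p = float(res.statistic), float(res.pvalue)
        p_adj = min(1.0, 4.0 * p)
        contrasts.append(
            {
                "pair": (other, gamma),
                "t": t_stat,
                "p": p,
                "p_bonferroni": p_adj,
                "significant": bool(p_adj < alpha),
                "degenerate": degenerate,
            }
        )
    return BandComparison(table=table, contrasts=contrasts)
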