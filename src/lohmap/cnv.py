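"""Binned read-depth log2-ratio screen for hemizygous chromosome/arm loss.

A deliberately simple tumor/normal depth-ratio caller: per-bin log2 of
library-size-normalized tumor vs normal counts, aggregated by the median per
chromosome (or arm), compared against a loss threshold.  For a tumor of
purity rho with a hemizygous (single-copy) loss, the expected ratio on the
lost region is log2(1 - rho/2); the default threshold of -0.1 therefore
detects losses down to rho ~= 0.134.  No GC or mappability correction is
applied — this screen targets simulated or pre-normalized counts and is a
stand-in for full allele-specific copy-number callers on real data.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional

import numpy as np
import pandas as pd

from .model import ArmMap, DataError

LOSS = "LOSS"
NEUTRAL_OR_GAIN = "NEUTRAL_OR_GAIN"
NO_CALL = "NO_CALL"

DEFAULT_LOSS_THRESHOLD = -0.1
DEFAULT_MIN_BINS = 20


@dataclass(frozen=True)
class ChromCall:
    """Median log2 copy-ratio and loss call for one chromosome or arm."""

    group: str
    n_bins: int
    median_log2: float
    call: str


def bin_log2_ratios(bins: pd.DataFrame, tumor_col: str = "tumor_count",
                    normal_col: str = "normal_count",
                    median_center: bool = True) -> pd.DataFrame:
    """Append per-bin ``log2_ratio`` of library-normalized tumor/normal counts.

    ratio_b = log2((tumor_b / T_total) / (normal_b / N_total)).  Bins with
    zero normal count are masked (NaN).  Normalizing by library size makes
    the result invariant to a global rescaling of either sample's counts;
    with ``median_center`` the genome-wide median ratio is subtracted so a
    mostly diploid genome sits at 0 even when large losses skew the totals.
    """
    t = bins[tumor_col].to_numpy(dtype=float)
    n = bins[normal_col].to_numpy(dtype=float)
    if np.any(t < 0) or np.any(n < 0):
        raise DataError("bin counts must be non-negative")
    t_total, n_total = t.sum(), n.sum()
    if t_total <= 0 or n_total <= 0:
        raise DataError("total tumor and normal bin counts must be positive")
    out = bins.copy()
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.log2((t / t_total) / (n / n_total))
    ratio[(n == 0) | (t == 0)] = np.nan
    if median_center and np.any(~np.isnan(ratio)):
        ratio = ratio - np.nanmedian(ratio)
    out["log2_ratio"] = ratio
    return out


def call_chromosome_loss(
    ratios: pd.DataFrame,
    loss_threshold: float = DEFAULT_LOSS_THRESHOLD,
    min_bins: int = DEFAULT_MIN_BINS,
    arms: Optional[ArmMap] = None,
    by_arm: bool = False,
) -> List[ChromCall]:
    """Median log2 ratio per chromosome (or arm) vs the loss threshold.

    LOSS iff median < loss_threshold (strict).  Groups with fewer than
    ``min_bins`` unmasked bins are reported as NO_CALL.  With ``by_arm``,
    bins are grouped by the arm containing their start position; centromeric
    bins are dropped.
    """
    df = ratios.dropna(subset=["log2_ratio"])
    if by_arm:
        if arms is None:
            raise DataError("by_arm grouping requires an ArmMap")
        labels = [
            f"{c}{arms.arm_of(c, int(s))}" if arms.arm_of(c, int(s)) else None
            for c, s in zip(df["chrom"], df["bin_start"])
        ]
        df = df.assign(_group=labels).dropna(subset=["_group"])
    else:
        df = df.assign(_group=df["chrom"])

    calls = []
    for group, sub in df.groupby("_group", sort=True):
        vals = sub["log2_ratio"].to_numpy()
        if len(vals) < min_bins:
            calls.append(ChromCall(str(group), len(vals), float("nan"), NO_CALL))
            continue
        med = float(np.median(vals))
        calls.append(
            ChromCall(str(group), len(vals), med, LOSS if med < loss_threshold else NEUTRAL_OR_GAIN)
        )
    return calls


def minimum_detectable_purity(loss_threshold: float = DEFAULT_LOSS_THRESHOLD) -> float:
    """Purity at which a hemizygous loss sits exactly on the threshold:
    solves log2(1 - rho/2) = loss_threshold."""
    return 2.0 * (1.0 - 2.0 ** loss_threshold)


def calls_to_frame(calls: List[ChromCall]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "group": [c.group for c in calls],
            "n_bins": [c.n_bins for c in calls],
            "median_log2": [c.median_log2 for c in calls],
            "call": [c.call for c in calls],
        }
    )
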