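"""Germline het SNP calling and per-tumor LOH-informative SNP selection.

The pipeline here is: (a) call germline heterozygous SNPs in the normal
sample by depth and VAF; (b) keep het SNPs whose tumor depth exceeds the
same strict bound; (c) exact two-sided binomial test of the tumor ref/alt
counts against 0.5; (d) Benjamini–Hochberg adjustment across all tested
SNPs of one tumor, keeping q < alpha as LOH-informative; (e) retain the
tumor only if it has enough informative SNPs for the platform mode;
(f) assign the retained allele as the majority allele.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Sequence, Union

import numpy as np
import pandas as pd
from scipy.stats import binom

from .model import (
    ALT,
    REF,
    AllelicDepthRecord,
    ConfigError,
    DataError,
    Thresholds,
    TumorLOHProfile,
)
from .variant_io import records_to_frame

FrameOrRecords = Union[pd.DataFrame, Sequence[AllelicDepthRecord]]


def _as_frame(records: FrameOrRecords, samples: Sequence[str]) -> pd.DataFrame:
    if isinstance(records, pd.DataFrame):
        return records
    return records_to_frame(records, samples)


def binomial_two_sided_p(k_alt: int, n: int) -> float:
    """Exact two-sided binomial p-value against p0 = 0.5.

    p = min(1, 2 * min(P[X <= k], P[X >= k])) for X ~ Bin(n, 1/2); by the
    symmetry of the null this equals the sum of probabilities of all
    outcomes no more likely than ``k_alt``.
    """
    if n < 1 or k_alt < 0 or k_alt > n:
        raise DataError(f"need 0 <= k_alt <= n and n >= 1, got k={k_alt}, n={n}")
    return float(binom_two_sided_p_vec(np.array([k_alt]), np.array([n]))[0])


def binom_two_sided_p_vec(k: np.ndarray, n: np.ndarray) -> np.ndarray:
    """Vectorized form of :func:`binomial_two_sided_p`."""
    k = np.asarray(k, dtype=np.int64)
    n = np.asarray(n, dtype=np.int64)
    lower = binom.cdf(k, n, 0.5)
    upper = binom.sf(k - 1, n, 0.5)
    return np.minimum(1.0, 2.0 * np.minimum(lower, upper))


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values, in the input order.

    After ascending sort, q(i) = min_{j >= i} (m * p(j) / j), capped at 1.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise DataError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum(1.0, np.minimum.accumulate(ranked[::-1])[::-1])
    q = np.empty(m, dtype=float)
    q[order] = q_sorted
    return q


def call_het_snps(
    records: FrameOrRecords, normal_sample: str, thr: Thresholds
) -> pd.DataFrame:
    """Identify germline heterozygous SNPs in the normal sample.

    Keeps sites with normal depth strictly greater than ``thr.min_depth``
    and VAF within the inclusive window [vaf_lo, vaf_hi].  Returns a frame
    sorted by (chrom, pos) that carries all sample count columns through.
    """
    df = _as_frame(records, [normal_sample])
    ref = df[f"{normal_sample}_ref"].to_numpy()
    alt = df[f"{normal_sample}_alt"].to_numpy()
    depth = ref + alt
    with np.errstate(divide="ignore", invalid="ignore"):
        vaf = np.where(depth > 0, alt / np.maximum(depth, 1), np.nan)
    keep = (depth > thr.min_depth) & (vaf >= thr.vaf_lo) & (vaf <= thr.vaf_hi)
    out = df.loc[keep].copy()
    out["normal_vaf"] = vaf[keep]
    return out.sort_values(["chrom", "pos"], kind="mergesort").reset_index(drop=True)


def assign_retained_allele(ref_count: int, alt_count: int) -> str:
    """REF if ref reads outnumber alt reads, else ALT; ties are impossible
    for informative SNPs (p = 1 can never pass the FDR filter) and raise."""
    if ref_count == alt_count:
        raise DataError(
            f"tied read counts ({ref_count}:{alt_count}) cannot belong to an informative SNP"
        )
    return REF if ref_count > alt_count else ALT


@dataclass
class SelectionResult:
    """Informative SNPs of one tumor plus retention and stage tallies."""

    tumor_id: str
    informative: pd.DataFrame
    retained: bool
    counts: Dict[str, int]

    def profile(self) -> TumorLOHProfile:
        alleles = {
            (row.chrom, int(row.pos), row.ref, row.alt): row.retained_allele
            for row in self.informative.itertuples(index=False)
        }
        return TumorLOHProfile(tumor_id=self.tumor_id, alleles=alleles, retained=self.retained)


def select_informative(
    tumor_records: FrameOrRecords,
    tumor_sample: str,
    het_snps: pd.DataFrame,
    thr: Thresholds,
) -> SelectionResult:
    """Steps (b)-(f) for one tumor sample.

    Tests het SNPs with tumor depth > min_depth, BH-adjusts across all
    tested SNPs of this tumor (one FDR family per tumor), keeps
    q < fdr_alpha, and assigns retained alleles.  ``retained`` is true when
    the informative count reaches the mode-specific minimum.
    """
    df = _as_frame(tumor_records, [tumor_sample])
    rcol, acol = f"{tumor_sample}_ref", f"{tumor_sample}_alt"
    if rcol not in df.columns or acol not in df.columns:
        raise ConfigError(f"tumor sample {tumor_sample!r} absent from input")

    het_sites = het_snps[["chrom", "pos", "ref", "alt"]]
    merged = het_sites.merge(df[["chrom", "pos", "ref", "alt", rcol, acol]],
                             on=["chrom", "pos", "ref", "alt"], how="inner")
    ref = merged[rcol].to_numpy(dtype=np.int64)
    alt = merged[acol].to_numpy(dtype=np.int64)
    depth = ref + alt
    tested = merged.loc[depth > thr.min_depth].copy()
    k = tested[acol].to_numpy(dtype=np.int64)
    n = (tested[rcol] + tested[acol]).to_numpy(dtype=np.int64)

    counts = {
        "n_het": int(len(het_snps)),
        "n_depth_pass": int(len(tested)),
        "n_tested": int(len(tested)),
    }
    if len(tested) == 0:
        empty = _empty_informative(tumor_sample)
        counts["n_informative"] = 0
        return SelectionResult(tumor_sample, empty, False, counts)

    p = binom_two_sided_p_vec(k, n)
    q = bh_adjust(p)
    keep = q < thr.fdr_alpha
    inf = tested.loc[keep].copy()
    inf["tumor_id"] = tumor_sample
    inf = inf.rename(columns={rcol: "ref_count", acol: "alt_count"})
    inf["p_value"] = p[keep]
    inf["q_value"] = q[keep]
    inf["retained_allele"] = np.where(inf["ref_count"] > inf["alt_count"], REF, ALT)
    # ties cannot pass q < alpha; guard anyway
    if (inf["ref_count"] == inf["alt_count"]).any():
        raise DataError("internal inconsistency: tied counts passed the FDR filter")
    inf = inf[
        ["chrom", "pos", "ref", "alt", "tumor_id",
         "ref_count", "alt_count", "p_value", "q_value", "retained_allele"]
    ].sort_values(["chrom", "pos"], kind="mergesort").reset_index(drop=True)

    counts["n_informative"] = int(len(inf))
    retained = len(inf) >= thr.min_informative
    return SelectionResult(tumor_sample, inf, retained, counts)


def _empty_informative(tumor_id: str) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "chrom": pd.Series(dtype=str),
            "pos": pd.Series(dtype=np.int64),
            "ref": pd.Series(dtype=str),
            "alt": pd.Series(dtype=str),
            "tumor_id": pd.Series(dtype=str),
            "ref_count": pd.Series(dtype=np.int64),
            "alt_count": pd.Series(dtype=np.int64),
            "p_value": pd.Series(dtype=float),
            "q_value": pd.Series(dtype=float),
            "retained_allele": pd.Series(dtype=str),
        }
    )


def select_informative_all(
    records: FrameOrRecords,
    normal_sample: str,
    tumor_samples: Sequence[str],
    thr: Thresholds,
) -> List[SelectionResult]:
    """Run het calling once and informative selection for every tumor."""
    samples = [normal_sample, *tumor_samples]
    df = _as_frame(records, samples)
    het = call_het_snps(df, normal_sample, thr)
    return [select_informative(df, t, het, thr) for t in tumor_samples]
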