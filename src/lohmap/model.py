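"""Core data model shared by all pipeline stages.

Coordinates are 1-based throughout (VCF convention).  Chromosome arms are
closed intervals: p = [1, p_end], q = [q_start, chrom_end]; positions strictly
between ``p_end`` and ``q_start`` are centromeric and carry no arm label.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Optional, Tuple

SiteKey = Tuple[str, int, str, str]
"""(chrom, pos, ref_base, alt_base) — the identity of one biallelic SNP site."""

REF = "REF"
ALT = "ALT"

#: hg19 centromere bounds per chromosome, derived from the UCSC cytoBand
#: ``acen`` rows: p_end = last 1-based bp of the p arm, q_start = first bp of
#: the q arm.  Only the chromosomes this pipeline is typically run on.
HG19_ARM_BOUNDS: Dict[str, Tuple[int, int]] = {
    "chr18": (15_400_000, 19_000_001),
}

#: hg19 chr18 length in bp (used as the simulator default).
HG19_CHR18_LENGTH = 78_077_248


class ConfigError(ValueError):
    """Bad configuration: missing samples, invalid thresholds, infeasible plans."""


class DataError(ValueError):
    """Malformed or inconsistent input data."""


@dataclass(frozen=True)
class AllelicDepthRecord:
    """One biallelic SNP site with per-sample (ref_count, alt_count) reads."""

    chrom: str
    pos: int
    ref_base: str
    alt_base: str
    depths: Dict[str, Tuple[int, int]]

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise DataError(f"pos must be >= 1, got {self.pos}")
        if self.ref_base == self.alt_base:
            raise DataError(f"ref and alt alleles identical at {self.chrom}:{self.pos}")
        for sample, (r, a) in self.depths.items():
            if r < 0 or a < 0:
                raise DataError(f"negative read count for {sample} at {self.chrom}:{self.pos}")

    @property
    def site(self) -> SiteKey:
        return (self.chrom, self.pos, self.ref_base, self.alt_base)

    def depth(self, sample: str) -> int:
        r, a = self.depths[sample]
        return r + a


@dataclass(frozen=True)
class ArmMap:
    """Per-chromosome arm boundaries: chrom -> (p_end, q_start), 1-based."""

    bounds: Dict[str, Tuple[int, int]]

    def __post_init__(self) -> None:
        for chrom, (p_end, q_start) in self.bounds.items():
            if p_end >= q_start:
                raise DataError(
                    f"{chrom}: p_end ({p_end}) must be < q_start ({q_start})"
                )

    @classmethod
    def hg19_default(cls) -> "ArmMap":
        return cls(dict(HG19_ARM_BOUNDS))

    def arm_of(self, chrom: str, pos: int) -> Optional[str]:
        """Return 'p', 'q', or None (centromeric / unknown chromosome)."""
        if chrom not in self.bounds:
            return None
        p_end, q_start = self.bounds[chrom]
        if pos <= p_end:
            return "p"
        if pos >= q_start:
            return "q"
        return None


@dataclass(frozen=True)
class Thresholds:
    """Filter thresholds for het-SNP calling and informative-SNP selection.

    ``min_depth`` is a strictly-greater-than bound on total read depth; the
    VAF window is inclusive on both ends.  ``mode`` selects the per-tumor
    retention threshold: WGS requires ``min_informative_wgs`` informative
    SNPs, WES requires ``min_informative_wes``.
    """

    min_depth: int = 10
    vaf_lo: float = 0.4
    vaf_hi: float = 0.6
    fdr_alpha: float = 0.1
    min_informative_wgs: int = 1000
    min_informative_wes: int = 100
    mode: str = "WGS"

    def __post_init__(self) -> None:
        if not (0.0 <= self.vaf_lo < self.vaf_hi <= 1.0):
            raise ConfigError(f"need 0 <= vaf_lo < vaf_hi <= 1, got [{self.vaf_lo}, {self.vaf_hi}]")
        if not (0.0 < self.fdr_alpha < 1.0):
            raise ConfigError(f"fdr_alpha must be in (0, 1), got {self.fdr_alpha}")
        if self.min_depth < 0:
            raise ConfigError("min_depth must be >= 0")
        if self.min_informative_wgs < 1 or self.min_informative_wes < 1:
            raise ConfigError("min_informative thresholds must be >= 1")
        if self.mode not in ("WGS", "WES"):
            raise ConfigError(f"mode must be WGS or WES, got {self.mode!r}")

    @property
    def min_informative(self) -> int:
        return self.min_informative_wgs if self.mode == "WGS" else self.min_informative_wes


@dataclass(frozen=True)
class ConcordanceConfig:
    """Thresholds for pairwise retained-allele concordance calls.

    A pair is SAME when overall and both per-arm concordances are >= ``hi``,
    OPPOSITE when all are <= ``lo``, ARM_DISCORDANT when one arm is >= ``hi``
    and the other <= ``lo`` (each arm holding >= ``min_arm_shared`` shared
    SNPs), AMBIGUOUS otherwise.
    """

    hi: float = 0.95
    lo: float = 0.05
    min_shared: int = 30
    min_arm_shared: int = 10

    def __post_init__(self) -> None:
        if not (0.0 <= self.lo < self.hi <= 1.0):
            raise ConfigError(f"need 0 <= lo < hi <= 1, got lo={self.lo}, hi={self.hi}")
        if self.min_shared < 1 or self.min_arm_shared < 1:
            raise ConfigError("minimum shared-SNP counts must be >= 1")


@dataclass
class TumorLOHProfile:
    """Per-tumor map of informative site -> retained allele, plus retention."""

    tumor_id: str
    alleles: Dict[SiteKey, str] = field(default_factory=dict)
    retained: bool = False

    @property
    def sites(self) -> frozenset:
        return frozenset(self.alleles)
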