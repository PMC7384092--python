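"""Synthetic tumor/normal cohorts with planted chromosome-loss patterns.

Generates allelic-depth tables (germline het SNPs with purity-mixed
hemizygous LOH), matching binned read counts for the copy-number screen,
and the planted ground truth, so the whole pipeline is testable without
external data.  Depths are negative-binomial (over-dispersed relative to
Poisson); allele counts are binomial given depth.  Everything is driven by
one ``numpy`` Generator, so a fixed seed gives byte-identical output.

Mixture algebra for a site whose germline alt allele sits on haplotype H,
in a tumor of purity rho with hemizygous loss retaining haplotype R:
total copies c = 2(1-rho) + rho, and the tumor alt-read fraction is
f = 1/(2-rho) if R == H else (1-rho)/(2-rho); outside LOH f = 1/2.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .model import ALT, REF, ArmMap, ConfigError, HG19_CHR18_LENGTH

H1 = "H1"
H2 = "H2"

SAME_ALLELE = "SAME_ALLELE"
OPPOSITE_ALLELES = "OPPOSITE_ALLELES"
ARM_DISCORDANT = "ARM_DISCORDANT"

_BASES = np.array(["A", "C", "G", "T"])

_APPROX_GENOME_BP = 2_880_000_000  # rough autosomal genome span for bin scaling


@dataclass(frozen=True)
class LohSpec:
    """Per-tumor LOH plan: which haplotype each arm retains (None = no LOH)."""

    retained_p: Optional[str] = None
    retained_q: Optional[str] = None

    def __post_init__(self) -> None:
        for v in (self.retained_p, self.retained_q):
            if v not in (None, H1, H2):
                raise ConfigError(f"retained haplotype must be H1/H2/None, got {v!r}")
        if (self.retained_p is None) != (self.retained_q is None):
            # PER_ARM with one arm unspecified is not a pattern the pipeline models
            raise ConfigError("specify retained haplotypes for both arms or neither")

    @property
    def kind(self) -> str:
        if self.retained_p is None:
            return "NONE"
        return "WHOLE" if self.retained_p == self.retained_q else "PER_ARM"

    @classmethod
    def none(cls) -> "LohSpec":
        return cls()

    @classmethod
    def whole(cls, retained: str) -> "LohSpec":
        return cls(retained, retained)

    @classmethod
    def per_arm(cls, p: str, q: str) -> "LohSpec":
        return cls(p, q)

    def retained_for_arm(self, arm: str) -> Optional[str]:
        return self.retained_p if arm == "p" else self.retained_q


@dataclass(frozen=True)
class SimConfig:
    seed: int
    n_tumors: int
    purities: Tuple[float, ...]
    loh_specs: Tuple[LohSpec, ...]
    planted_pattern: str = SAME_ALLELE
    chrom: str = "chr18"
    chrom_length: int = HG19_CHR18_LENGTH
    p_end: int = 15_400_000
    q_start: int = 19_000_001
    n_snps: int = 3000
    normal_mean_depth: float = 30.0
    tumor_mean_depth: float = 60.0
    depth_dispersion: float = 10.0
    mode: str = "WGS"
    wes_thinning: float = 0.1
    error_rate: float = 0.001
    n_bins: int = 500
    n_background_bins: Optional[int] = None  # default: genome-proportional
    bin_mean_reads: float = 1000.0
    bin_dispersion: float = 200.0  # bins pool many reads: mildly over-dispersed

    def __post_init__(self) -> None:
        if self.n_tumors < 1:
            raise ConfigError("need at least one tumor")
        if len(self.purities) != self.n_tumors or len(self.loh_specs) != self.n_tumors:
            raise ConfigError("purities and loh_specs must have one entry per tumor")
        if any(not (0.0 <= r <= 1.0) for r in self.purities):
            raise ConfigError("purity must lie in [0, 1]")
        if self.normal_mean_depth <= 0 or self.tumor_mean_depth <= 0:
            raise ConfigError("mean depths must be positive")
        if not (1 <= self.p_end < self.q_start <= self.chrom_length):
            raise ConfigError("need 1 <= p_end < q_start <= chrom_length")
        if self.mode not in ("WGS", "WES"):
            raise ConfigError(f"mode must be WGS or WES, got {self.mode!r}")

    @property
    def resolved_background_bins(self) -> int:
        """Background (diploid) bins at the same genomic bin density as the
        target chromosome, covering the rest of an ~2.88 Gb genome, so the
        genome-wide median log2 ratio is anchored at copy-neutral."""
        if self.n_background_bins is not None:
            return self.n_background_bins
        rest = _APPROX_GENOME_BP - self.chrom_length
        return max(1, round(self.n_bins * rest / self.chrom_length))

    @property
    def effective_n_snps(self) -> int:
        """WES mode thins SNP density to emulate exome sparsity."""
        if self.mode == "WES":
            return max(1, round(self.n_snps * self.wes_thinning))
        return self.n_snps

    @property
    def tumor_ids(self) -> List[str]:
        return [f"T{i + 1}" for i in range(self.n_tumors)]

    def arm_map(self) -> ArmMap:
        return ArmMap({self.chrom: (self.p_end, self.q_start)})


@dataclass
class SimTruth:
    """Planted ground truth emitted alongside the simulated data."""

    pattern: str
    tumor_ids: List[str]
    purities: List[float]
    loh_specs: List[LohSpec]
    alt_haplotype: List[str] = field(default_factory=list)  # per SNP: H1 or H2
    positions: List[int] = field(default_factory=list)

    def expected_retained_allele(self, tumor_idx: int, snp_idx: int, arm: str) -> Optional[str]:
        """ALT if the alt-bearing haplotype is the one retained, else REF;
        None where the tumor has no LOH."""
        retained = self.loh_specs[tumor_idx].retained_for_arm(arm)
        if retained is None:
            return None
        return ALT if self.alt_haplotype[snp_idx] == retained else REF

    def groups_for_arm(self, arm: str) -> List[List[str]]:
        """Partition of LOH tumors by the haplotype retained on this arm."""
        g = {H1: [], H2: []}
        for tid, spec in zip(self.tumor_ids, self.loh_specs):
            r = spec.retained_for_arm(arm)
            if r is not None:
                g[r].append(tid)
        return [sorted(g[H1]), sorted(g[H2])]

    def to_json(self) -> dict:
        return {
            "pattern": self.pattern,
            "tumor_ids": self.tumor_ids,
            "purities": self.purities,
            "loh_specs": [asdict(s) for s in self.loh_specs],
            "alt_haplotype": self.alt_haplotype,
            "positions": self.positions,
        }


@dataclass
class SimResult:
    depths: pd.DataFrame
    bins: pd.DataFrame
    truth: SimTruth
    config: SimConfig


def _negbin(rng: np.random.Generator, mean: np.ndarray, size_param: float) -> np.ndarray:
    """Negative binomial with given mean and dispersion ('size') parameter."""
    mean = np.asarray(mean, dtype=float)
    p = size_param / (size_param + mean)
    return rng.negative_binomial(size_param, p, size=mean.shape)


def tumor_alt_fraction(purity: float, alt_retained: bool) -> float:
    """Expected tumor alt-read fraction at a het SNP inside a hemizygous LOH
    region: 1/(2-rho) when the alt-bearing haplotype is retained, else
    (1-rho)/(2-rho)."""
    if alt_retained:
        return 1.0 / (2.0 - purity)
    return (1.0 - purity) / (2.0 - purity)


def simulate_patient(cfg: SimConfig) -> SimResult:
    """Simulate one patient: normal + tumors at germline het SNPs, plus bins."""
    rng = np.random.default_rng(cfg.seed)
    n = cfg.effective_n_snps

    # SNP positions uniform over the two arms (centromere gap excluded)
    p_len = cfg.p_end
    q_len = cfg.chrom_length - cfg.q_start + 1
    usable = p_len + q_len
    pool = np.unique(rng.integers(0, usable, size=2 * n + 100))
    while pool.size < n:  # vanishingly rare unless n ~ usable
        pool = np.unique(np.concatenate([pool, rng.integers(0, usable, size=n)]))
    raw = pool[np.sort(rng.choice(pool.size, size=n, replace=False))]
    pos = np.sort(np.where(raw < p_len, raw + 1, raw - p_len + cfg.q_start))
    on_p = pos <= cfg.p_end

    ref_idx = rng.integers(0, 4, size=n)
    alt_idx = (ref_idx + rng.integers(1, 4, size=n)) % 4
    alt_hap = np.where(rng.integers(0, 2, size=n) == 0, H1, H2)

    data: Dict[str, np.ndarray] = {
        "chrom": np.full(n, cfg.chrom),
        "pos": pos,
        "ref": _BASES[ref_idx],
        "alt": _BASES[alt_idx],
    }

    ndepth = _negbin(rng, np.full(n, cfg.normal_mean_depth), cfg.depth_dispersion)
    nalt = rng.binomial(ndepth, 0.5)
    data["normal_ref"] = ndepth - nalt
    data["normal_alt"] = nalt

    e = cfg.error_rate
    for t, (tid, rho, spec) in enumerate(zip(cfg.tumor_ids, cfg.purities, cfg.loh_specs)):
        f = np.full(n, 0.5)
        c = np.full(n, 2.0)
        for arm, mask in (("p", on_p), ("q", ~on_p)):
            retained = spec.retained_for_arm(arm)
            if retained is None:
                continue
            c[mask] = 2.0 * (1.0 - rho) + rho  # hemizygous loss: 1 copy in tumor cells
            alt_kept = alt_hap[mask] == retained
            f[mask] = np.where(
                alt_kept,
                tumor_alt_fraction(rho, True),
                tumor_alt_fraction(rho, False),
            )
        f_obs = f * (1.0 - e) + (1.0 - f) * e
        tdepth = _negbin(rng, cfg.tumor_mean_depth * c / 2.0, cfg.depth_dispersion)
        talt = rng.binomial(tdepth, f_obs)
        data[f"{tid}_ref"] = tdepth - talt
        data[f"{tid}_alt"] = talt

    depths = pd.DataFrame(data)
    bins = _simulate_bins(rng, cfg)
    truth = SimTruth(
        pattern=cfg.planted_pattern,
        tumor_ids=cfg.tumor_ids,
        purities=list(cfg.purities),
        loh_specs=list(cfg.loh_specs),
        alt_haplotype=list(alt_hap),
        positions=[int(x) for x in pos],
    )
    return SimResult(depths=depths, bins=bins, truth=truth, config=cfg)


def _simulate_bins(rng: np.random.Generator, cfg: SimConfig) -> pd.DataFrame:
    """Bin counts on the target chromosome plus a diploid background
    chromosome so library-size normalization has a neutral anchor."""
    width = max(1, cfg.chrom_length // cfg.n_bins)
    starts = np.arange(cfg.n_bins, dtype=np.int64) * width + 1
    ends = np.minimum(starts + width - 1, cfg.chrom_length)
    mids = (starts + ends) // 2
    arm = np.where(mids <= cfg.p_end, "p", np.where(mids >= cfg.q_start, "q", "cen"))
    # centromeric bins are unmappable in practice; drop them up front
    keep = arm != "cen"
    starts, ends, arm = starts[keep], ends[keep], arm[keep]
    n_target = len(starts)

    n_bg = cfg.resolved_background_bins
    bg_width = max(1, (_APPROX_GENOME_BP - cfg.chrom_length) // max(n_bg, 1))
    bg_starts = np.arange(n_bg, dtype=np.int64) * bg_width + 1

    chroms = np.concatenate([np.full(n_target, cfg.chrom), np.full(n_bg, "chrBG")])
    all_starts = np.concatenate([starts, bg_starts])
    all_ends = np.concatenate([ends, bg_starts + bg_width - 1])
    n_total = len(all_starts)

    out: Dict[str, np.ndarray] = {
        "chrom": chroms,
        "bin_start": all_starts,
        "bin_end": all_ends,
        "normal_count": _negbin(rng, np.full(n_total, cfg.bin_mean_reads), cfg.bin_dispersion),
    }
    for tid, rho, spec in zip(cfg.tumor_ids, cfg.purities, cfg.loh_specs):
        c = np.full(n_total, 2.0)
        for a in ("p", "q"):
            if spec.retained_for_arm(a) is not None:
                c[:n_target][arm == a] = 2.0 * (1.0 - rho) + rho
        out[f"{tid}_count"] = _negbin(rng, cfg.bin_mean_reads * c / 2.0, cfg.bin_dispersion)
    return pd.DataFrame(out)


def plant_pattern(
    pattern: str, n_tumors: int, fraction_with_loh: float = 1.0
) -> List[LohSpec]:
    """Assign per-tumor LOH plans realizing a patient-level pattern.

    SAME_ALLELE: every LOH tumor retains H1.  OPPOSITE_ALLELES: LOH tumors
    split between H1 and H2 (at least one each), consistent across arms.
    ARM_DISCORDANT: exactly one tumor retains different haplotypes on p and
    q; the rest are whole-chromosome (split between H1/H2 when possible).
    Tumors beyond ``fraction_with_loh`` get no LOH.
    """
    if pattern not in (SAME_ALLELE, OPPOSITE_ALLELES, ARM_DISCORDANT):
        raise ConfigError(f"unknown pattern {pattern!r}")
    if not (0.0 < fraction_with_loh <= 1.0):
        raise ConfigError("fraction_with_loh must be in (0, 1]")
    n_loh = max(1, round(n_tumors * fraction_with_loh))
    min_needed = {SAME_ALLELE: 1, OPPOSITE_ALLELES: 2, ARM_DISCORDANT: 2}[pattern]
    n_loh = max(n_loh, min_needed)
    if n_loh > n_tumors:
        raise ConfigError(
            f"pattern {pattern} needs >= {min_needed} LOH tumors but only {n_tumors} tumors requested"
        )

    specs: List[LohSpec] = []
    if pattern == SAME_ALLELE:
        specs = [LohSpec.whole(H1)] * n_loh
    elif pattern == OPPOSITE_ALLELES:
        n_h1 = max(1, n_loh - n_loh // 2)
        specs = [LohSpec.whole(H1)] * n_h1 + [LohSpec.whole(H2)] * (n_loh - n_h1)
    else:
        rest = n_loh - 1
        n_h1 = max(1, rest - rest // 2)
        specs = (
            [LohSpec.per_arm(H1, H2)]
            + [LohSpec.whole(H1)] * n_h1
            + [LohSpec.whole(H2)] * (rest - n_h1)
        )
    specs += [LohSpec.none()] * (n_tumors - n_loh)
    return specs


def patient1_topology() -> Dict[str, LohSpec]:
    """The six-LOH-tumor arm-discordant grouping used as a canonical test
    topology: {T5, T8} vs {T6, T7, T9} whole-chromosome, with T2 siding with
    the first group on 18p and the second on 18q."""
    return {
        "T2": LohSpec.per_arm(H1, H2),
        "T5": LohSpec.whole(H1),
        "T8": LohSpec.whole(H1),
        "T6": LohSpec.whole(H2),
        "T7": LohSpec.whole(H2),
        "T9": LohSpec.whole(H2),
    }


def write_vcf(depths: pd.DataFrame, samples: Sequence[str], path: str,
              chrom_lengths: Optional[Dict[str, int]] = None) -> None:
    """Write the allelic-depth table as a minimal VCF v4.2 with FORMAT AD."""
    lines = ["##fileformat=VCFv4.2"]
    chroms = list(dict.fromkeys(depths["chrom"]))
    for c in chroms:
        ln = (chrom_lengths or {}).get(c)
        lines.append(f"##contig=<ID={c}" + (f",length={ln}>" if ln else ">"))
    lines.append(
        '##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths for the ref and alt alleles">'
    )
    lines.append("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(samples))
    with open(path, "w", newline="\n") as fh:
        fh.write("\n".join(lines) + "\n")
        for row in depths.itertuples(index=False):
            d = row._asdict()
            fields = [
                str(d["chrom"]), str(d["pos"]), ".", str(d["ref"]), str(d["alt"]),
                ".", "PASS", ".", "AD",
            ]
            fields += [f"{d[f'{s}_ref']},{d[f'{s}_alt']}" for s in samples]
            fh.write("\t".join(fields) + "\n")


def write_truth_json(truth: SimTruth, path: str) -> None:
    with open(path, "w", newline="\n") as fh:
        json.dump(truth.to_json(), fh, indent=2, sort_keys=True)
        fh.write("\n")


def het_pass_probability(
    mean_depth: float, dispersion: float, min_depth: int = 10,
    vaf_lo: float = 0.4, vaf_hi: float = 0.6, max_depth: int = 500,
) -> float:
    """Analytic P(depth > min_depth and VAF in window) for a germline het
    site under the simulator's depth model, by enumeration over the
    negative-binomial depth distribution."""
    from scipy.stats import binom, nbinom

    p_nb = dispersion / (dispersion + mean_depth)
    total = 0.0
    for d in range(min_depth + 1, max_depth + 1):
        pd_ = nbinom.pmf(d, dispersion, p_nb)
        if pd_ < 1e-15 and d > mean_depth:
            break
        lo = math.ceil(vaf_lo * d)
        hi = math.floor(vaf_hi * d)
        if hi >= lo:
            total += pd_ * (binom.cdf(hi, d, 0.5) - binom.cdf(lo - 1, d, 0.5))
    return total
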