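"""Readers and writers for the formats the pipeline touches.

Input: VCF v4.x with per-sample AD, or a flat TSV dialect with columns
``chrom, pos, ref, alt, <sample>_ref, <sample>_alt``.  Arm boundaries come
from a UCSC-style cytoband file (5 columns, acen rows mark the centromere),
a 3-column ``chrom  p_end  q_start`` table, or the built-in hg19 default.
All output is deterministic, byte-stable TSV/JSON with floats printed to six
significant digits.
"""

from __future__ import annotations

import json
import logging
import os
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import pandas as pd

from .model import AllelicDepthRecord, ArmMap, ConfigError, DataError

logger = logging.getLogger(__name__)

_BASES = {"A", "C", "G", "T"}


@dataclass
class SkipCounts:
    """Accounting of VCF body lines excluded during normalization."""

    multiallelic: int = 0
    indel: int = 0
    missing_ad: int = 0

    @property
    def total(self) -> int:
        return self.multiallelic + self.indel + self.missing_ad

    def as_dict(self) -> Dict[str, int]:
        return {
            "n_skipped_multiallelic": self.multiallelic,
            "n_skipped_indel": self.indel,
            "n_skipped_missing_ad": self.missing_ad,
        }


def _is_snp(ref: str, alts: Sequence[str]) -> bool:
    return (
        len(ref) == 1
        and ref in _BASES
        and all(len(a) == 1 and a in _BASES for a in alts)
    )


def read_allelic_depths(
    path: str, samples: Sequence[str]
) -> Tuple[List[AllelicDepthRecord], SkipCounts]:
    """Read per-sample allelic depths from a VCF into normalized records.

    Only biallelic SNP lines with an AD value for every requested sample are
    kept; everything else is skipped and tallied in the returned
    :class:`SkipCounts`.  Records are sorted by (chrom, pos).
    """
    from cyvcf2 import VCF

    if not os.path.exists(path):
        raise IOError(f"VCF not found: {path}")
    vcf = VCF(path)
    header_samples = list(vcf.samples)
    missing = [s for s in samples if s not in header_samples]
    if missing:
        raise ConfigError(f"samples not in VCF header: {missing} (header has {header_samples})")
    idx = {s: header_samples.index(s) for s in samples}

    records: List[AllelicDepthRecord] = []
    skips = SkipCounts()
    for v in vcf:
        alts = v.ALT or []
        if len(alts) != 1:
            skips.multiallelic += 1
            continue
        if not _is_snp(v.REF, alts):
            skips.indel += 1
            continue
        ad = v.format("AD")
        if ad is None:
            skips.missing_ad += 1
            continue
        depths: Dict[str, Tuple[int, int]] = {}
        ok = True
        for s in samples:
            row = ad[idx[s]]
            if len(row) < 2 or row[0] < 0 or row[1] < 0:  # cyvcf2 encodes '.' as negative
                ok = False
                break
            depths[s] = (int(row[0]), int(row[1]))
        if not ok:
            skips.missing_ad += 1
            continue
        records.append(
            AllelicDepthRecord(
                chrom=v.CHROM, pos=v.POS, ref_base=v.REF, alt_base=alts[0], depths=depths
            )
        )
    vcf.close()
    if skips.total:
        logger.info("read_allelic_depths: skipped %d sites (%s)", skips.total, skips.as_dict())
    records.sort(key=lambda r: (r.chrom, r.pos))
    return records, skips


def read_allelic_depths_tsv(
    path: str, samples: Sequence[str]
) -> Tuple[List[AllelicDepthRecord], SkipCounts]:
    """Read the flat-TSV dialect (chrom, pos, ref, alt, <sample>_ref/_alt)."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    for s in samples:
        for suffix in ("_ref", "_alt"):
            if f"{s}{suffix}" not in df.columns:
                raise ConfigError(f"column {s}{suffix} missing from {path}")
    records = frame_to_records(df, samples)
    return records, SkipCounts()


def records_to_frame(
    records: Sequence[AllelicDepthRecord], samples: Sequence[str]
) -> pd.DataFrame:
    """Columnar view of records: one row per site, two count columns per sample."""
    data: Dict[str, list] = {
        "chrom": [r.chrom for r in records],
        "pos": [r.pos for r in records],
        "ref": [r.ref_base for r in records],
        "alt": [r.alt_base for r in records],
    }
    for s in samples:
        data[f"{s}_ref"] = [r.depths[s][0] for r in records]
        data[f"{s}_alt"] = [r.depths[s][1] for r in records]
    return pd.DataFrame(data)


def frame_to_records(df: pd.DataFrame, samples: Sequence[str]) -> List[AllelicDepthRecord]:
    records = []
    for row in df.itertuples(index=False):
        d = row._asdict()
        depths = {s: (int(d[f"{s}_ref"]), int(d[f"{s}_alt"])) for s in samples}
        records.append(
            AllelicDepthRecord(
                chrom=str(d["chrom"]),
                pos=int(d["pos"]),
                ref_base=str(d["ref"]),
                alt_base=str(d["alt"]),
                depths=depths,
            )
        )
    records.sort(key=lambda r: (r.chrom, r.pos))
    return records


def read_arm_map(path: Optional[str] = None) -> ArmMap:
    """Parse arm boundaries; with no path, return the built-in hg19 default.

    A 5-column file is treated as a UCSC cytoband table (0-based starts); the
    centromere is the union of the ``acen`` bands, so p_end = min acen start
    (as a 1-based last-p-arm bp) and q_start = max acen end + 1.  A 3-column
    file is read as explicit ``chrom  p_end  q_start`` (1-based).
    """
    if path is None:
        return ArmMap.hg19_default()
    if not os.path.exists(path):
        raise IOError(f"arm map not found: {path}")
    rows = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            rows.append(line.split("\t"))
    if not rows:
        raise DataError(f"arm map {path} is empty")
    ncol = len(rows[0])
    bounds: Dict[str, Tuple[int, int]] = {}
    if ncol >= 5:
        acen: Dict[str, List[Tuple[int, int]]] = {}
        for chrom, start, end, _band, stain in (r[:5] for r in rows):
            if stain == "acen":
                acen.setdefault(chrom, []).append((int(start), int(end)))
        if not acen:
            raise DataError(f"no acen bands found in cytoband file {path}")
        for chrom, spans in acen.items():
            p_end = min(s for s, _ in spans)  # 0-based acen start == 1-based last p bp
            q_start = max(e for _, e in spans) + 1
            bounds[chrom] = (p_end, q_start)
    elif ncol == 3:
        for chrom, p_end, q_start in rows:
            bounds[chrom] = (int(p_end), int(q_start))
    else:
        raise DataError(f"arm map {path}: expected 3 or 5 columns, got {ncol}")
    return ArmMap(bounds)


def _fmt(x) -> str:
    if isinstance(x, float):
        return f"{x:.6g}"
    return str(x)


def write_tsv(df: pd.DataFrame, path: str) -> None:
    """Byte-stable TSV: floats at 6 significant digits, '\\n' line endings."""
    with open(path, "w", newline="\n") as fh:
        fh.write("\t".join(df.columns) + "\n")
        for row in df.itertuples(index=False):
            fh.write("\t".join(_fmt(v) for v in row) + "\n")


def write_json(obj, path: str) -> None:
    with open(path, "w", newline="\n") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")


def write_results(
    out_dir: str,
    informative: pd.DataFrame,
    profiles: pd.DataFrame,
    pairs: pd.DataFrame,
    patient: dict,
    summary: dict,
) -> Dict[str, str]:
    """Write the standard output bundle; returns name -> path."""
    os.makedirs(out_dir, exist_ok=True)
    paths = {
        "informative": os.path.join(out_dir, "informative_snps.tsv"),
        "profiles": os.path.join(out_dir, "tumor_profiles.tsv"),
        "pairs": os.path.join(out_dir, "pair_concordance.tsv"),
        "patient": os.path.join(out_dir, "patient_pattern.json"),
        "summary": os.path.join(out_dir, "run_summary.json"),
    }
    write_tsv(informative, paths["informative"])
    write_tsv(profiles, paths["profiles"])
    write_tsv(pairs, paths["pairs"])
    write_json(patient, paths["patient"])
    write_json(summary, paths["summary"])
    return paths
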