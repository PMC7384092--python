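"""Cross-tumor comparison of retained alleles and patient-level pattern calls.

Tumors that kept the same chromosome copy agree at essentially every shared
informative SNP; tumors that kept opposite copies disagree at essentially
every one.  Pairwise concordance therefore separates cleanly, and the
patient-level call reduces to 2-coloring a signed agreement graph per arm.
Parental haplotypes are identified only up to relabeling, so groups are
reported as group-1/group-2.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Dict, FrozenSet, List, Optional, Sequence, Tuple

import math

from .model import ArmMap, ConcordanceConfig, SiteKey, TumorLOHProfile

SAME = "SAME"
OPPOSITE = "OPPOSITE"
ARM_DISCORDANT = "ARM_DISCORDANT"
AMBIGUOUS = "AMBIGUOUS"

SAME_ALLELE = "SAME_ALLELE"
OPPOSITE_ALLELES = "OPPOSITE_ALLELES"
UNDETERMINED = "UNDETERMINED"


@dataclass(frozen=True)
class PairConcordance:
    tumor_i: str
    tumor_j: str
    n_shared: int
    n_shared_p: int
    n_shared_q: int
    concordance_all: float  # NaN when n_shared == 0
    concordance_p: float
    concordance_q: float
    call: str


@dataclass
class PatientPattern:
    patient_id: str
    pattern: str
    groups: Dict[str, List[List[str]]] = field(default_factory=dict)
    pair_calls: List[PairConcordance] = field(default_factory=list)
    n_common_sites: int = 0
    note: str = ""


def common_informative_sites(profiles: Sequence[TumorLOHProfile]) -> FrozenSet[SiteKey]:
    """Intersection of informative-site sets across all given profiles."""
    if not profiles:
        return frozenset()
    sites = profiles[0].sites
    for p in profiles[1:]:
        sites = sites & p.sites
    return sites


def _concordance(
    p_i: TumorLOHProfile, p_j: TumorLOHProfile, sites
) -> Tuple[int, float]:
    n = len(sites)
    if n == 0:
        return 0, math.nan
    agree = sum(1 for s in sites if p_i.alleles[s] == p_j.alleles[s])
    return n, agree / n


def pairwise_concordance(
    p_i: TumorLOHProfile,
    p_j: TumorLOHProfile,
    arms: ArmMap,
    cfg: ConcordanceConfig = ConcordanceConfig(),
) -> PairConcordance:
    """Compare retained alleles of two tumors over their shared informative SNPs."""
    shared = p_i.sites & p_j.sites
    shared_p = {s for s in shared if arms.arm_of(s[0], s[1]) == "p"}
    shared_q = {s for s in shared if arms.arm_of(s[0], s[1]) == "q"}

    n_all, c_all = _concordance(p_i, p_j, shared)
    n_p, c_p = _concordance(p_i, p_j, shared_p)
    n_q, c_q = _concordance(p_i, p_j, shared_q)

    call = AMBIGUOUS
    if n_all >= cfg.min_shared:
        p_ok = n_p >= cfg.min_arm_shared
        q_ok = n_q >= cfg.min_arm_shared
        if p_ok and q_ok and (
            (c_p >= cfg.hi and c_q <= cfg.lo) or (c_p <= cfg.lo and c_q >= cfg.hi)
        ):
            call = ARM_DISCORDANT
        elif (
            c_all >= cfg.hi
            and (not p_ok or c_p >= cfg.hi)
            and (not q_ok or c_q >= cfg.hi)
        ):
            call = SAME
        elif (
            c_all <= cfg.lo
            and (not p_ok or c_p <= cfg.lo)
            and (not q_ok or c_q <= cfg.lo)
        ):
            call = OPPOSITE

    return PairConcordance(
        tumor_i=p_i.tumor_id,
        tumor_j=p_j.tumor_id,
        n_shared=n_all,
        n_shared_p=n_p,
        n_shared_q=n_q,
        concordance_all=c_all,
        concordance_p=c_p,
        concordance_q=c_q,
        call=call,
    )


class _ParityUnionFind:
    """Union-find with edge parity: tracks whether two nodes are in the same
    or opposite group; detects contradictions (non-2-colorable graphs)."""

    def __init__(self, nodes: Sequence[str]):
        self.parent = {n: n for n in nodes}
        self.parity = {n: 0 for n in nodes}  # parity relative to root

    def find(self, x: str) -> Tuple[str, int]:
        path = []
        while self.parent[x] != x:
            path.append(x)
            x = self.parent[x]
        par = 0
        for y in reversed(path):
            par ^= self.parity[y]
            self.parent[y] = x
            self.parity[y] = par
        return x, self.parity[path[0]] if path else 0

    def union(self, a: str, b: str, opposite: bool) -> bool:
        """Merge with the given relation; False on contradiction."""
        ra, pa = self.find(a)
        rb, pb = self.find(b)
        want = (pa ^ pb) if not opposite else (pa ^ pb ^ 1)
        if ra == rb:
            return want == 0 if not opposite else (pa ^ pb) == 1
        self.parent[rb] = ra
        self.parity[rb] = pa ^ pb ^ (1 if opposite else 0)
        return True

    def partition(self, nodes: Sequence[str]) -> List[List[str]]:
        """Two groups, deterministic: each component's lowest-id node goes to
        group 1; cross-component assignment is arbitrary up to relabeling."""
        groups: Dict[Tuple[str, int], List[str]] = {}
        for n in sorted(nodes):
            r, p = self.find(n)
            groups.setdefault((r, p), []).append(n)
        g1: List[str] = []
        g2: List[str] = []
        roots = sorted({r for r, _ in groups})
        for r in roots:
            members0 = groups.get((r, 0), [])
            members1 = groups.get((r, 1), [])
            # orient each component so its lowest id lands in group 1
            lo0 = members0[0] if members0 else None
            lo1 = members1[0] if members1 else None
            if lo1 is not None and (lo0 is None or lo1 < lo0):
                members0, members1 = members1, members0
            g1.extend(members0)
            g2.extend(members1)
        return [sorted(g1), sorted(g2)]


def _arm_sign(pc: PairConcordance, arm: str, cfg: ConcordanceConfig) -> int:
    """+1 same, -1 opposite, 0 indeterminate for one arm of one pair."""
    n = pc.n_shared_p if arm == "p" else pc.n_shared_q
    c = pc.concordance_p if arm == "p" else pc.concordance_q
    if n < cfg.min_arm_shared or math.isnan(c):
        return 0
    if c >= cfg.hi:
        return 1
    if c <= cfg.lo:
        return -1
    return 0


def classify_patient(
    profiles: Sequence[TumorLOHProfile],
    arms: ArmMap,
    cfg: ConcordanceConfig = ConcordanceConfig(),
    patient_id: str = "patient",
) -> PatientPattern:
    """Classify the patient-level pattern of parental-allele loss.

    Builds per-arm signed agreement graphs over the retained tumors, checks
    2-colorability, and calls ARM_DISCORDANT if any pair disagrees between
    arms, OPPOSITE_ALLELES if the tumors split into two consistent groups,
    SAME_ALLELE if they form one group, and UNDETERMINED for degenerate or
    mutually inconsistent inputs.
    """
    retained = [p for p in profiles if p.retained]
    if len(retained) < 2:
        return PatientPattern(
            patient_id=patient_id,
            pattern=UNDETERMINED,
            note=f"only {len(retained)} retained tumor profile(s); need >= 2",
        )
    ids = sorted(p.tumor_id for p in retained)
    by_id = {p.tumor_id: p for p in retained}
    pairs = [
        pairwise_concordance(by_id[a], by_id[b], arms, cfg)
        for a, b in itertools.combinations(ids, 2)
    ]
    n_common = len(common_informative_sites(retained))

    uf = {arm: _ParityUnionFind(ids) for arm in ("p", "q", "all")}
    consistent = True
    any_discordant = False
    any_edge = False
    any_opposite = False
    for pc in pairs:
        if pc.call == ARM_DISCORDANT:
            any_discordant = True
        if pc.call in (SAME, OPPOSITE):
            # a whole-chromosome call constrains both arms and the overall graph
            opp = pc.call == OPPOSITE
            any_edge = True
            any_opposite = any_opposite or opp
            for g in ("p", "q", "all"):
                if not uf[g].union(pc.tumor_i, pc.tumor_j, opposite=opp):
                    consistent = False
        for arm in ("p", "q"):
            sign = _arm_sign(pc, arm, cfg)
            if sign == 0:
                continue
            any_edge = True
            any_opposite = any_opposite or sign == -1
            if not uf[arm].union(pc.tumor_i, pc.tumor_j, opposite=(sign == -1)):
                consistent = False

    if not consistent:
        return PatientPattern(
            patient_id=patient_id,
            pattern=UNDETERMINED,
            pair_calls=pairs,
            n_common_sites=n_common,
            note="pair calls are mutually inconsistent (agreement graph not 2-colorable)",
        )
    if not any_edge:
        return PatientPattern(
            patient_id=patient_id,
            pattern=UNDETERMINED,
            pair_calls=pairs,
            n_common_sites=n_common,
            note="no determinate pair relationships",
        )

    part_p = uf["p"].partition(ids)
    part_q = uf["q"].partition(ids)
    if any_discordant:
        return PatientPattern(
            patient_id=patient_id,
            pattern=ARM_DISCORDANT,
            groups={"p": part_p, "q": part_q},
            pair_calls=pairs,
            n_common_sites=n_common,
        )
    pattern = OPPOSITE_ALLELES if any_opposite else SAME_ALLELE
    return PatientPattern(
        patient_id=patient_id,
        pattern=pattern,
        groups={"all": uf["all"].partition(ids)},
        pair_calls=pairs,
        n_common_sites=n_common,
    )


def pairs_to_rows(pairs: Sequence[PairConcordance]) -> List[dict]:
    """Flatten pair results for TSV output."""
    return [
        {
            "tumor_i": pc.tumor_i,
            "tumor_j": pc.tumor_j,
            "n_shared": pc.n_shared,
            "n_shared_p": pc.n_shared_p,
            "n_shared_q": pc.n_shared_q,
            "concordance_all": pc.concordance_all,
            "concordance_p": pc.concordance_p,
            "concordance_q": pc.concordance_q,
            "call": pc.call,
        }
        for pc in pairs
    ]
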