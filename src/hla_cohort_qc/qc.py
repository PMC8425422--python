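"""Study-wide HLA identity QC.

Confident allele calls are cross-compared between every pair of samples
into a squared identity matrix; samples are grouped by thresholding that
matrix, and declared sample->subject labels can be evaluated against it
(precision/recall/F1 over sample pairs, with an F1-maximising threshold
sweep and mislabel flags).
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from typing import Mapping, Sequence

from .errors import ArgumentError
from .genotyper import SampleTyping

logger = logging.getLogger(__name__)

#: Recommended grouping thresholds (percent identity) by layout.
DEFAULT_GROUP_THRESHOLD = {"paired": 80.0, "single": 70.0}
#: Recommended confidence (p-value) thresholds by layout.
DEFAULT_CONFIDENCE_THRESHOLD = {"paired": 0.05, "single": 0.5}
#: Cohorts with fewer distinct alleles than this are low-diversity.
LOW_DIVERSITY_CUTOFF = 50


@dataclass
class AlleleProfile:
    """Confidently typed allele slots of one sample.

    Each gene carries a multiset of 0-2 four-digit groups; a homozygous
    call contributes its allele twice.
    """

    sample_id: str
    alleles: dict[str, Counter]

    @property
    def n_confident(self) -> int:
        return sum(sum(ms.values()) for ms in self.alleles.values())


@dataclass(frozen=True)
class IdentityCell:
    shared: int
    comparable: int

    @property
    def percent(self) -> float:
        if self.comparable == 0:
            return 0.0
        return 100.0 * self.shared / self.comparable


@dataclass
class IdentityMatrix:
    sample_ids: list[str]
    cells: list[list[IdentityCell]]
    totals: list[int]

    def percent(self, i: int, j: int) -> float:
        return self.cells[i][j].percent


@dataclass
class EvalResult:
    threshold_pct: float
    precision: float
    recall: float
    f1: float
    confusion: tuple[int, int, int, int]  # TP, FP, FN, TN
    mislabel_flags: list[tuple[str, str, str]]  # (sample, declared, best-match subject)
    sweep: list[tuple[float, float, float, float]] = field(default_factory=list)


@dataclass
class DiversityReport:
    distinct_alleles: int
    low_diversity: bool


def filter_alleles(typing: SampleTyping, p_threshold: float = 0.05) -> AlleleProfile:
    """Keep only allele slots whose confidence p-value passes the threshold.

    A slot is kept iff p < p_threshold; a homozygous call contributes two
    identical slots iff p1 passes.
    """
    if not 0 < p_threshold <= 1:
        raise ArgumentError(f"p_threshold must be in (0, 1], got {p_threshold}")
    alleles: dict[str, Counter] = {}
    for gene, call in typing.calls.items():
        ms: Counter = Counter()
        if call.zygosity == "hom" and call.p1 is not None and call.p1 < p_threshold:
            ms[call.allele1] = 2
        elif call.zygosity == "het":
            if call.p1 is not None and call.p1 < p_threshold:
                ms[call.allele1] += 1
            if call.p2 is not None and call.p2 < p_threshold:
                ms[call.allele2] += 1
        alleles[gene] = ms
    return AlleleProfile(typing.sample_id, alleles)


def pairwise_identity(a: AlleleProfile, b: AlleleProfile) -> IdentityCell:
    """Shared and comparable allele slots between two profiles.

    Only genes with at least one confident slot in BOTH profiles count:
    shared is the multiset intersection, comparable the smaller slot count
    per gene, so shared <= comparable and a locus failing the confidence
    filter in one sample does not penalise the pair.
    """
    shared = 0
    comparable = 0
    for gene, ms_a in a.alleles.items():
        ms_b = b.alleles.get(gene)
        if not ms_a or not ms_b:
            continue
        shared += sum((ms_a & ms_b).values())
        comparable += min(sum(ms_a.values()), sum(ms_b.values()))
    return IdentityCell(shared, comparable)


def build_matrix(profiles: Sequence[AlleleProfile]) -> IdentityMatrix:
    """All-vs-all identity matrix (symmetric; diagonal 100% when typed)."""
    if not profiles:
        raise ArgumentError("no profiles to compare")
    n = len(profiles)
    cells = [[IdentityCell(0, 0)] * n for _ in range(n)]
    for i in range(n):
        for j in range(i, n):
            cell = pairwise_identity(profiles[i], profiles[j])
            cells[i][j] = cell
            cells[j][i] = cell
    for p in profiles:
        if p.n_confident == 0:
            logger.warning("%s: no confident alleles; matrix row is all-zero",
                           p.sample_id)
    return IdentityMatrix([p.sample_id for p in profiles], cells,
                          [p.n_confident for p in profiles])


def group_samples(matrix: IdentityMatrix, threshold_pct: float = 80.0) -> list[list[str]]:
    """Single-linkage clusters: connected components of the graph with an
    edge wherever pairwise identity >= threshold_pct."""
    if not 0 <= threshold_pct <= 101:
        raise ArgumentError(f"threshold_pct out of range: {threshold_pct}")
    n = len(matrix.sample_ids)
    parent = list(range(n))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for i in range(n):
        for j in range(i + 1, n):
            if matrix.percent(i, j) >= threshold_pct:
                parent[find(i)] = find(j)
    comps: dict[int, list[str]] = {}
    for i, sid in enumerate(matrix.sample_ids):
        comps.setdefault(find(i), []).append(sid)
    return sorted((sorted(c) for c in comps.values()), key=lambda c: c[0])


def _confusion_at(matrix: IdentityMatrix, same: list[list[bool]], t: float):
    n = len(matrix.sample_ids)
    tp = fp = fn = tn = 0
    for i in range(n):
        for j in range(i + 1, n):
            pred = matrix.percent(i, j) >= t
            if same[i][j]:
                tp, fn = (tp + 1, fn) if pred else (tp, fn + 1)
            else:
                fp, tn = (fp + 1, tn) if pred else (fp, tn + 1)
    return tp, fp, fn, tn


def _prf(tp: int, fp: int, fn: int) -> tuple[float, float, float]:
    precision = tp / (tp + fp) if tp + fp else 0.0
    recall = tp / (tp + fn) if tp + fn else 0.0
    f1 = (2 * precision * recall / (precision + recall)
          if precision + recall else 0.0)
    return precision, recall, f1


def evaluate_labels(matrix: IdentityMatrix, truth: Mapping[str, str]) -> EvalResult:
    """Evaluate declared sample->subject labels against the identity matrix.

    Each unordered sample pair is predicted same-source iff its identity
    is >= t; t sweeps all observed percent values plus 0 and 100, and the
    F1-maximising threshold is reported (ties -> largest t).  A sample is
    flagged as a potential mislabel when its highest-identity partner at
    the chosen threshold belongs to a different declared subject.
    """
    missing = [s for s in matrix.sample_ids if s not in truth]
    if missing:
        raise ArgumentError(f"samples missing from label table: {missing}")
    n = len(matrix.sample_ids)
    same = [[truth[a] == truth[b] for b in matrix.sample_ids]
            for a in matrix.sample_ids]
    thresholds = {0.0, 100.0}
    for i in range(n):
        for j in range(i + 1, n):
            thresholds.add(round(matrix.percent(i, j), 10))
    sweep = []
    best = None
    for t in sorted(thresholds):
        tp, fp, fn, tn = _confusion_at(matrix, same, t)
        precision, recall, f1 = _prf(tp, fp, fn)
        sweep.append((t, precision, recall, f1))
        if best is None or f1 >= best[3]:  # ties -> largest t (ascending sweep)
            best = (t, precision, recall, f1, (tp, fp, fn, tn))
    t_best, precision, recall, f1, confusion = best
    flags: list[tuple[str, str, str]] = []
    for i, sid in enumerate(matrix.sample_ids):
        partners = [(matrix.percent(i, j), matrix.sample_ids[j])
                    for j in range(n) if j != i]
        if not partners:
            continue
        pct, partner = min(partners, key=lambda x: (-x[0], x[1]))  # tie -> smallest id
        if pct >= t_best and truth[partner] != truth[sid]:
            flags.append((sid, truth[sid], truth[partner]))
    return EvalResult(t_best, precision, recall, f1, confusion, flags, sweep)


def check_diversity(profiles: Sequence[AlleleProfile]) -> DiversityReport:
    """Count distinct four-digit alleles across all confident slots.

    Fewer than 50 distinct alleles marks the cohort as low-diversity, where
    identity-based sample allocation is unreliable.
    """
    distinct: set[str] = set()
    for p in profiles:
        for ms in p.alleles.values():
            distinct.update(ms)
    return DiversityReport(len(distinct), len(distinct) < LOW_DIVERSITY_CUTOFF)
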