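"""Per-sample four-digit HLA genotyping.

Reads are aligned end-to-end (full read length, ungapped, both strands,
at most ``max_mismatches`` substitutions) against every reference allele.
Hits are collapsed to four-digit groups and counted per gene; up to two
alleles per gene are called in two passes, with a z-score outlier p-value
as the confidence statistic and an RPKM expression estimate.

The aligner uses a pigeonhole seed index: a read with at most *m*
mismatches must match one of its *m+1* disjoint seeds exactly, so only
seed-anchored candidate placements are verified (by vectorised Hamming
count).  This is exactly equivalent to a brute-force scan of every window
on both strands.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
from scipy.stats import norm

from .errors import FormatError
from .reference import AlleleReference
from .samples import SampleSpec, stream_reads

logger = logging.getLogger(__name__)

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")
_VALID_BASES = frozenset("ACGTN")


def revcomp(seq: str) -> str:
    """Reverse complement of a nucleotide string (N self-complements)."""
    return seq.translate(_COMPLEMENT)[::-1]


class InvalidReadError(FormatError):
    """Read contains characters outside ACGTN."""


@dataclass
class TypingParams:
    """Tunables for per-sample typing."""

    max_mismatches: int = 2
    hom_ratio: float = 0.05  # second allele needs >= hom_ratio * c1 pass-2 support


class ReadAligner:
    """End-to-end ungapped read aligner over an allele reference."""

    def __init__(self, ref: AlleleReference, max_mismatches: int = 2):
        if max_mismatches < 0:
            raise ValueError("max_mismatches must be >= 0")
        self.ref = ref
        self.max_mismatches = max_mismatches
        self._names = [r.allele_name for r in ref.records]
        self._groups = [r.group4 for r in ref.records]
        self._seqs = [r.sequence for r in ref.records]
        self._arrs = [np.frombuffer(r.sequence.encode(), dtype=np.uint8)
                      for r in ref.records]
        self._indexes: dict[int, dict[str, list[tuple[int, int]]]] = {}

    def _index_for(self, k: int) -> dict[str, list[tuple[int, int]]]:
        idx = self._indexes.get(k)
        if idx is None:
            idx = {}
            for ai, seq in enumerate(self._seqs):
                for pos in range(len(seq) - k + 1):
                    idx.setdefault(seq[pos:pos + k], []).append((ai, pos))
            self._indexes[k] = idx
        return idx

    def _align_ids(self, read: str) -> set[int]:
        """Indices of alleles containing the read (or its RC) end-to-end."""
        if not _VALID_BASES.issuperset(read):
            raise InvalidReadError("read contains non-ACGTN characters")
        m = self.max_mismatches
        L = len(read)
        if L == 0:
            return set()
        k = max(1, L // (m + 1))
        n_seeds = min(m + 1, L)  # k=1 when the read is shorter than m+1
        index = self._index_for(k)
        arrs = self._arrs
        hits: set[int] = set()
        for strand_read in (read, revcomp(read)):
            rarr = np.frombuffer(strand_read.encode(), dtype=np.uint8)
            seen: set[tuple[int, int]] = set()
            for i in range(n_seeds):
                seed = strand_read[i * k:(i + 1) * k]
                for ai, pos in index.get(seed, ()):
                    if ai in hits:
                        continue
                    start = pos - i * k
                    if start < 0:
                        continue
                    ref_arr = arrs[ai]
                    if start + L > ref_arr.shape[0]:
                        continue
                    key = (ai, start)
                    if key in seen:
                        continue
                    seen.add(key)
                    if np.count_nonzero(ref_arr[start:start + L] != rarr) <= m:
                        hits.add(ai)
        return hits

    def align(self, read: str) -> set[str]:
        """Allele names hit by *read* on either strand."""
        return {self._names[i] for i in self._align_ids(read)}

    def align_groups(self, read: str) -> frozenset[str]:
        """Four-digit groups hit by *read* on either strand."""
        return frozenset(self._groups[i] for i in self._align_ids(read))


def align_read(read: str, ref: AlleleReference, max_mismatches: int = 2) -> set[str]:
    """One-shot convenience wrapper around :class:`ReadAligner`.

    Prefer constructing a ReadAligner when aligning many reads: the seed
    index is built once per (reference, seed length).
    """
    return ReadAligner(ref, max_mismatches).align(read)


@dataclass
class GroupCounts:
    """Read (or read-pair) counts per four-digit group for one gene.

    ``counts`` covers every reference group of the gene, zeros included.
    """

    gene: str
    counts: dict[str, int]
    total_sample_reads: int


@dataclass
class GeneEvidence:
    """Per-gene histogram of the group-sets hit by each read unit.

    Keyed by the frozenset of four-digit groups of this gene that a read
    (single-end) or a concordant pair (paired-end) hit; retaining the sets
    rather than marginal counts makes the second calling pass (re-counting
    after removal of reads hitting the first allele's group) exact.
    """

    gene: str
    groupset_counts: Counter = field(default_factory=Counter)

    def marginal(self, ref: AlleleReference, exclude: str | None = None) -> dict[str, int]:
        counts = {g: 0 for g in ref.groups_by_gene.get(self.gene, ())}
        for gs, c in self.groupset_counts.items():
            if exclude is not None and exclude in gs:
                continue
            for g in gs:
                counts[g] += c
        return counts


@dataclass
class SampleEvidence:
    evidence: dict[str, GeneEvidence]
    total_units: int  # reads (single-end) or pairs (paired-end) processed
    skipped_reads: int


@dataclass
class LocusCall:
    """Genotype call for one gene in one sample."""

    gene: str
    allele1: str | None
    p1: float | None
    allele2: str | None
    p2: float | None
    zygosity: str  # "het" | "hom" | "nocall"
    supporting_counts: tuple[int, int]
    rpkm: float


@dataclass
class SampleTyping:
    sample_id: str
    layout: str
    total_reads: int
    calls: dict[str, LocusCall]


def collect_evidence(
    spec: SampleSpec,
    ref: AlleleReference,
    aligner: ReadAligner | None = None,
    max_mismatches: int = 2,
) -> SampleEvidence:
    """Stream a sample and accumulate per-gene group-set evidence.

    Single-end: a read supports every group containing >=1 hit allele.
    Paired-end: a pair supports a group only if BOTH mates hit it.
    """
    if aligner is None:
        aligner = ReadAligner(ref, max_mismatches)
    gene_of = {g: gene for gene, groups in ref.groups_by_gene.items() for g in groups}
    evidence = {gene: GeneEvidence(gene) for gene in ref.genes}
    total = 0
    skipped = 0
    for unit in stream_reads(spec):
        total += 1
        try:
            if spec.layout == "single":
                groups = aligner.align_groups(unit[1])
            else:
                (_, seq1), (_, seq2) = unit
                g1 = aligner.align_groups(seq1)
                groups = (g1 & aligner.align_groups(seq2)) if g1 else frozenset()
        except InvalidReadError:
            skipped += 1
            continue
        if not groups:
            continue
        per_gene: dict[str, set[str]] = {}
        for g in groups:
            per_gene.setdefault(gene_of[g], set()).add(g)
        for gene, gs in per_gene.items():
            evidence[gene].groupset_counts[frozenset(gs)] += 1
    if skipped:
        logger.warning("%s: skipped %d reads with non-ACGTN characters",
                       spec.sample_id, skipped)
    return SampleEvidence(evidence, total, skipped)


def count_group_hits(
    spec: SampleSpec, ref: AlleleReference, max_mismatches: int = 2
) -> dict[str, GroupCounts]:
    """Per-gene four-digit group counts for one sample (pass-1 view)."""
    sev = collect_evidence(spec, ref, max_mismatches=max_mismatches)
    return {
        gene: GroupCounts(gene, ev.marginal(ref), sev.total_units)
        for gene, ev in sev.evidence.items()
    }


def outlier_pvalue(counts: GroupCounts | Mapping[str, int], candidate: str) -> float:
    """Confidence p-value for *candidate* being a read-count outlier.

    z = (c - mean) / sd over the counts of all OTHER groups of the gene
    (zero-count reference groups included; population sd); p = 1 - Phi(z).
    A gene with a single reference group has no competitors: p = 0.
    """
    mapping = counts.counts if isinstance(counts, GroupCounts) else counts
    if candidate not in mapping:
        raise KeyError(f"candidate {candidate} not in counts")
    others = np.array([c for g, c in mapping.items() if g != candidate], dtype=float)
    if others.size == 0:
        return 0.0
    c = float(mapping[candidate])
    mu = float(others.mean())
    sigma = float(others.std(ddof=0))
    if sigma == 0.0:
        return 0.0 if c > mu else 1.0
    return float(norm.sf((c - mu) / sigma))


def _argmax_group(counts: Mapping[str, int]) -> tuple[str | None, int]:
    """Highest-count group; ties broken to the lexicographically smallest."""
    best: str | None = None
    best_c = 0
    for g in sorted(counts):
        c = counts[g]
        if c > best_c:
            best, best_c = g, c
    return best, best_c


def compute_expression(
    call: LocusCall,
    counts: GroupCounts | Mapping[str, int],
    total_reads: int,
    ref: AlleleReference,
) -> float:
    """RPKM = 1e9 * c_locus / (L * total_reads).

    c_locus = pass-1 reads supporting the called group(s); L = mean cDNA
    length of the called group(s)' reference alleles.  nocall -> 0.
    """
    if call.zygosity == "nocall" or total_reads <= 0:
        return 0.0
    mapping = counts.counts if isinstance(counts, GroupCounts) else counts
    groups = [call.allele1]
    if call.zygosity == "het" and call.allele2 is not None:
        groups.append(call.allele2)
    c_locus = sum(mapping.get(g, 0) for g in groups)
    lengths = [len(r.sequence) for g in groups for r in ref.records_for_group(g)]
    if not lengths or c_locus == 0:
        return 0.0
    L = float(np.mean(lengths))
    return 1e9 * c_locus / (L * total_reads)


def call_locus_from_evidence(
    ev: GeneEvidence,
    ref: AlleleReference,
    total_units: int,
    params: TypingParams | None = None,
) -> LocusCall:
    """Two-pass allele calling for one gene.

    Pass 1: top group by count with its outlier p-value.  Pass 2: drop
    every read unit that hit any allele of the pass-1 group, re-count, and
    take the new top group.  Homozygous if the pass-2 support falls below
    ``hom_ratio`` of the pass-1 count (or nothing remains).
    """
    params = params or TypingParams()
    counts1 = ev.marginal(ref)
    g1, c1 = _argmax_group(counts1)
    if g1 is None or c1 == 0:
        return LocusCall(ev.gene, None, None, None, None, "nocall", (0, 0), 0.0)
    ties = [g for g, c in counts1.items() if c == c1]
    if len(ties) > 1:
        logger.warning("%s: pass-1 tie between %s; taking %s",
                       ev.gene, sorted(ties), g1)
    p1 = outlier_pvalue(counts1, g1)
    counts2 = ev.marginal(ref, exclude=g1)
    g2, c2 = _argmax_group(counts2)
    if g2 is None or c2 == 0 or c2 < params.hom_ratio * c1:
        call = LocusCall(ev.gene, g1, p1, None, None, "hom", (c1, c2), 0.0)
    else:
        p2 = outlier_pvalue(counts2, g2)
        call = LocusCall(ev.gene, g1, p1, g2, p2, "het", (c1, c2), 0.0)
    call.rpkm = compute_expression(call, counts1, total_units, ref)
    return call


def call_locus(
    spec: SampleSpec,
    ref: AlleleReference,
    gene: str,
    max_mismatches: int = 2,
    params: TypingParams | None = None,
) -> LocusCall:
    """Convenience: collect evidence for *spec* and call a single gene."""
    sev = collect_evidence(spec, ref, max_mismatches=max_mismatches)
    return call_locus_from_evidence(sev.evidence[gene], ref, sev.total_units, params)


def type_sample(
    spec: SampleSpec,
    ref: AlleleReference,
    params: TypingParams | None = None,
    aligner: ReadAligner | None = None,
) -> SampleTyping:
    """Type one sample: one LocusCall per gene in the reference selection."""
    params = params or TypingParams()
    sev = collect_evidence(spec, ref, aligner=aligner,
                           max_mismatches=params.max_mismatches)
    calls = {
        gene: call_locus_from_evidence(sev.evidence[gene], ref, sev.total_units, params)
        for gene in ref.genes
    }
    return SampleTyping(spec.sample_id, spec.layout, sev.total_units, calls)
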