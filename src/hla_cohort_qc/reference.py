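"""HLA allele reference: FASTA parsing, four-digit reduction, gene selection.

The reference is a FASTA file of cDNA allele sequences whose headers carry
standard HLA nomenclature tokens (``A*01:01:01:01``).  Alleles are collapsed
to four-digit groups (``A*01:01``) at load time; four-digit groups are the
unit of typing and of all downstream comparisons.
"""

from __future__ import annotations

import gzip
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

from Bio import SeqIO

from .errors import ArgumentError, FormatError, InputError

logger = logging.getLogger(__name__)

#: The six supported HLA genes, in canonical report order.
SUPPORTED_GENES: tuple[str, ...] = ("A", "B", "C", "DPB1", "DQB1", "DRB1")

#: Gene dropped in the default five-gene selection (lowest expression).
DEFAULT_EXCLUDED_GENE = "DQB1"

# Nomenclature: GENE*dd:dd[:dd[:dd]][expression suffix letter]
_ALLELE_RE = re.compile(
    r"^(?:HLA-)?(?P<gene>[A-Z][A-Z0-9]*)\*(?P<f1>\d+):(?P<f2>\d+)(?::\d+)*[A-Z]?$"
)

_VALID_SEQ_RE = re.compile(r"^[ACGTN]+$")


@dataclass(frozen=True)
class AlleleRecord:
    """A single reference allele at full nomenclature resolution."""

    gene: str
    allele_name: str
    group4: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.sequence:
            raise FormatError(f"allele {self.allele_name}: empty sequence")
        if self.gene not in SUPPORTED_GENES:
            raise FormatError(f"allele {self.allele_name}: unsupported gene {self.gene}")


@dataclass
class AlleleReference:
    """Catalogue of allele records grouped to four-digit resolution per gene."""

    records: list[AlleleRecord]
    genes: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        names = [r.allele_name for r in self.records]
        if len(names) != len(set(names)):
            raise FormatError("duplicate allele names in reference")
        present = {r.gene for r in self.records}
        if not self.genes:
            self.genes = [g for g in SUPPORTED_GENES if g in present]
        self.groups_by_gene: dict[str, set[str]] = {g: set() for g in self.genes}
        for rec in self.records:
            self.groups_by_gene[rec.gene].add(rec.group4)

    def __len__(self) -> int:
        return len(self.records)

    def records_for_gene(self, gene: str) -> list[AlleleRecord]:
        return [r for r in self.records if r.gene == gene]

    def records_for_group(self, group4: str) -> list[AlleleRecord]:
        return [r for r in self.records if r.group4 == group4]


def parse_allele_name(token: str) -> tuple[str, str] | None:
    """Return ``(gene, group4)`` if *token* is an HLA allele name, else None."""
    m = _ALLELE_RE.match(token)
    if m is None:
        return None
    gene = m.group("gene")
    return gene, f"{gene}*{m.group('f1')}:{m.group('f2')}"


def reduce_to_group(allele_name: str) -> str:
    """Reduce a full nomenclature string to its four-digit group.

    ``A*01:01:01:01`` -> ``A*01:01``.  Idempotent.

    Raises
    ------
    FormatError
        If *allele_name* does not match ``GENE*ff(:ff)+``.
    """
    parsed = parse_allele_name(allele_name)
    if parsed is None:
        raise FormatError(f"malformed allele name: {allele_name!r}")
    return parsed[1]


def _open_maybe_gzip(path: Path):
    with open(path, "rb") as probe:
        magic = probe.read(2)
    if magic == b"\x1f\x8b":
        return gzip.open(path, "rt")
    return open(path, "rt")


def _header_allele(description: str) -> tuple[str, str, str] | None:
    """Scan whitespace-separated header tokens for an allele name.

    Accepts both bare headers (``>A*01:01:01:01``) and IMGT-style headers
    (``>HLA:HLA00001 A*01:01:01:01 1098 bp``); the first matching token wins.
    Returns ``(gene, allele_name, group4)`` or None.
    """
    for token in description.split():
        parsed = parse_allele_name(token)
        if parsed is not None:
            gene, group4 = parsed
            name = token[4:] if token.startswith("HLA-") else token
            return gene, name, group4
    return None


def parse_allele_fasta(path: str | Path) -> AlleleReference:
    """Parse an HLA allele reference FASTA (plain or gzip-compressed).

    Records whose gene is outside the supported six are dropped with a
    logged count.  Sequences are uppercased; characters outside ``ACGTN``
    are a fatal format error.

    Raises
    ------
    InputError
        If *path* is missing or unreadable.
    FormatError
        If no parsable allele headers are found, or a sequence is invalid.
    """
    path = Path(path)
    if not path.is_file():
        raise InputError(f"reference FASTA not found: {path}")
    records: list[AlleleRecord] = []
    seen: set[str] = set()
    n_dropped = 0
    try:
        with _open_maybe_gzip(path) as handle:
            for rec in SeqIO.parse(handle, "fasta"):
                parsed = _header_allele(rec.description)
                if parsed is None:
                    n_dropped += 1
                    continue
                gene, allele_name, group4 = parsed
                if gene not in SUPPORTED_GENES:
                    n_dropped += 1
                    continue
                if allele_name in seen:
                    raise FormatError(f"duplicate allele {allele_name} in {path}")
                seq = str(rec.seq).upper()
                if not seq:
                    raise FormatError(f"allele {allele_name}: empty sequence")
                if not _VALID_SEQ_RE.match(seq):
                    raise FormatError(
                        f"allele {allele_name}: sequence contains non-ACGTN characters"
                    )
                seen.add(allele_name)
                records.append(AlleleRecord(gene, allele_name, group4, seq))
    except OSError as exc:
        raise InputError(f"cannot read reference FASTA {path}: {exc}") from exc
    if n_dropped:
        logger.warning("%s: dropped %d records (unsupported gene or no allele token)",
                       path.name, n_dropped)
    if not records:
        raise FormatError(f"no parsable HLA allele headers in {path}")
    return AlleleReference(records)


def select_genes(
    ref: AlleleReference,
    gene_count: int = 5,
    custom: Sequence[str] | None = None,
) -> AlleleReference:
    """Subset the reference to the requested gene panel.

    ``gene_count=5`` drops DQB1 (the default panel); ``gene_count=6`` keeps
    all six genes; a *custom* list overrides gene_count entirely.
    """
    if custom is not None:
        wanted = list(dict.fromkeys(custom))
        if not wanted:
            raise ArgumentError("custom gene list is empty")
        bad = [g for g in wanted if g not in SUPPORTED_GENES]
        if bad:
            raise ArgumentError(
                f"unsupported gene(s) {bad}; supported: {list(SUPPORTED_GENES)}"
            )
    elif gene_count == 6:
        wanted = list(SUPPORTED_GENES)
    elif gene_count == 5:
        wanted = [g for g in SUPPORTED_GENES if g != DEFAULT_EXCLUDED_GENE]
    else:
        raise ArgumentError(f"gene_count must be 5 or 6, got {gene_count!r}")
    keep = set(wanted)
    genes = [g for g in SUPPORTED_GENES if g in keep and g in ref.genes]
    return AlleleReference([r for r in ref.records if r.gene in keep], genes=genes)
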