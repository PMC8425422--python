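"""Population-frequency-driven synthetic RNA-seq cohort simulator.

Generates FASTQ cohorts (single- or paired-end) from per-gene allele
frequency tables under Hardy-Weinberg sampling, with a wgsim-like internal
read simulator (uniform start positions, i.i.d. substitution errors,
constant quality), and writes a ground-truth table so that typing and QC
can be validated end to end without any external data.
"""

from __future__ import annotations

import gzip
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import ArgumentError, FormatError, InputError
from .genotyper import revcomp
from .reference import (
    SUPPORTED_GENES,
    AlleleRecord,
    AlleleReference,
    reduce_to_group,
)

logger = logging.getLogger(__name__)

#: Frequency assigned to reference alleles absent from a population table.
FILL_IN_FREQUENCY = 1e-3

#: Relative per-gene read share (DQB1 lowest, matching its low expression).
DEFAULT_EXPRESSION_WEIGHTS = {
    "A": 1.0, "B": 1.0, "C": 0.8, "DRB1": 0.6, "DPB1": 0.3, "DQB1": 0.15,
}

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_BASE_INDEX = np.zeros(256, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _BASE_INDEX[_b] = _i


@dataclass
class FrequencyTable:
    """Per-gene map of four-digit group -> population frequency (sums to 1)."""

    freqs: dict[str, dict[str, float]]

    @property
    def genes(self) -> list[str]:
        return [g for g in SUPPORTED_GENES if g in self.freqs]

    def validate(self, tol: float = 1e-9) -> None:
        for gene, fmap in self.freqs.items():
            if not fmap:
                raise FormatError(f"{gene}: empty frequency map")
            total = sum(fmap.values())
            if abs(total - 1.0) > tol:
                raise FormatError(f"{gene}: frequencies sum to {total}, not 1")


@dataclass
class Genotype:
    """Diploid genotype: per gene, two (group4, full allele name) copies."""

    copies: dict[str, tuple[tuple[str, str], tuple[str, str]]]

    def groups(self, gene: str) -> tuple[str, str]:
        (g1, _), (g2, _) = self.copies[gene]
        return g1, g2


@dataclass
class TruthRow:
    sample_id: str
    individual_id: str
    layout: str
    read_length: int
    reads_generated: int


@dataclass
class TruthTable:
    rows: list[TruthRow]
    genotypes: dict[str, Genotype]

    def subject_of(self) -> dict[str, str]:
        return {r.sample_id: r.individual_id for r in self.rows}

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(r.sample_id, r.individual_id, r.layout, r.read_length,
              r.reads_generated) for r in self.rows],
            columns=["sample_id", "individual_id", "layout", "read_length",
                     "reads_generated"],
        )

    def write(self, path: Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    def write_genotypes(self, path: Path) -> None:
        rows = []
        for ind in sorted(self.genotypes):
            gt = self.genotypes[ind]
            for gene in sorted(gt.copies):
                for copy_idx, (group, allele) in enumerate(gt.copies[gene], 1):
                    rows.append((ind, gene, copy_idx, group, allele))
        pd.DataFrame(rows, columns=["individual_id", "gene", "copy", "group4",
                                    "allele_name"]).to_csv(path, sep="\t",
                                                           index=False)


@dataclass
class SimParams:
    """Cohort simulation parameters.

    Samples per individual are drawn uniformly from
    ``[samples_min, samples_max]`` (default 1..X-1); total HLA reads per
    sample uniformly from ``[reads_min, reads_max]``.
    """

    n_individuals: int = 10
    samples_min: int = 1
    samples_max: int | None = None  # defaults to n_individuals - 1
    layout: str = "paired"
    read_length: int = 75
    reads_min: int = 50_000
    reads_max: int = 100_000
    error_rate: float = 0.01
    fragment_mean: float = 200.0
    fragment_sd: float = 20.0
    expression_weights: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_EXPRESSION_WEIGHTS))
    gzip_output: bool = False

    def __post_init__(self) -> None:
        x = self.n_individuals
        if x < 2:
            raise ArgumentError("n_individuals must be >= 2")
        smax = self.samples_max if self.samples_max is not None else x - 1
        if not 0 < self.samples_min <= smax < x:
            raise ArgumentError(
                f"samples per individual must satisfy 0 < n < {x}")
        if self.layout not in ("single", "paired"):
            raise ArgumentError(f"bad layout {self.layout!r}")
        if self.read_length not in (75, 100):
            logger.warning("non-standard read length %d (typical: 75 or 100)",
                           self.read_length)
        if self.read_length <= 0:
            raise ArgumentError("read_length must be positive")
        if not 0 <= self.error_rate <= 0.2:
            raise ArgumentError("error_rate must be in [0, 0.2]")
        if not 0 < self.reads_min <= self.reads_max:
            raise ArgumentError("need 0 < reads_min <= reads_max")
        if any(w <= 0 for w in self.expression_weights.values()):
            raise ArgumentError("expression weights must be positive")


def load_frequency_table(path: str | Path) -> FrequencyTable:
    """Load a TSV with columns gene, allele, frequency.

    Allele names are reduced to four-digit groups.  Per-gene sums must be
    within 0.01 of 1 and are then renormalised to sum exactly 1.
    """
    path = Path(path)
    if not path.is_file():
        raise InputError(f"frequency table not found: {path}")
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"gene", "allele", "frequency"}
    if not required.issubset(df.columns):
        raise FormatError(f"{path}: need columns {sorted(required)}")
    freqs: dict[str, dict[str, float]] = {}
    for _, row in df.iterrows():
        gene = row["gene"].strip()
        if gene not in SUPPORTED_GENES:
            raise FormatError(f"{path}: unknown gene {gene!r}")
        group = reduce_to_group(row["allele"].strip())
        f = float(row["frequency"])
        if f <= 0:
            raise FormatError(f"{path}: non-positive frequency for {group}")
        gmap = freqs.setdefault(gene, {})
        if group in gmap:
            raise FormatError(f"{path}: duplicate allele {group}")
        gmap[group] = f
    for gene, gmap in freqs.items():
        total = sum(gmap.values())
        if abs(total - 1.0) > 0.01:
            raise FormatError(
                f"{path}: {gene} frequencies sum to {total:.4f} (off by > 0.01)")
        for g in gmap:
            gmap[g] /= total
    table = FrequencyTable(freqs)
    table.validate()
    return table


def adjust_frequencies(table: FrequencyTable, ref: AlleleReference) -> FrequencyTable:
    """Fill in reference groups missing from the population table.

    Every reference four-digit group absent from the table gains frequency
    0.001; the gene's frequencies are then renormalised to sum exactly 1.
    """
    unknown = [g for g in table.genes if g not in ref.groups_by_gene]
    if unknown:
        raise ArgumentError(f"table genes not in reference: {unknown}")
    out: dict[str, dict[str, float]] = {}
    for gene in table.genes:
        gmap = dict(table.freqs[gene])
        for group in ref.groups_by_gene[gene]:
            if group not in gmap:
                gmap[group] = FILL_IN_FREQUENCY
        total = sum(gmap.values())
        out[gene] = {g: f / total for g, f in gmap.items()}
    adjusted = FrequencyTable(out)
    adjusted.validate()
    return adjusted


def sample_genotype(
    table: FrequencyTable, ref: AlleleReference, rng: np.random.Generator
) -> Genotype:
    """Draw a diploid genotype: two independent categorical draws per gene
    (Hardy-Weinberg, no linkage), then a concrete full-resolution allele
    uniformly within each drawn group."""
    copies: dict[str, tuple[tuple[str, str], tuple[str, str]]] = {}
    for gene in table.genes:
        groups = sorted(table.freqs[gene])
        probs = np.array([table.freqs[gene][g] for g in groups])
        probs = probs / probs.sum()
        picked = []
        for _ in range(2):
            group = groups[int(rng.choice(len(groups), p=probs))]
            alleles = sorted(r.allele_name for r in ref.records_for_group(group))
            if not alleles:
                raise ArgumentError(f"group {group} has no reference allele")
            name = alleles[int(rng.integers(len(alleles)))]
            picked.append((group, name))
        copies[gene] = (picked[0], picked[1])
    return Genotype(copies)


def _apply_errors(seq: str, rate: float, rng: np.random.Generator) -> str:
    if rate <= 0:
        return seq
    arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
    hit = np.nonzero(rng.random(arr.shape[0]) < rate)[0]
    if hit.size:
        idx = _BASE_INDEX[arr[hit]]
        shift = rng.integers(1, 4, size=hit.size)
        arr[hit] = _BASES[(idx + shift) % 4]
    return arr.tobytes().decode()


def _open_out(path: Path, gz: bool):
    if gz:
        # fixed mtime/filename so identical seeds give identical bytes
        return gzip.GzipFile(path, "wb", mtime=0)
    return open(path, "wb")


def simulate_sample(
    genotype: Genotype,
    ref: AlleleReference,
    params: SimParams,
    rng: np.random.Generator,
    out_dir: str | Path,
    sample_id: str,
    n_reads: int,
) -> tuple[list[Path], int]:
    """Write FASTQ file(s) for one sample; returns (paths, reads generated).

    Each read unit picks a gene proportionally to expression weights, one
    of the two allele copies uniformly, and a uniform start; substitution
    errors are applied i.i.d. at ``error_rate``.  Paired-end emits mate 2
    as the reverse complement of the other end of a normal-length fragment.
    Returns the number of reads written (pairs count as 2).
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    seq_of = {r.allele_name: r.sequence for r in ref.records}
    genes = [g for g in sorted(genotype.copies) if g in params.expression_weights]
    if not genes:
        raise ArgumentError("no overlap between genotype genes and weights")
    w = np.array([params.expression_weights[g] for g in genes], dtype=float)
    w = w / w.sum()
    L = params.read_length
    paired = params.layout == "paired"
    n_units = n_reads // 2 if paired else n_reads
    gene_idx = rng.choice(len(genes), size=n_units, p=w)
    copy_idx = rng.integers(0, 2, size=n_units)
    ext = ".fastq.gz" if params.gzip_output else ".fastq"
    qual = "I" * L
    shrunk = False

    if paired:
        paths = [out_dir / f"{sample_id}_R1{ext}", out_dir / f"{sample_id}_R2{ext}"]
    else:
        paths = [out_dir / f"{sample_id}{ext}"]
    handles = [_open_out(p, params.gzip_output) for p in paths]
    try:
        for u in range(n_units):
            gene = genes[gene_idx[u]]
            _, allele = genotype.copies[gene][copy_idx[u]]
            seq = seq_of[allele]
            if len(seq) < L:
                raise ArgumentError(
                    f"allele {allele} shorter than read length {L}")
            if paired:
                frag = int(round(rng.normal(params.fragment_mean,
                                            params.fragment_sd)))
                if frag > len(seq):
                    frag = len(seq)
                    shrunk = True
                frag = max(frag, L)
                start = int(rng.integers(0, len(seq) - frag + 1))
                r1 = _apply_errors(seq[start:start + L], params.error_rate, rng)
                r2 = _apply_errors(revcomp(seq[start + frag - L:start + frag]),
                                  params.error_rate, rng)
                rid = f"{sample_id}:{u}"
                handles[0].write(f"@{rid}/1\n{r1}\n+\n{qual}\n".encode())
                handles[1].write(f"@{rid}/2\n{r2}\n+\n{qual}\n".encode())
            else:
                start = int(rng.integers(0, len(seq) - L + 1))
                read = seq[start:start + L]
                if rng.integers(0, 2):
                    read = revcomp(read)
                read = _apply_errors(read, params.error_rate, rng)
                handles[0].write(f"@{sample_id}:{u}\n{read}\n+\n{qual}\n".encode())
    finally:
        for h in handles:
            h.close()
    if shrunk:
        logger.warning("%s: fragment length shrunk to allele length for some reads",
                       sample_id)
    return paths, n_units * 2 if paired else n_units


def simulate_cohort(
    params: SimParams,
    freq_table: FrequencyTable,
    ref: AlleleReference,
    seed: int | np.random.Generator,
    out_dir: str | Path,
) -> TruthTable:
    """Simulate a full cohort into *out_dir* and write its ground truth.

    X genotypes are drawn from the (fill-in adjusted) frequency table; each
    individual receives a uniform number of samples, each with a uniform
    total HLA read count.  Byte-identical output for identical seeds.
    Writes ``truth.tsv`` and ``genotypes.tsv`` alongside the FASTQ files.
    """
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    table = adjust_frequencies(freq_table, ref)
    smax = params.samples_max if params.samples_max is not None \
        else params.n_individuals - 1
    genotypes: dict[str, Genotype] = {}
    rows: list[TruthRow] = []
    counter = 0
    for i in range(params.n_individuals):
        ind = f"I{i + 1:02d}"
        genotypes[ind] = sample_genotype(table, ref, rng)
        n_samples = int(rng.integers(params.samples_min, smax + 1))
        for _ in range(n_samples):
            counter += 1
            sid = f"S{counter:03d}"
            n_reads = int(rng.integers(params.reads_min, params.reads_max + 1))
            _, generated = simulate_sample(genotypes[ind], ref, params, rng,
                                           out_dir, sid, n_reads)
            rows.append(TruthRow(sid, ind, params.layout, params.read_length,
                                 generated))
    truth = TruthTable(rows, genotypes)
    truth.write(out_dir / "truth.tsv")
    truth.write_genotypes(out_dir / "genotypes.tsv")
    return truth


def synthetic_reference(
    rng: np.random.Generator,
    genes: Sequence[str] = SUPPORTED_GENES,
    groups_per_gene: int = 100,
    seq_len: int = 400,
    alleles_per_group: int = 1,
) -> AlleleReference:
    """Random synthetic allele reference with pairwise-distinct groups.

    Group sequences are independent uniform nucleotide strings (so any two
    groups differ at ~75% of positions); extra alleles within a group are
    near-copies with a few substitutions, mimicking sub-four-digit variation.
    """
    records: list[AlleleRecord] = []
    for gene in genes:
        for gi in range(1, groups_per_gene + 1):
            group = f"{gene}*{gi:02d}:01"
            base = _BASES[rng.integers(0, 4, size=seq_len)]
            for ai in range(1, alleles_per_group + 1):
                arr = base.copy()
                if ai > 1:  # a few silent-style substitutions per extra allele
                    pos = rng.choice(seq_len, size=min(2, seq_len), replace=False)
                    idx = _BASE_INDEX[arr[pos]]
                    arr[pos] = _BASES[(idx + rng.integers(1, 4, size=pos.size)) % 4]
                name = group if alleles_per_group == 1 else f"{group}:{ai:02d}"
                records.append(AlleleRecord(gene, name, group,
                                            arr.tobytes().decode()))
    return AlleleReference(records, genes=list(genes))


def synthetic_frequency_table(
    ref: AlleleReference,
    rng: np.random.Generator | None = None,
    concentration: float | None = None,
) -> FrequencyTable:
    """Frequency table covering every reference group.

    Uniform per-gene frequencies by default; with *concentration* (and an
    rng) frequencies are Dirichlet-distributed for skewed populations.
    """
    freqs: dict[str, dict[str, float]] = {}
    for gene in ref.genes:
        groups = sorted(ref.groups_by_gene[gene])
        if concentration is not None:
            if rng is None:
                raise ArgumentError("Dirichlet frequencies need an rng")
            p = rng.dirichlet(np.full(len(groups), concentration))
        else:
            p = np.full(len(groups), 1.0 / len(groups))
        p = p / p.sum()
        freqs[gene] = {g: float(f) for g, f in zip(groups, p)}
    table = FrequencyTable(freqs)
    table.validate()
    return table


def write_reference_fasta(ref: AlleleReference, path: str | Path) -> None:
    """Write a reference as FASTA (for CLI round-trips and fixtures)."""
    path = Path(path)
    with open(path, "w") as fh:
        for rec in ref.records:
            fh.write(f">{rec.allele_name}\n{rec.sequence}\n")


def write_frequency_table(table: FrequencyTable, path: str | Path) -> None:
    rows = [(gene, group, f)
            for gene in table.genes
            for group, f in sorted(table.freqs[gene].items())]
    pd.DataFrame(rows, columns=["gene", "allele", "frequency"]).to_csv(
        Path(path), sep="\t", index=False)
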