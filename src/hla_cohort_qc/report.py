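"""TSV report writers (and readers for round-trip checks).

All percentages are printed with one decimal and p-values in scientific
notation with three significant digits, so report diffs are bit-exact.
Files are written atomically (write-then-rename).
"""

from __future__ import annotations

import os
from pathlib import Path
from typing import Iterable, Sequence

from .errors import InputError
from .genotyper import LocusCall, SampleTyping
from .qc import EvalResult, IdentityMatrix

GENOTYPE_COLUMNS = ("gene", "allele1", "p1", "allele2", "p2", "zygosity", "rpkm")


def fmt_percent(x: float) -> str:
    return f"{x:.1f}"


def fmt_pvalue(p: float | None) -> str:
    return "NA" if p is None else f"{p:.2e}"


def _atomic_write(path: Path, lines: Iterable[str]) -> None:
    tmp = path.with_name(path.name + ".tmp")
    with open(tmp, "w") as fh:
        for line in lines:
            fh.write(line)
            fh.write("\n")
    os.replace(tmp, path)


def write_genotype_tsv(typing: SampleTyping, path: str | Path) -> None:
    """Per-sample genotype report: one row per gene."""
    lines = ["\t".join(GENOTYPE_COLUMNS)]
    for gene in typing.calls:
        c = typing.calls[gene]
        lines.append("\t".join([
            gene,
            c.allele1 or "NA",
            fmt_pvalue(c.p1),
            c.allele2 or "NA",
            fmt_pvalue(c.p2),
            c.zygosity,
            f"{c.rpkm:.3f}",
        ]))
    _atomic_write(Path(path), lines)


def read_genotype_tsv(path: str | Path, sample_id: str | None = None) -> SampleTyping:
    """Re-parse a genotype report (supporting counts are not round-tripped)."""
    path = Path(path)
    if not path.is_file():
        raise InputError(f"genotype report not found: {path}")
    calls: dict[str, LocusCall] = {}
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if tuple(header) != GENOTYPE_COLUMNS:
            raise InputError(f"{path}: unexpected header {header}")
        for line in fh:
            gene, a1, p1, a2, p2, zyg, rpkm = line.rstrip("\n").split("\t")
            calls[gene] = LocusCall(
                gene,
                None if a1 == "NA" else a1,
                None if p1 == "NA" else float(p1),
                None if a2 == "NA" else a2,
                None if p2 == "NA" else float(p2),
                zyg,
                (0, 0),
                float(rpkm),
            )
    sid = sample_id if sample_id is not None else path.name.removesuffix(".genotype.tsv")
    return SampleTyping(sid, "single", 0, calls)


def write_reports(
    typings: Sequence[SampleTyping],
    matrix: IdentityMatrix,
    groups: Sequence[Sequence[str]],
    eval_result: EvalResult | None,
    outdir: str | Path,
    log_lines: Sequence[str] = (),
) -> list[Path]:
    """Write the full report set; returns the list of files written.

    Per sample: ``<id>.genotype.tsv``.  Cohort-wide: identity_percent.tsv,
    identity_counts.tsv, alleles_total.tsv, groups.tsv, identity_long.tsv,
    optionally eval.tsv, plus run.log.
    """
    outdir = Path(outdir)
    try:
        outdir.mkdir(parents=True, exist_ok=True)
    except OSError as exc:
        raise InputError(f"cannot create output folder {outdir}: {exc}") from exc
    written: list[Path] = []

    for typing in typings:
        p = outdir / f"{typing.sample_id}.genotype.tsv"
        write_genotype_tsv(typing, p)
        written.append(p)

    ids = matrix.sample_ids
    n = len(ids)
    header = "sample\t" + "\t".join(ids)

    lines = [header]
    for i in range(n):
        lines.append(ids[i] + "\t" + "\t".join(
            fmt_percent(matrix.percent(i, j)) for j in range(n)))
    p = outdir / "identity_percent.tsv"
    _atomic_write(p, lines)
    written.append(p)

    lines = [header]
    for i in range(n):
        lines.append(ids[i] + "\t" + "\t".join(
            f"{matrix.cells[i][j].shared}/{matrix.cells[i][j].comparable}"
            for j in range(n)))
    p = outdir / "identity_counts.tsv"
    _atomic_write(p, lines)
    written.append(p)

    lines = ["sample\tconfident_alleles"]
    lines += [f"{sid}\t{tot}" for sid, tot in zip(ids, matrix.totals)]
    p = outdir / "alleles_total.tsv"
    _atomic_write(p, lines)
    written.append(p)

    lines = ["group\tsample"]
    for gi, members in enumerate(groups, 1):
        lines += [f"G{gi:03d}\t{sid}" for sid in members]
    p = outdir / "groups.tsv"
    _atomic_write(p, lines)
    written.append(p)

    # long format, plot-ready: N^2 rows
    lines = ["sample_i\tsample_j\tpercent"]
    for i in range(n):
        for j in range(n):
            lines.append(f"{ids[i]}\t{ids[j]}\t{fmt_percent(matrix.percent(i, j))}")
    p = outdir / "identity_long.tsv"
    _atomic_write(p, lines)
    written.append(p)

    if eval_result is not None:
        lines = ["threshold\tprecision\trecall\tf1\tchosen"]
        for t, prec, rec, f1 in eval_result.sweep:
            chosen = 1 if t == eval_result.threshold_pct else 0
            lines.append(f"{fmt_percent(t)}\t{prec:.4f}\t{rec:.4f}\t{f1:.4f}\t{chosen}")
        for sid, declared, best in eval_result.mislabel_flags:
            lines.append(f"# mislabel\t{sid}\tdeclared={declared}\tbest_match={best}")
        p = outdir / "eval.tsv"
        _atomic_write(p, lines)
        written.append(p)

    p = outdir / "run.log"
    _atomic_write(p, list(log_lines))
    written.append(p)
    return written
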