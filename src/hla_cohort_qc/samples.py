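"""FASTQ sample discovery and read streaming.

A cohort lives in one folder of ``.fastq``/``.fq`` files (optionally gzip
compressed).  Mate files are paired by a shared filename stem plus a mate
token (``_R1``/``_R2``, ``_1``/``_2`` or ``.1``/``.2``); everything else is
treated as single-end.  Compression is detected from magic bytes, not the
extension.
"""

from __future__ import annotations

import gzip
import logging
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterator

from .errors import FormatError, InputError

logger = logging.getLogger(__name__)

_FASTQ_EXT_RE = re.compile(r"\.(fastq|fq)(\.gz)?$", re.IGNORECASE)
# mate token at the end of the stem: _R1 / _R2, _1 / _2, .1 / .2
_MATE_RE = re.compile(r"^(?P<stem>.+?)(?:[._]R?(?P<mate>[12]))$")


@dataclass(frozen=True)
class SampleSpec:
    """One sample: id, layout and its 1 (single) or 2 (paired) FASTQ files."""

    sample_id: str
    layout: str  # "single" | "paired"
    files: tuple[Path, ...]
    read_length: int = 0

    def __post_init__(self) -> None:
        if self.layout not in ("single", "paired"):
            raise ValueError(f"bad layout {self.layout!r}")
        if len(self.files) != (2 if self.layout == "paired" else 1):
            raise ValueError(f"{self.sample_id}: layout/file-count mismatch")


def _strip_ext(name: str) -> str | None:
    m = _FASTQ_EXT_RE.search(name)
    return name[: m.start()] if m else None


def _open_fastq(path: Path):
    with open(path, "rb") as probe:
        magic = probe.read(2)
    if magic == b"\x1f\x8b":
        return gzip.open(path, "rt")
    return open(path, "rt")


def _probe_read_length(path: Path) -> int:
    try:
        with _open_fastq(path) as fh:
            fh.readline()
            seq = fh.readline().strip()
            return len(seq)
    except OSError as exc:
        raise InputError(f"cannot read {path}: {exc}") from exc


def discover_samples(folder: str | Path) -> list[SampleSpec]:
    """Discover samples in *folder*, auto-detecting single- vs paired-end.

    Returns SampleSpecs in deterministic lexicographic order of sample id.
    A mate token without its partner is demoted to single-end with a warning.

    Raises
    ------
    InputError
        If the folder does not exist or contains no FASTQ files.
    """
    folder = Path(folder)
    if not folder.is_dir():
        raise InputError(f"input folder not found: {folder}")
    fastqs = sorted(p for p in folder.iterdir()
                    if p.is_file() and _FASTQ_EXT_RE.search(p.name))
    if not fastqs:
        raise InputError(f"no samples found: no .fastq/.fq files in {folder}")

    mates: dict[str, dict[str, Path]] = {}
    singles: list[tuple[str, Path]] = []
    for path in fastqs:
        base = _strip_ext(path.name)
        m = _MATE_RE.match(base) if base else None
        if m:
            mates.setdefault(m.group("stem"), {})[m.group("mate")] = path
        else:
            singles.append((base, path))

    specs: list[SampleSpec] = []
    for stem, pair in mates.items():
        if "1" in pair and "2" in pair:
            specs.append(SampleSpec(stem, "paired", (pair["1"], pair["2"]),
                                    _probe_read_length(pair["1"])))
        else:
            (mate, path), = pair.items()
            logger.warning("%s: mate %s present without partner; treating as single-end",
                           path.name, mate)
            base = _strip_ext(path.name)
            specs.append(SampleSpec(base, "single", (path,), _probe_read_length(path)))
    for stem, path in singles:
        specs.append(SampleSpec(stem, "single", (path,), _probe_read_length(path)))

    specs.sort(key=lambda s: s.sample_id)
    ids = [s.sample_id for s in specs]
    if len(ids) != len(set(ids)):
        dup = sorted({i for i in ids if ids.count(i) > 1})
        raise InputError(f"duplicate sample ids after pairing: {dup}")
    return specs


def _fastq_records(path: Path) -> Iterator[tuple[str, str]]:
    """Yield ``(read_id, sequence)`` from a 4-line-record FASTQ file."""
    with _open_fastq(path) as fh:
        idx = 0
        while True:
            header = fh.readline()
            if not header:
                return
            seq = fh.readline()
            plus = fh.readline()
            qual = fh.readline()
            idx += 1
            if not qual:
                raise FormatError(f"{path}: truncated FASTQ record #{idx}")
            if not header.startswith("@") or not plus.startswith("+"):
                raise FormatError(f"{path}: malformed FASTQ record #{idx}")
            yield header[1:].strip().split()[0], seq.strip().upper()


def stream_reads(spec: SampleSpec):
    """Stream reads from a sample.

    Single-end: yields ``(id, seq)``.  Paired-end: yields
    ``((id1, seq1), (id2, seq2))`` with the two mate files consumed in
    lockstep; unequal record counts are a fatal format error.
    """
    if spec.layout == "single":
        yield from _fastq_records(spec.files[0])
        return
    it1 = _fastq_records(spec.files[0])
    it2 = _fastq_records(spec.files[1])
    sentinel = object()
    while True:
        r1 = next(it1, sentinel)
        r2 = next(it2, sentinel)
        if r1 is sentinel and r2 is sentinel:
            return
        if r1 is sentinel or r2 is sentinel:
            raise FormatError(
                f"{spec.sample_id}: mate files have unequal record counts"
            )
        yield r1, r2
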