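"""Readers and writers for FASTA, BED, bedGraph, and expression tables.

All formats use 0-based half-open coordinates. Readers validate and reject
malformed records instead of silently repairing them; every writer produces
files its matching reader parses back to equal values. Generated files may
carry ``# seed=N`` provenance comments, which all readers skip.
"""

from __future__ import annotations

import hashlib
import logging
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .core import CoverageTrack, GenomicInterval

logger = logging.getLogger(__name__)

_AMBIGUOUS = set("RYSWKMBDHVN")


class FormatError(ValueError):
    """A file violates its format contract."""


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read a FASTA file into a contig -> upper-case sequence mapping.

    Ambiguous IUPAC letters are preserved but logged; duplicate contig
    names, empty files, and content before the first header are rejected.
    """
    path = Path(path)
    with open(path) as handle:
        first = handle.readline()
        while first.startswith((";", "#")):
            first = handle.readline()
        if not first.startswith(">"):
            raise FormatError(f"{path}: not a FASTA file (no '>' header)")
    sequences: dict[str, str] = {}
    for record in SeqIO.parse(path, "fasta"):
        if record.id in sequences:
            raise FormatError(f"{path}: duplicate contig name {record.id!r}")
        seq = str(record.seq).upper()
        ambiguous = set(seq) & _AMBIGUOUS
        if ambiguous:
            logger.warning(
                "%s: contig %s contains ambiguous IUPAC letters %s",
                path,
                record.id,
                "".join(sorted(ambiguous)),
            )
        sequences[record.id] = seq
    if not sequences:
        raise FormatError(f"{path}: empty FASTA file")
    return sequences


def write_fasta(
    sequences: Mapping[str, str], path: str | Path, seed: int | None = None
) -> None:
    """Write sequences as 60-column-wrapped FASTA; seed goes in descriptions."""
    desc = f"seed={seed}" if seed is not None else ""
    records = [
        SeqRecord(Seq(seq), id=name, description=desc)
        for name, seq in sequences.items()
    ]
    SeqIO.write(records, str(path), "fasta")


def _read_table(path: Path, n_min_cols: int, what: str) -> list[list[str]]:
    rows = []
    with open(path) as handle:
        for lineno, line in enumerate(handle, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < n_min_cols:
                raise FormatError(
                    f"{path}:{lineno}: expected >= {n_min_cols} columns in {what}"
                )
            rows.append(parts)
    return rows


def read_bed(path: str | Path) -> list[GenomicInterval]:
    """Read BED3/BED6 intervals, preserving start/end bit-exactly."""
    path = Path(path)
    intervals = []
    for parts in _read_table(path, 3, "BED"):
        try:
            start, end = int(parts[1]), int(parts[2])
        except ValueError as exc:
            raise FormatError(f"{path}: non-integer BED coordinate") from exc
        if start >= end or start < 0:
            raise FormatError(
                f"{path}: invalid interval {parts[0]}:{start}-{end}"
            )
        name = parts[3] if len(parts) > 3 and parts[3] != "." else None
        strand = parts[5] if len(parts) > 5 and parts[5] != "." else None
        intervals.append(GenomicInterval(parts[0], start, end, name, strand))
    return intervals


def write_bed(
    intervals: Iterable[GenomicInterval], path: str | Path, seed: int | None = None
) -> None:
    with open(path, "w") as handle:
        if seed is not None:
            handle.write(f"# seed={seed}\n")
        for iv in intervals:
            fields = [iv.contig, str(iv.start), str(iv.end)]
            if iv.name is not None or iv.strand is not None:
                fields += [iv.name or ".", "0", iv.strand or "."]
            handle.write("\t".join(fields) + "\n")


def read_bedgraph(path: str | Path, bin_size: int) -> CoverageTrack:
    """Read a 4-column bedGraph into fixed-width bins.

    Source intervals are rebinned by length-weighted averaging (positions
    not covered by any interval count as zero); overlapping intervals and
    negative values are rejected.
    """
    path = Path(path)
    if bin_size <= 0:
        raise ValueError("bin_size must be positive")
    raw: dict[str, list[tuple[int, int, float]]] = {}
    for parts in _read_table(path, 4, "bedGraph"):
        try:
            start, end, value = int(parts[1]), int(parts[2]), float(parts[3])
        except ValueError as exc:
            raise FormatError(f"{path}: malformed bedGraph record {parts}") from exc
        if start >= end or start < 0:
            raise FormatError(f"{path}: invalid interval {parts[0]}:{start}-{end}")
        if value < 0:
            raise FormatError(f"{path}: negative value {value} at {parts[0]}:{start}")
        raw.setdefault(parts[0], []).append((start, end, value))

    data = {}
    for contig, ivs in raw.items():
        ivs.sort()
        for (s0, e0, _), (s1, _, _) in zip(ivs, ivs[1:]):
            if s1 < e0:
                raise FormatError(
                    f"{path}: overlapping intervals on {contig} at {s1} < {e0}"
                )
        length = ivs[-1][1]
        n_bins = -(-length // bin_size)
        acc = np.zeros(n_bins)
        for s, e, v in ivs:
            first, last = s // bin_size, (e - 1) // bin_size
            for b in range(first, last + 1):
                lo, hi = max(s, b * bin_size), min(e, (b + 1) * bin_size)
                acc[b] += v * (hi - lo)
        data[contig] = acc / bin_size
    return CoverageTrack(data, bin_size=bin_size)


def write_bedgraph(
    track: CoverageTrack, path: str | Path, seed: int | None = None
) -> None:
    """Write one bedGraph line per bin (zero bins included)."""
    with open(path, "w") as handle:
        if seed is not None:
            handle.write(f"# seed={seed}\n")
        for contig, values in track.data.items():
            bs = track.bin_size
            for i, v in enumerate(values):
                handle.write(f"{contig}\t{i * bs}\t{(i + 1) * bs}\t{v:.10g}\n")


def read_expression(path: str | Path) -> pd.DataFrame:
    """Read a gene/control/treated TSV into a gene-indexed DataFrame."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t", comment="#")
    required = {"gene", "control", "treated"}
    if not required <= set(df.columns):
        raise FormatError(
            f"{path}: expression table needs columns {sorted(required)}"
        )
    if df["gene"].duplicated().any():
        raise FormatError(f"{path}: duplicate gene ids")
    df = df.set_index("gene")[["control", "treated"]].astype(float)
    if (df < 0).any().any():
        raise FormatError(f"{path}: negative expression values")
    return df


def write_expression(
    table: pd.DataFrame, path: str | Path, seed: int | None = None
) -> None:
    with open(path, "w") as handle:
        if seed is not None:
            handle.write(f"# seed={seed}\n")
        table.rename_axis("gene").reset_index().to_csv(
            handle, sep="\t", index=False
        )


def file_digest(path: str | Path) -> str:
    """SHA-256 digest of a file, for provenance logging."""
    h = hashlib.sha256()
    with open(path, "rb") as handle:
        for chunk in iter(lambda: handle.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()
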