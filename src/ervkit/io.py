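"""Readers/writers for the formats the pipeline touches.

FASTA reading is strict (duplicate names and empty records are errors, with
line numbers) because downstream stages key sequences by name.  All writes go
through :func:`atomic_write`: content is written to a temporary file in the
destination directory and renamed into place, so a crashed run never leaves a
truncated output.

GFF3 features use 1-based inclusive coordinates (GFF3-native, and the
package-wide convention).
"""

from __future__ import annotations

import dataclasses
import hashlib
import os
import tempfile
from collections.abc import Iterable, Mapping
from contextlib import contextmanager
from urllib.parse import quote, unquote

import pandas as pd
import yaml


@contextmanager
def atomic_write(path: str | os.PathLike):
    """Write-then-rename context manager yielding a text handle."""
    path = os.fspath(path)
    d = os.path.dirname(os.path.abspath(path))
    os.makedirs(d, exist_ok=True)
    fd, tmp = tempfile.mkstemp(dir=d, suffix=".tmp")
    try:
        with os.fdopen(fd, "w") as fh:
            yield fh
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise


def read_fasta(path: str | os.PathLike) -> dict[str, str]:
    """Read FASTA into an ordered ``{name: sequence}`` mapping.

    Names are taken up to the first whitespace.  Duplicate names, empty
    records and sequence data before the first header raise ``ValueError``
    naming the offending line.  CRLF and LF files parse identically.
    """
    seqs: dict[str, str] = {}
    name = None
    parts: list[str] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.rstrip("\r\n")
            if line.startswith(">"):
                if name is not None and not parts:
                    raise ValueError(f"{path}: empty record {name!r} before line {lineno}")
                if name is not None:
                    seqs[name] = "".join(parts)
                name = line[1:].split()[0] if line[1:].strip() else ""
                if not name:
                    raise ValueError(f"{path}:{lineno}: malformed header (no name)")
                if name in seqs:
                    raise ValueError(f"{path}:{lineno}: duplicate record name {name!r}")
                parts = []
            elif line.strip():
                if name is None:
                    raise ValueError(f"{path}:{lineno}: sequence data before first header")
                parts.append(line.strip())
    if name is not None:
        if not parts:
            raise ValueError(f"{path}: empty record {name!r} at end of file")
        seqs[name] = "".join(parts)
    if not seqs:
        raise ValueError(f"{path}: no FASTA records")
    return seqs


def write_fasta(seqs: Mapping[str, str], path: str | os.PathLike, wrap: int = 60) -> None:
    with atomic_write(path) as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), wrap):
                fh.write(seq[i : i + wrap] + "\n")


@dataclasses.dataclass
class GffFeature:
    """One GFF3 feature line; ``start``/``end`` are 1-based inclusive."""

    seqid: str
    source: str
    type: str
    start: int
    end: int
    score: float | None
    strand: str  # '+', '-' or '.'
    attributes: dict[str, str] = dataclasses.field(default_factory=dict)
    phase: str = "."


_GFF_SAFE = "".join(c for c in map(chr, range(33, 127)) if c not in "=;,%&\t")


def _attr_escape(v: str) -> str:
    return quote(v, safe=_GFF_SAFE + " ")


def write_gff3(features: Iterable[GffFeature], path: str | os.PathLike) -> None:
    with atomic_write(path) as fh:
        fh.write("##gff-version 3\n")
        for f in features:
            if f.start < 1 or f.end < f.start:
                raise ValueError(f"invalid GFF3 coordinates ({f.start}, {f.end}) on {f.seqid}")
            if f.strand not in "+-.":
                raise ValueError(f"invalid strand {f.strand!r}")
            attrs = ";".join(f"{k}={_attr_escape(str(v))}" for k, v in f.attributes.items())
            score = "." if f.score is None else f"{f.score:g}"
            fh.write(
                "\t".join(
                    [f.seqid, f.source, f.type, str(f.start), str(f.end), score, f.strand, f.phase, attrs or "."]
                )
                + "\n"
            )


def read_gff3(path: str | os.PathLike) -> list[GffFeature]:
    feats = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.rstrip("\r\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 9:
                raise ValueError(f"{path}:{lineno}: expected 9 columns, got {len(cols)}")
            attrs = {}
            if cols[8] != ".":
                for pair in cols[8].split(";"):
                    if pair:
                        k, _, v = pair.partition("=")
                        attrs[k] = unquote(v)
            start, end = int(cols[3]), int(cols[4])
            if start < 1 or end < start:
                raise ValueError(f"{path}:{lineno}: invalid coordinates ({start}, {end})")
            feats.append(
                GffFeature(
                    seqid=cols[0],
                    source=cols[1],
                    type=cols[2],
                    start=start,
                    end=end,
                    score=None if cols[5] == "." else float(cols[5]),
                    strand=cols[6],
                    phase=cols[7],
                    attributes=attrs,
                )
            )
    return feats


def read_plate_tsv(path: str | os.PathLike) -> pd.DataFrame:
    """Read a plate TSV with mandatory header ``well  stimulus  replicate  value``."""
    df = pd.read_csv(path, sep="\t")
    required = {"well", "stimulus", "replicate", "value"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing plate columns {sorted(missing)}")
    return df


def write_plate_tsv(df: pd.DataFrame, path: str | os.PathLike) -> None:
    with atomic_write(path) as fh:
        df.to_csv(fh, sep="\t", index=False)


def read_orf_table(path: str | os.PathLike) -> dict[str, tuple[int, int]]:
    """Read an ORF coordinate TSV with columns ``orf  start  end`` (1-based inclusive)."""
    df = pd.read_csv(path, sep="\t")
    for col in ("orf", "start", "end"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing column {col!r}")
    orfs = {}
    for _, row in df.iterrows():
        name = str(row["orf"])
        if name in orfs:
            raise ValueError(f"{path}: duplicate ORF name {name!r}")
        orfs[name] = (int(row["start"]), int(row["end"]))
    return orfs


def config_hash(config: Mapping) -> str:
    blob = yaml.safe_dump(dict(config), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def write_config(config: Mapping, path: str | os.PathLike) -> None:
    """Serialize the effective run configuration next to the outputs."""
    with atomic_write(path) as fh:
        yaml.safe_dump(dict(config), fh, sort_keys=True)
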