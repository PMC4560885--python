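"""File formats: TSV matrices, miRBase-style GFF3, BED6, PGM images, JSON.

Conventions
-----------
* Count/expression matrices: tab-separated, features in rows, a header row of
  sample ids, the first column holding feature ids.
* GFF3 annotation: 1-based closed intervals on disk, converted to 0-based
  half-open at parse time.  Feature types are ``miRNA_primary_transcript``
  (precursor) and ``miRNA`` (mature), linked by ``ID``/``Derives_from``.
* BED6 alignments: 0-based half-open, strand in column 6.
* Images: 8-bit PGM via imageio.

Round-trip (read of write) is the identity on valid files; malformed lines
are reported with their line number.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence

import imageio.v3 as iio
import numpy as np
import pandas as pd

from .quantify import Precursor, ReadAlignment


# ---------------------------------------------------------------------------
# TSV matrices and tables

def write_matrix(df: pd.DataFrame, path: str | Path, index_label: str = "feature") -> None:
    df.to_csv(path, sep="\t", index_label=index_label)


def read_matrix(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def write_table(df: pd.DataFrame, path: str | Path, index: bool = False) -> None:
    df.to_csv(path, sep="\t", index=index)


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# GFF3 (miRBase-like subset)

def write_gff3(annotation: Sequence[Precursor], path: str | Path) -> None:
    lines = ["##gff-version 3"]
    for p in annotation:
        # half-open -> 1-based closed
        lines.append(
            "\t".join(
                [
                    p.chrom, "seromir", "miRNA_primary_transcript",
                    str(p.start + 1), str(p.end), ".", p.strand, ".",
                    f"ID={p.precursor_id};Name={p.precursor_id}",
                ]
            )
        )
        for arm, iv in (("5p", p.mature5p), ("3p", p.mature3p)):
            if iv is None:
                continue
            mid = p.mature_ids[arm]
            lines.append(
                "\t".join(
                    [
                        p.chrom, "seromir", "miRNA",
                        str(iv[0] + 1), str(iv[1]), ".", p.strand, ".",
                        f"ID={mid};Name={mid};Derives_from={p.precursor_id}",
                    ]
                )
            )
    Path(path).write_text("\n".join(lines) + "\n")


def _gff_attributes(field: str, lineno: int) -> dict[str, str]:
    out = {}
    for part in field.strip().split(";"):
        if not part:
            continue
        if "=" not in part:
            raise ValueError(f"GFF3 line {lineno}: malformed attribute {part!r}")
        k, v = part.split("=", 1)
        out[k.strip()] = v.strip()
    return out


def read_gff3(path: str | Path) -> list[Precursor]:
    """Parse a miRBase-style GFF3 into Precursor records.

    Mature ``miRNA`` features are attached to their precursor through
    ``Derives_from``; the arm is inferred from the mature id suffix when
    present, otherwise from strand-aware position within the precursor.
    """
    rows = []
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        if not raw.strip() or raw.startswith("#"):
            continue
        parts = raw.split("\t")
        if len(parts) != 9:
            raise ValueError(f"GFF3 line {lineno}: expected 9 columns, got {len(parts)}")
        chrom, _, ftype, start, end, _, strand, _, attrs = parts
        try:
            start_i, end_i = int(start), int(end)
        except ValueError as exc:
            raise ValueError(f"GFF3 line {lineno}: non-integer coordinates") from exc
        if start_i > end_i:
            raise ValueError(f"GFF3 line {lineno}: start > end")
        rows.append((lineno, chrom, ftype, start_i - 1, end_i, strand, _gff_attributes(attrs, lineno)))

    precs: dict[str, dict] = {}
    order: list[str] = []
    for lineno, chrom, ftype, start, end, strand, attrs in rows:
        if ftype != "miRNA_primary_transcript":
            continue
        pid = attrs.get("ID")
        if pid is None:
            raise ValueError(f"GFF3 line {lineno}: precursor without ID attribute")
        precs[pid] = dict(chrom=chrom, start=start, end=end, strand=strand, m={})
        order.append(pid)
    for lineno, chrom, ftype, start, end, strand, attrs in rows:
        if ftype != "miRNA":
            continue
        parent = attrs.get("Derives_from")
        if parent not in precs:
            raise ValueError(f"GFF3 line {lineno}: Derives_from references unknown precursor")
        mid = attrs.get("ID", "")
        p = precs[parent]
        if mid.endswith("-5p"):
            arm = "5p"
        elif mid.endswith("-3p"):
            arm = "3p"
        else:
            mid_pos = 0.5 * (start + end)
            left = mid_pos < 0.5 * (p["start"] + p["end"])
            arm = ("5p" if left else "3p") if strand == "+" else ("3p" if left else "5p")
        p["m"][arm] = ((start, end), mid or None)
    out = []
    for pid in order:
        p = precs[pid]
        m5 = p["m"].get("5p")
        m3 = p["m"].get("3p")
        out.append(
            Precursor(
                precursor_id=pid, chrom=p["chrom"], start=p["start"], end=p["end"],
                strand=p["strand"],
                mature5p=m5[0] if m5 else None, mature3p=m3[0] if m3 else None,
                mature5p_id=m5[1] if m5 else None, mature3p_id=m3[1] if m3 else None,
            )
        )
    return out


# ---------------------------------------------------------------------------
# BED6 alignments

def write_bed6(reads: Sequence[ReadAlignment], path: str | Path) -> None:
    lines = [
        "\t".join([r.chrom, str(r.start), str(r.end), r.name, "0", r.strand])
        for r in reads
    ]
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))


def read_bed6(path: str | Path) -> list[ReadAlignment]:
    reads = []
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        if not raw.strip() or raw.startswith(("#", "track", "browser")):
            continue
        parts = raw.split("\t")
        if len(parts) < 6:
            raise ValueError(f"BED line {lineno}: expected 6 columns, got {len(parts)}")
        chrom, start, end, name, _, strand = parts[:6]
        try:
            start_i, end_i = int(start), int(end)
        except ValueError as exc:
            raise ValueError(f"BED line {lineno}: non-integer coordinates") from exc
        if start_i >= end_i:
            raise ValueError(f"BED line {lineno}: start >= end")
        if strand not in ("+", "-"):
            raise ValueError(f"BED line {lineno}: bad strand {strand!r}")
        reads.append(ReadAlignment(chrom=chrom, start=start_i, end=end_i, strand=strand, name=name))
    return reads


# ---------------------------------------------------------------------------
# PGM images and JSON

def write_pgm(pixels: np.ndarray, path: str | Path) -> None:
    iio.imwrite(Path(path), np.asarray(pixels, dtype=np.uint8), extension=".pgm")


def read_pgm(path: str | Path) -> np.ndarray:
    return np.asarray(iio.imread(Path(path)), dtype=np.uint8)


def write_json(obj, path: str | Path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True, default=_jsonable) + "\n")


def read_json(path: str | Path):
    return json.loads(Path(path).read_text())


def _jsonable(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON-serializable: {type(obj)}")
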