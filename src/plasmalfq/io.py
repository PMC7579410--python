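"""Readers and writers for the plain-text formats the pipeline touches.

FASTA goes through Biopython.  Abundance matrices are tab-delimited; two
dialects are supported: a ``generic`` layout (first column the accession,
remaining columns named ``<individual>_d<day>``) and a ``maxquant`` layout
mirroring the proteinGroups.txt export (``Majority protein IDs``,
``LFQ intensity <sample>``, ``Reverse``, ``Potential contaminant``).

Zero or blank intensities are treated as missing, following the convention of
label-free search engines where a zero means "not detected", not "absent".
"""

from __future__ import annotations

import math
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .datatypes import AbundanceTensor, ProteinRecord, SampleKey

__all__ = [
    "read_fasta",
    "write_fasta",
    "read_abundance_table",
    "write_abundance_table",
    "write_results",
    "read_config",
]

DEFAULT_CONTAMINANT_PREFIX = "CON__"
DEFAULT_DECOY_PREFIX = "REV__"


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(
    path: str | Path,
    contaminant_prefix: str = DEFAULT_CONTAMINANT_PREFIX,
    decoy_prefix: str = DEFAULT_DECOY_PREFIX,
) -> list[ProteinRecord]:
    """Read a protein database; the header token before the first whitespace
    is the accession, and configured prefixes flag contaminants/decoys."""
    records: list[ProteinRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        accession = rec.id
        if accession in seen:
            raise ValueError(f"duplicate accession {accession!r} in {path}")
        seen.add(accession)
        records.append(
            ProteinRecord(
                accession=accession,
                sequence=str(rec.seq).upper(),
                is_contaminant=accession.startswith(contaminant_prefix),
                is_decoy=accession.startswith(decoy_prefix),
            )
        )
    if not records:
        raise ValueError(f"no FASTA records in {path}")
    return records


def write_fasta(records: Sequence[ProteinRecord], path: str | Path) -> None:
    """Write records 60-column wrapped; headers carry only the accession."""
    if not records:
        raise ValueError("no records to write")
    seq_records = [
        SeqRecord(Seq(r.sequence), id=r.accession, description="") for r in records
    ]
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        SeqIO.write(seq_records, fh, "fasta")


# ---------------------------------------------------------------------------
# abundance tables
# ---------------------------------------------------------------------------

def _read_rows(path: str | Path) -> list[list[str]]:
    with open(path, encoding="utf-8") as fh:
        rows = [line.rstrip("\n").split("\t") for line in fh if line.strip("\n")]
    if len(rows) < 2:
        raise ValueError(f"{path}: need a header and at least one data row")
    width = len(rows[0])
    for i, row in enumerate(rows):
        if len(row) != width:
            raise ValueError(f"{path}: ragged row {i + 1} ({len(row)} fields, expected {width})")
    return rows


def _parse_cell(cell: str, where: str) -> tuple[float, bool]:
    """(value, observed); blanks, NaN and zero intensities are missing."""
    cell = cell.strip()
    if cell == "" or cell.lower() == "nan":
        return (np.nan, False)
    if "," in cell:
        raise ValueError(f"{where}: {cell!r} — decimal point only, no thousands separators")
    try:
        v = float(cell)
    except ValueError as exc:
        raise ValueError(f"{where}: unparseable number {cell!r}") from exc
    if v == 0.0:
        return (np.nan, False)
    return (v, True)


def read_abundance_table(path: str | Path, dialect: str = "generic") -> AbundanceTensor:
    """Read a protein x sample abundance matrix on the linear scale."""
    if dialect not in ("generic", "maxquant"):
        raise ValueError(f"unknown dialect {dialect!r}")
    rows = _read_rows(path)
    header, body = rows[0], rows[1:]

    if dialect == "generic":
        acc_col = 0
        sample_cols = list(range(1, len(header)))
        sample_keys = [SampleKey.from_label(header[j]) for j in sample_cols]
        keep = body
    else:
        def col(name: str) -> int:
            try:
                return header.index(name)
            except ValueError as exc:
                raise ValueError(f"{path}: missing column {name!r}") from exc

        acc_col = col("Majority protein IDs")
        rev_col = col("Reverse")
        con_col = col("Potential contaminant")
        sample_cols = [j for j, h in enumerate(header) if h.startswith("LFQ intensity ")]
        if not sample_cols:
            raise ValueError(f"{path}: no 'LFQ intensity <sample>' columns")
        sample_keys = [
            SampleKey.from_label(header[j][len("LFQ intensity "):]) for j in sample_cols
        ]
        keep = [r for r in body if r[rev_col].strip() != "+" and r[con_col].strip() != "+"]

    proteins: list[str] = []
    values = np.empty((len(keep), len(sample_cols)))
    mask = np.empty((len(keep), len(sample_cols)), dtype=bool)
    for i, row in enumerate(keep):
        acc = row[acc_col].strip()
        if not acc:
            raise ValueError(f"{path}: empty accession on data row {i + 1}")
        proteins.append(acc)
        for k, j in enumerate(sample_cols):
            values[i, k], mask[i, k] = _parse_cell(row[j], f"{path} row {i + 1}")
    return AbundanceTensor(proteins=proteins, samples=sample_keys, values=values, mask=mask, scale="linear")


def write_abundance_table(tensor: AbundanceTensor, path: str | Path) -> None:
    """Write the generic dialect; masked entries become blank cells."""
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("protein\t" + "\t".join(tensor.column_labels()) + "\n")
        for i, acc in enumerate(tensor.proteins):
            cells = [
                _format_float(tensor.values[i, j]) if tensor.mask[i, j] else ""
                for j in range(len(tensor.samples))
            ]
            fh.write(acc + "\t" + "\t".join(cells) + "\n")


def _format_float(x: float) -> str:
    return f"{x:.12g}"


# ---------------------------------------------------------------------------
# generic results tables
# ---------------------------------------------------------------------------

def write_results(records: pd.DataFrame | Sequence[dict], path: str | Path) -> None:
    """Write any tabular result as TSV with a deterministic column order.

    Floats are serialized to 12 significant digits so that a write/read
    round trip is lossless at that precision.
    """
    if isinstance(records, pd.DataFrame):
        frame = records
    else:
        frame = pd.DataFrame(list(records))
    if frame.empty:
        raise ValueError("no records to write")
    frame.to_csv(path, sep="\t", index=False, float_format="%.12g", lineterminator="\n")


def read_results(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

def read_config(path: str | Path) -> dict[str, object]:
    """Parse a ``key = value`` config file.

    Values are coerced to int, float, or bool when they look like one;
    comma-separated values become lists (e.g. ``days = 0,7,14``).
    """
    out: dict[str, object] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ValueError(f"{path}:{lineno}: expected key=value, got {line!r}")
            key, _, raw = line.partition("=")
            key, raw = key.strip(), raw.strip()
            if "," in raw:
                out[key] = [_coerce(tok.strip()) for tok in raw.split(",") if tok.strip()]
            else:
                out[key] = _coerce(raw)
    return out


def _coerce(tok: str) -> object:
    low = tok.lower()
    if low in ("true", "false"):
        return low == "true"
    try:
        return int(tok)
    except ValueError:
        pass
    try:
        return float(tok)
    except ValueError:
        pass
    return tok
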