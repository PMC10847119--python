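"""File parsing and writing for the pipeline's plain-text interchange formats.

Proteins arrive as FASTA; every tabular stage speaks tab-separated UTF-8
with a header row and ``.`` for missing values; counts may also arrive as
matrix-market triplets; contig annotations are accepted in AIRR-style or
Cell Ranger-style dialects.  Runs are recorded in a JSON manifest (tool
version, seed, parameters) sufficient to reproduce them.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
from Bio import SeqIO

from .affinity import TitrationSeries
from .peptides import PeptideTile, ProteinRecord
from .repertoire import CONTIG_COLUMNS
from .stability import RevealMeasurement

__all__ = [
    "read_fasta",
    "read_reveal",
    "read_titrations",
    "read_contigs",
    "read_counts",
    "write_tiles",
    "write_table",
    "write_manifest",
]

MISSING = "."

# column synonyms: package name -> accepted input headers (first match wins)
_CONTIG_SYNONYMS = {
    "barcode": ["barcode", "cell_id"],
    "chain": ["chain", "locus"],
    "v_gene": ["v_gene", "v_call"],
    "j_gene": ["j_gene", "j_call"],
    "cdr3_aa": ["cdr3_aa", "cdr3", "junction_aa"],
    "cdr3_nt": ["cdr3_nt", "junction"],
    "productive": ["productive"],
    "high_confidence": ["high_confidence", "high_conf"],
    "umis": ["umis", "umi_count", "duplicate_count"],
}

_TRUTHY = {"true", "t", "1", "yes"}
_FALSY = {"false", "f", "0", "no", "none", "", MISSING}


def _to_bool(value) -> bool:
    if isinstance(value, (bool, np.bool_)):
        return bool(value)
    if isinstance(value, (int, np.integer, float)):
        return bool(value)
    s = str(value).strip().lower()
    if s in _TRUTHY:
        return True
    if s in _FALSY:
        return False
    raise ValueError(f"cannot interpret {value!r} as a boolean")


def read_fasta(path: str | Path) -> list[ProteinRecord]:
    """Read proteins from FASTA.

    The first whitespace-separated token of each header is the id, the
    remainder the display name; sequences are uppercased (wrapped lines are
    joined by the parser).  Empty files, duplicate ids and illegal residues
    raise specific errors.
    """
    records = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ValueError(f"{path}: duplicate FASTA id {rec.id!r}")
        seen.add(rec.id)
        name = rec.description[len(rec.id) :].strip() or rec.id
        records.append(ProteinRecord(id=rec.id, name=name, sequence=str(rec.seq).upper()))
    if not records:
        raise ValueError(f"{path}: no FASTA records found")
    return records


def read_reveal(path: str | Path) -> list[RevealMeasurement]:
    """Read two-timepoint binding scores from TSV
    (``peptide_name, y0, y24[, t]``)."""
    df = pd.read_csv(path, sep="\t")
    required = {"peptide_name", "y0", "y24"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    if "t" not in df.columns:
        df["t"] = 24.0
    return [
        RevealMeasurement(
            peptide_name=str(r.peptide_name), y0=float(r.y0), y24=float(r.y24), t=float(r.t)
        )
        for r in df.itertuples()
    ]


def read_titrations(path: str | Path) -> list[TitrationSeries]:
    """Read titrations from TSV (``label, concentration_nM, mfi``), one
    :class:`TitrationSeries` per label, in file order of first appearance."""
    df = pd.read_csv(path, sep="\t")
    missing = {"label", "concentration_nM", "mfi"} - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    series = []
    for label in df["label"].drop_duplicates():
        sub = df[df["label"] == label]
        series.append(
            TitrationSeries(
                label=str(label),
                concentrations=sub["concentration_nM"].to_list(),
                mfi=sub["mfi"].to_list(),
            )
        )
    return series


def read_contigs(path: str | Path) -> pd.DataFrame:
    """Read a contig annotation table (CSV or TSV; AIRR-style or Cell
    Ranger-style headers) into the package's contig schema."""
    path = Path(path)
    sep = "\t" if path.suffix.lower() in {".tsv", ".txt"} else ","
    raw = pd.read_csv(path, sep=sep)
    out = {}
    for col, synonyms in _CONTIG_SYNONYMS.items():
        found = next((s for s in synonyms if s in raw.columns), None)
        if found is None:
            if col == "high_confidence":
                out[col] = pd.Series(True, index=raw.index)
                continue
            raise ValueError(
                f"{path}: no column for {col!r} (accepted: {synonyms})"
            )
        out[col] = raw[found]
    df = pd.DataFrame(out)
    df["productive"] = df["productive"].map(_to_bool)
    df["high_confidence"] = df["high_confidence"].map(_to_bool)
    df["umis"] = df["umis"].astype(int)
    # normalize AIRR locus spellings (e.g. "tra") to TRA/TRB
    df["chain"] = df["chain"].astype(str).str.upper()
    return df[CONTIG_COLUMNS]


def read_counts(path: str | Path) -> pd.DataFrame:
    """Read a genes x cells count matrix.

    ``.mtx`` files are read as matrix-market triplets, with gene and cell
    names taken from sibling ``<stem>.genes.txt`` / ``<stem>.cells.txt``
    files when present; anything else is read as dense TSV with gene names
    in the first column and cell names in the header.
    """
    path = Path(path)
    if path.suffix == ".mtx":
        from scipy.io import mmread

        mat = mmread(str(path)).toarray().astype(np.int64)
        genes_file = path.with_suffix(".genes.txt")
        cells_file = path.with_suffix(".cells.txt")
        genes = (
            genes_file.read_text().split()
            if genes_file.exists()
            else [f"G{i}" for i in range(mat.shape[0])]
        )
        cells = (
            cells_file.read_text().split()
            if cells_file.exists()
            else [f"C{i}" for i in range(mat.shape[1])]
        )
        return pd.DataFrame(mat, index=genes, columns=cells)
    df = pd.read_csv(path, sep="\t", index_col=0)
    return df.astype(np.int64)


def write_tiles(tiles: list[PeptideTile], path: str | Path) -> None:
    """Write tiles as TSV (``parent_id, name, start, end, sequence``)."""
    df = pd.DataFrame(
        [
            {
                "parent_id": t.parent_id,
                "name": t.name,
                "start": t.start,
                "end": t.end,
                "sequence": t.sequence,
            }
            for t in tiles
        ]
    )
    write_table(df, path)


def write_table(df: pd.DataFrame, path: str | Path) -> None:
    """Write a DataFrame as the package's TSV dialect (``.`` for missing)."""
    df.to_csv(path, sep="\t", index=False, na_rep=MISSING)


def write_manifest(path: str | Path, seed: int | None, parameters: dict[str, Any]) -> None:
    """Record a run's provenance (tool version, seed, parameters) as JSON."""
    from . import __version__

    manifest = {"tool": "immunoquant", "version": __version__, "seed": seed,
                "parameters": parameters}
    Path(path).write_text(json.dumps(manifest, indent=2, default=str) + "\n")
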