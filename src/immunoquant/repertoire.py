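"""Paired alpha/beta TCR clonotype aggregation from single-cell V(D)J contigs.

Single-cell immune profiling emits one annotated contig per assembled TCR
chain per cell barcode.  This module filters those contigs to one productive,
high-confidence TRA and one TRB per cell, groups cells by identical paired
(V gene, J gene, nucleotide CDR3) chains -- the granularity used by the
common 10x convention -- and ranks the resulting clonotypes by clone count.

Contig tables are plain :class:`pandas.DataFrame` objects with (at least)
the columns ``barcode, chain, v_gene, j_gene, cdr3_aa, cdr3_nt, productive,
high_confidence, umis``, compatible with AIRR-style or Cell Ranger-style
contig annotation exports (see :func:`immunoquant.io.read_contigs`).
"""

from __future__ import annotations

import pandas as pd

__all__ = ["CONTIG_COLUMNS", "filter_contigs", "aggregate_clonotypes"]

CONTIG_COLUMNS = [
    "barcode",
    "chain",
    "v_gene",
    "j_gene",
    "cdr3_aa",
    "cdr3_nt",
    "productive",
    "high_confidence",
    "umis",
]

_KEY_COLUMNS = [
    "tra_v_gene",
    "tra_j_gene",
    "tra_cdr3_nt",
    "trb_v_gene",
    "trb_j_gene",
    "trb_cdr3_nt",
]


def _validate(records: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in CONTIG_COLUMNS if c not in records.columns]
    if missing:
        raise ValueError(f"contig table is missing columns: {missing}")
    bad_chain = set(records["chain"].unique()) - {"TRA", "TRB"}
    if bad_chain:
        raise ValueError(f"unknown chain value(s): {sorted(bad_chain)}; expected TRA/TRB")
    if (records["umis"] < 1).any():
        raise ValueError("UMI counts must be >= 1")
    return records


def filter_contigs(records: pd.DataFrame) -> pd.DataFrame:
    """Reduce a contig table to one TRA and one TRB per surviving cell.

    Keeps productive, high-confidence contigs; within each (barcode, chain)
    the highest-UMI contig wins (ties resolved to the lexicographically
    smallest ``cdr3_nt``, so the rule is deterministic); finally only cells
    retaining both one TRA and one TRB survive.  The output may be empty.
    """
    records = _validate(records)
    kept = records[
        records["productive"].astype(bool) & records["high_confidence"].astype(bool)
    ].copy()
    if kept.empty:
        return kept.reset_index(drop=True)
    # UMI dominance within (barcode, chain); ties -> smallest cdr3_nt
    kept = kept.sort_values(
        ["barcode", "chain", "umis", "cdr3_nt"],
        ascending=[True, True, False, True],
        kind="mergesort",
    )
    kept = kept.drop_duplicates(subset=["barcode", "chain"], keep="first")
    n_chains = kept.groupby("barcode")["chain"].nunique()
    paired = n_chains[n_chains == 2].index
    out = kept[kept["barcode"].isin(paired)]
    return out.sort_values(["barcode", "chain"], kind="mergesort").reset_index(drop=True)


def aggregate_clonotypes(records: pd.DataFrame) -> pd.DataFrame:
    """Group filtered contigs into paired clonotypes ranked by clone count.

    ``records`` must already satisfy the :func:`filter_contigs` contract
    (exactly one TRA and one TRB per barcode).  Cells sharing identical
    (TRA V/J/CDR3nt, TRB V/J/CDR3nt) keys form one clonotype; clonotypes
    are ordered by descending clone count with ties broken by key, and
    frequencies are computed over all paired cells.

    Returns
    -------
    pandas.DataFrame
        Columns ``tra_v_gene, tra_j_gene, tra_cdr3_nt, trb_v_gene,
        trb_j_gene, trb_cdr3_nt, clone_count, frequency, rank``.
    """
    records = _validate(records)
    if records.empty:
        return pd.DataFrame(columns=_KEY_COLUMNS + ["clone_count", "frequency", "rank"])
    per_chain = records.groupby("barcode")["chain"].agg(["nunique", "size"])
    if not ((per_chain["nunique"] == 2) & (per_chain["size"] == 2)).all():
        raise ValueError(
            "records must contain exactly one TRA and one TRB per barcode; "
            "run filter_contigs first"
        )
    wide = records.pivot(index="barcode", columns="chain")
    keys = pd.DataFrame(
        {
            "tra_v_gene": wide[("v_gene", "TRA")],
            "tra_j_gene": wide[("j_gene", "TRA")],
            "tra_cdr3_nt": wide[("cdr3_nt", "TRA")],
            "trb_v_gene": wide[("v_gene", "TRB")],
            "trb_j_gene": wide[("j_gene", "TRB")],
            "trb_cdr3_nt": wide[("cdr3_nt", "TRB")],
        }
    )
    counts = keys.groupby(_KEY_COLUMNS, sort=True).size().rename("clone_count").reset_index()
    counts = counts.sort_values(
        ["clone_count"] + _KEY_COLUMNS, ascending=[False] + [True] * 6, kind="mergesort"
    ).reset_index(drop=True)
    counts["frequency"] = counts["clone_count"] / counts["clone_count"].sum()
    counts["rank"] = counts.index + 1
    return counts
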