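"""Tabular input/output: MK tables, SFS, and gene-class labels as TSV."""

from __future__ import annotations

import pandas as pd

from .alignment import MKTable
from .sfs import SFS

MK_COLUMNS = ["gene_id", "class", "P_N", "P_S", "D_N", "D_S", "L_N", "L_S"]


def write_mk_tables(tables: list[MKTable], path, extra: dict | None = None) -> None:
    """Write per-gene MK tables (optionally with extra per-gene columns)."""
    rows = []
    for t in tables:
        row = {
            "gene_id": t.gene_id, "class": t.class_label,
            "P_N": t.P_N, "P_S": t.P_S, "D_N": t.D_N, "D_S": t.D_S,
            "L_N": t.L_N, "L_S": t.L_S,
        }
        if extra and t.gene_id in extra:
            row.update(extra[t.gene_id])
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_mk_tables(path) -> list[MKTable]:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in MK_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    return [
        MKTable(
            gene_id=str(r.gene_id), class_label=str(r["class"]),
            P_N=int(r.P_N), P_S=int(r.P_S), D_N=int(r.D_N), D_S=int(r.D_S),
            L_N=float(r.L_N), L_S=float(r.L_S),
        )
        for _, r in df.iterrows()
    ]


def write_sfs(sfs: SFS, path) -> None:
    sfs.to_dataframe().to_csv(path, sep="\t", index=False)


def read_sfs(path, n: int | None = None, site_class: str = "synonymous") -> SFS:
    df = pd.read_csv(path, sep="\t")
    folded = "minor_allele_count" in df.columns
    counts = df["n_sites"].to_numpy(dtype=float)
    if n is None:
        n = 2 * len(counts) if folded else len(counts) + 1
    return SFS(n=n, counts=counts, folded=folded, site_class=site_class)


def read_class_labels(path) -> dict[str, str]:
    df = pd.read_csv(path, sep="\t")
    cols = list(df.columns)
    if "gene_id" in cols and "class" in cols:
        return dict(zip(df["gene_id"].astype(str), df["class"].astype(str)))
    # headerless two-column fallback
    df = pd.read_csv(path, sep="\t", header=None, names=["gene_id", "class"])
    return dict(zip(df["gene_id"].astype(str), df["class"].astype(str)))
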