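"""Genotype file formats: delimited tables and Genepop.

Delimited dialect: CSV with columns ``individual_id, x, y, zone,
[cluster_id], <locus>_a1, <locus>_a2, ...``; a missing locus has both fields
empty.  Genepop dialect: standard 2- or 3-digit allele encoding with ``0`` /
``000`` as the missing sentinel; coordinates and zone labels are not part of
the Genepop format, so they come back as zeros / the pop index.
"""

from __future__ import annotations

import csv

import numpy as np
import pandas as pd

from .genetics import MISSING, GenotypeError, GenotypeTable


def write_genotypes_delimited(table: GenotypeTable, path) -> None:
    df = table.to_frame()
    for name in table.locus_names:
        for suffix in ("_a1", "_a2"):
            col = f"{name}{suffix}"
            df[col] = df[col].astype(object)
            df.loc[df[col] == MISSING, col] = ""
    df.to_csv(path, index=False)


def read_genotypes_delimited(path) -> GenotypeTable:
    df = pd.read_csv(path, dtype={"individual_id": str, "zone": str})
    required = {"individual_id", "x", "y", "zone"}
    if not required <= set(df.columns):
        raise GenotypeError(f"{path}: missing columns {required - set(df.columns)}")
    locus_names = []
    for col in df.columns:
        if col.endswith("_a1"):
            name = col[:-3]
            if f"{name}_a2" not in df.columns:
                raise GenotypeError(f"{path}: locus {name} lacks _a2 column")
            locus_names.append(name)
    if not locus_names:
        raise GenotypeError(f"{path}: no locus columns found")
    n = len(df)
    alleles = np.full((n, len(locus_names), 2), MISSING, dtype=int)
    for l, name in enumerate(locus_names):
        for k, suffix in enumerate(("_a1", "_a2")):
            col = df[f"{name}{suffix}"]
            vals = pd.to_numeric(col, errors="coerce")
            bad = vals.isna() & col.notna() & (col.astype(str).str.strip() != "")
            if bad.any():
                row = int(np.flatnonzero(bad)[0])
                raise GenotypeError(
                    f"{path}: malformed allele at line {row + 2}, "
                    f"column {name}{suffix}"
                )
            ok = vals.notna()
            alleles[ok.to_numpy(), l, k] = vals[ok].astype(int).to_numpy()
    cluster = (
        df["cluster_id"].astype(str).to_numpy()
        if "cluster_id" in df.columns
        else None
    )
    return GenotypeTable(
        ids=df["individual_id"].to_numpy(dtype=object),
        x=df["x"].to_numpy(dtype=float),
        y=df["y"].to_numpy(dtype=float),
        zone=df["zone"].to_numpy(dtype=object),
        alleles=alleles,
        locus_names=locus_names,
        cluster_id=cluster,
    )


def write_genotypes_genepop(
    table: GenotypeTable, path, digits: int = 3, title: str = "lgflow export"
) -> None:
    """Write one Genepop population per zone."""
    if digits not in (2, 3):
        raise GenotypeError("genepop digits must be 2 or 3")
    with open(path, "w") as fh:
        fh.write(title + "\n")
        for name in table.locus_names:
            fh.write(name + "\n")
        for zone in pd.unique(table.zone):
            fh.write("Pop\n")
            sel = np.flatnonzero(table.zone == zone)
            for i in sel:
                parts = []
                for l in range(table.n_loci):
                    a1, a2 = table.alleles[i, l]
                    a1 = 0 if a1 == MISSING else a1
                    a2 = 0 if a2 == MISSING else a2
                    parts.append(f"{a1:0{digits}d}{a2:0{digits}d}")
                fh.write(f"{table.ids[i]} , " + " ".join(parts) + "\n")


def read_genotypes_genepop(path, digits: int = 3) -> GenotypeTable:
    if digits not in (2, 3):
        raise GenotypeError("genepop digits must be 2 or 3")
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh]
    if len(lines) < 3:
        raise GenotypeError(f"{path}: not a genepop file")
    locus_names: list[str] = []
    i = 1
    while i < len(lines) and lines[i].strip().lower() != "pop":
        chunk = [s.strip() for s in lines[i].split(",") if s.strip()]
        locus_names.extend(chunk)
        i += 1
    if i == len(lines):
        raise GenotypeError(f"{path}: no Pop line found")
    ids, zones, rows = [], [], []
    pop_idx = 0
    for lineno, line in enumerate(lines[i:], start=i + 1):
        if not line.strip():
            continue
        if line.strip().lower() == "pop":
            pop_idx += 1
            continue
        if "," not in line:
            raise GenotypeError(f"{path}: malformed row at line {lineno}")
        ind, genos = line.split(",", 1)
        tokens = genos.split()
        if len(tokens) != len(locus_names):
            raise GenotypeError(
                f"{path}: line {lineno}: expected {len(locus_names)} loci, "
                f"got {len(tokens)}"
            )
        row = []
        for tok in tokens:
            if len(tok) != 2 * digits or not tok.isdigit():
                raise GenotypeError(
                    f"{path}: line {lineno}: bad genotype token {tok!r}"
                )
            a1, a2 = int(tok[:digits]), int(tok[digits:])
            if a1 == 0 or a2 == 0:
                row.append((MISSING, MISSING))
            else:
                row.append((a1, a2))
        ids.append(ind.strip())
        zones.append(f"pop{pop_idx + 1}")
        rows.append(row)
    if not rows:
        raise GenotypeError(f"{path}: no individuals")
    return GenotypeTable(
        ids=np.array(ids, dtype=object),
        x=np.zeros(len(ids)),
        y=np.zeros(len(ids)),
        zone=np.array(zones, dtype=object),
        alleles=np.array(rows, dtype=int),
        locus_names=locus_names,
    )


def read_genotypes(path, dialect: str = "delimited", **kw) -> GenotypeTable:
    if dialect == "delimited":
        return read_genotypes_delimited(path)
    if dialect == "genepop":
        return read_genotypes_genepop(path, **kw)
    raise GenotypeError(f"unknown genotype dialect {dialect!r}")


def write_node_sets(node_sets: dict, raster, path) -> None:
    """Lek cells as a delimited table (cluster_id, row, col, x, y)."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["cluster_id", "row", "col", "x", "y"])
        for cid in sorted(node_sets):
            for r, c in node_sets[cid]:
                x, y = raster.cell_center(r, c)
                w.writerow([cid, r, c, x, y])


def read_node_sets(path) -> dict:
    df = pd.read_csv(path)
    out: dict = {}
    for _, row in df.iterrows():
        out.setdefault(str(row["cluster_id"]), []).append(
            (int(row["row"]), int(row["col"]))
        )
    return out
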