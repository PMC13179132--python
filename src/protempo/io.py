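"""Readers and writers for the on-disk formats.

All tabular formats are UTF-8, tab-separated, single header row.  Gene sets
use standard GMT (name, description, members...); the description field holds
the source-database tag.  Readers validate and reject rather than coerce:
duplicate features, unknown samples or out-of-range correlations are hard
errors naming the offending rows.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .datatypes import (
    EDGE_COLUMNS,
    GENE_SET_SOURCES,
    SAMPLE_COLUMNS,
    AbundanceMatrix,
    CorrelationNetwork,
    GeneSet,
    GeneSetCollection,
    OrthologyMap,
    PhosphositeMatrix,
    ValidationError,
    validate_sample_sheet,
)

log = logging.getLogger(__name__)

_NA_VALUES = ["", "NA"]


def read_sample_sheet(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str}, keep_default_na=False,
                     na_values=_NA_VALUES)
    return validate_sample_sheet(df)


def write_sample_sheet(samples: pd.DataFrame, path: str | Path) -> None:
    samples[SAMPLE_COLUMNS].to_csv(path, sep="\t", index=False)


def read_abundance_matrix(
    path: str | Path,
    sample_sheet: str | Path | pd.DataFrame,
    scale: str = "raw",
) -> AbundanceMatrix:
    """Read a feature-by-sample TSV joined with its sample sheet.

    The first column holds feature IDs; remaining columns must all appear in
    the sample sheet.  Empty cells and ``NA`` are read as missing, never as
    zero.  Duplicate feature IDs are a hard error naming the duplicates.
    """
    df = pd.read_csv(path, sep="\t", index_col=0, keep_default_na=False,
                     na_values=_NA_VALUES)
    df.index = df.index.astype(str)
    df.index.name = None
    if df.index.has_duplicates:
        dup = sorted(set(df.index[df.index.duplicated()]))
        raise ValidationError(f"duplicate feature IDs in {path}: {dup}")
    if isinstance(sample_sheet, (str, Path)):
        sheet = read_sample_sheet(sample_sheet)
    else:
        sheet = validate_sample_sheet(sample_sheet)
    unknown = [c for c in df.columns if c not in sheet.index]
    if unknown:
        raise ValidationError(
            f"samples in matrix absent from sample sheet: {unknown}"
        )
    return AbundanceMatrix(df, sheet, scale=scale)


def write_abundance_matrix(
    matrix: AbundanceMatrix,
    path: str | Path,
    sample_sheet_path: str | Path | None = None,
) -> None:
    out = matrix.values.copy()
    out.index.name = "feature"
    out.to_csv(path, sep="\t", na_rep="NA")
    if sample_sheet_path is not None:
        write_sample_sheet(matrix.samples, sample_sheet_path)


# ---------------------------------------------------------------------------
# GMT gene sets

def read_gene_sets(
    path: str | Path, default_source: str | None = None
) -> GeneSetCollection:
    """Read a GMT file into a :class:`GeneSetCollection`.

    The GMT description field supplies the source tag when it is one of the
    recognised categories; otherwise ``default_source`` is used.  Sets with
    no members are dropped with a logged warning.
    """
    sets: dict[str, GeneSet] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise ValidationError(f"{path}:{lineno}: malformed GMT line")
            name, desc = parts[0], parts[1]
            members = frozenset(m for m in parts[2:] if m)
            if not members:
                log.warning("dropping empty gene set %r (%s:%d)", name, path, lineno)
                continue
            if desc in GENE_SET_SOURCES:
                source = desc
            elif default_source is not None:
                source = default_source
            else:
                raise ValidationError(
                    f"{path}:{lineno}: description {desc!r} is not a known source "
                    f"tag and no default_source was given"
                )
            if name in sets:
                raise ValidationError(f"{path}:{lineno}: duplicate set name {name!r}")
            sets[name] = GeneSet(name=name, members=members, source=source)
    return GeneSetCollection(sets)


def write_gene_sets(collection: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for gs in collection:
            fh.write("\t".join([gs.name, gs.source, *sorted(gs.members)]) + "\n")


# ---------------------------------------------------------------------------
# Edge lists

def write_edge_list(network: CorrelationNetwork, path: str | Path) -> None:
    network.edges.to_csv(path, sep="\t", index=False)


def read_edge_list(
    path: str | Path,
    r_min: float = 0.95,
    alpha: float = 0.01,
    n_samples: int | None = None,
    validate_thresholds: bool = False,
) -> CorrelationNetwork:
    """Read a TSV edge list; exact inverse of :func:`write_edge_list`.

    Malformed rows raise with their line number.  ``r`` outside [-1, 1] or a
    sign inconsistent with ``r`` is rejected.
    """
    df = pd.read_csv(path, sep="\t", dtype={"protein_a": str, "protein_b": str})
    missing = [c for c in EDGE_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: missing edge columns {missing}")
    for col in ("r", "p_raw", "p_adj"):
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[vals.isna() & df[col].notna()]
        if len(bad):
            # +2: one for the header, one for 1-based numbering
            raise ValidationError(f"{path}: malformed {col} at line {bad[0] + 2}")
        df[col] = vals
    out_of_range = df.index[df["r"].abs() > 1 + 1e-12]
    if len(out_of_range):
        raise ValidationError(
            f"{path}: r outside [-1, 1] at line {out_of_range[0] + 2}"
        )
    net = CorrelationNetwork(df, r_min=r_min, alpha=alpha, n_samples=n_samples)
    if validate_thresholds:
        r = net.edges["r"].to_numpy()
        if (np.abs(r) < r_min).any() or (net.edges["p_adj"] >= alpha).any():
            raise ValidationError(f"{path}: edges violate the stated thresholds")
    return net


# ---------------------------------------------------------------------------
# Small auxiliary tables

def read_orthology_map(path: str | Path) -> OrthologyMap:
    """Two-column TSV (human feature ID, mouse feature ID); must be 1:1."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.shape[1] < 2:
        raise ValidationError(f"{path}: orthology map needs two columns")
    return OrthologyMap(zip(df.iloc[:, 0], df.iloc[:, 1]))


def write_orthology_map(omap: OrthologyMap, path: str | Path) -> None:
    pd.DataFrame(list(omap.items()), columns=["human", "mouse"]).to_csv(
        path, sep="\t", index=False
    )


def read_kinase_substrate_table(path: str | Path) -> pd.DataFrame:
    """Kinase-substrate TSV with columns kinase, substrate, residue, position.

    A combined ``site`` column (``S123`` style) is accepted in place of the
    residue/position pair.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    need = {"kinase", "substrate"}
    if not need <= set(df.columns):
        raise ValidationError(f"{path}: needs columns {sorted(need)}")
    if "site" in df.columns and "residue" not in df.columns:
        df["residue"] = df["site"].str[0]
        df["position"] = df["site"].str[1:]
    if "residue" not in df.columns or "position" not in df.columns:
        raise ValidationError(f"{path}: needs residue/position (or site) columns")
    df["position"] = df["position"].astype(int)
    return df[["kinase", "substrate", "residue", "position"]]


def write_kinase_substrate_table(ks: pd.DataFrame, path: str | Path) -> None:
    ks[["kinase", "substrate", "residue", "position"]].to_csv(
        path, sep="\t", index=False
    )


def read_ppi_table(path: str | Path) -> set[frozenset[str]]:
    """Two-column TSV of interacting protein pairs -> set of unordered pairs."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.shape[1] < 2:
        raise ValidationError(f"{path}: PPI table needs two columns")
    return {
        frozenset((a, b))
        for a, b in zip(df.iloc[:, 0], df.iloc[:, 1])
        if a != b
    }


def write_ppi_table(pairs: set[frozenset[str]], path: str | Path) -> None:
    rows = sorted(tuple(sorted(p)) for p in pairs)
    pd.DataFrame(rows, columns=["protein_a", "protein_b"]).to_csv(
        path, sep="\t", index=False
    )


# ---------------------------------------------------------------------------
# Phosphosite matrices

def read_phosphosite_matrix(
    path: str | Path,
    sample_sheet: str | Path | pd.DataFrame,
    site_table: str | Path | pd.DataFrame | None = None,
    scale: str = "log2_ratio",
) -> PhosphositeMatrix:
    """Read a site-by-sample TSV; site identity comes from ``site_table`` or,
    failing that, is parsed from ``PROTEIN_S123``-style row IDs."""
    from .datatypes import parse_site_id

    mat = pd.read_csv(path, sep="\t", index_col=0, keep_default_na=False,
                      na_values=_NA_VALUES)
    mat.index = mat.index.astype(str)
    mat.index.name = None
    if isinstance(sample_sheet, (str, Path)):
        sheet = read_sample_sheet(sample_sheet)
    else:
        sheet = validate_sample_sheet(sample_sheet)
    if site_table is None:
        rows = {sid: parse_site_id(sid) for sid in mat.index}
        sites = pd.DataFrame.from_dict(
            rows, orient="index", columns=["protein", "residue", "position"]
        )
    elif isinstance(site_table, (str, Path)):
        sites = pd.read_csv(site_table, sep="\t", index_col=0, dtype={"position": int})
    else:
        sites = site_table
    return PhosphositeMatrix(mat, sheet, sites, scale=scale)


def write_phosphosite_matrix(
    sites: PhosphositeMatrix,
    path: str | Path,
    site_table_path: str | Path | None = None,
    sample_sheet_path: str | Path | None = None,
) -> None:
    out = sites.values.copy()
    out.index.name = "site_id"
    out.to_csv(path, sep="\t", na_rep="NA")
    if site_table_path is not None:
        st = sites.sites.copy()
        st.index.name = "site_id"
        st.to_csv(site_table_path, sep="\t")
    if sample_sheet_path is not None:
        write_sample_sheet(sites.samples, sample_sheet_path)


def read_alias_table(path: str | Path) -> dict[str, str]:
    """Optional two-column accession->symbol alias file."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.shape[1] < 2:
        raise ValidationError(f"{path}: alias table needs two columns")
    return dict(zip(df.iloc[:, 0], df.iloc[:, 1]))
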