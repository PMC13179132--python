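"""Core in-memory containers shared by every analysis stage.

The common currency is the :class:`AbundanceMatrix`: a dense feature-by-sample
table of quantifications (raw intensities / counts, or log2 ratios against a
per-group geometric-mean baseline) together with per-sample metadata.  Gene-set
collections, correlation networks, phosphosite tables and ortholog maps are
thin validated wrappers around pandas objects.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

SCALES = ("raw", "log2_ratio")
ASSAYS = ("protein", "rna", "phosphosite")
SPECIES = ("human", "mouse", "synthetic")
RESIDUES = ("S", "T", "Y")

SAMPLE_COLUMNS = ["sample_id", "species", "cell_line", "stage", "replicate", "assay"]

GENE_SET_SOURCES = (
    "complex",
    "pathway",
    "go_bp",
    "go_mf",
    "go_cc",
    "localization",
    "ppi",
    "tf_targets",
    "kinase_substrates",
    "disease",
)

#: Gene-set sources treated as GO categories (subject to the <=150-gene cap).
GO_SOURCES = ("go_bp", "go_mf", "go_cc")

EDGE_COLUMNS = ["protein_a", "protein_b", "r", "p_raw", "p_adj", "sign"]

_SITE_ID_RE = re.compile(r"^(?P<protein>.+)_(?P<residue>[STY])(?P<position>[1-9][0-9]*)$")


class ValidationError(ValueError):
    """Raised when an input violates a container invariant.

    Readers reject invariant-violating input outright instead of coercing it.
    """


def validate_sample_sheet(samples: pd.DataFrame) -> pd.DataFrame:
    """Validate and canonicalize a sample-metadata table.

    Accepts a frame with the columns ``sample_id, species, cell_line, stage,
    replicate, assay`` (``sample_id`` may instead be the index) and returns a
    copy indexed by ``sample_id``.  Stage order is taken as order of first
    appearance in the sheet and stored as an ordered categorical.
    """
    df = samples.copy()
    if "sample_id" not in df.columns:
        if df.index.name == "sample_id":
            df = df.reset_index()
        else:
            raise ValidationError("sample sheet must have a 'sample_id' column")
    missing = [c for c in SAMPLE_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"sample sheet missing columns: {missing}")
    dup = df["sample_id"][df["sample_id"].duplicated()].tolist()
    if dup:
        raise ValidationError(f"duplicate sample_id values: {sorted(set(dup))}")
    bad_species = sorted(set(df["species"]) - set(SPECIES))
    if bad_species:
        raise ValidationError(f"unknown species: {bad_species} (allowed: {SPECIES})")
    bad_assay = sorted(set(df["assay"]) - set(ASSAYS))
    if bad_assay:
        raise ValidationError(f"unknown assay: {bad_assay} (allowed: {ASSAYS})")
    df["replicate"] = df["replicate"].astype(int)
    if (df["replicate"] < 1).any():
        raise ValidationError("replicate numbers must be positive integers")
    stage_order = list(dict.fromkeys(df["stage"]))
    df["stage"] = pd.Categorical(df["stage"], categories=stage_order, ordered=True)
    return df.set_index("sample_id", drop=False)


@dataclass
class AbundanceMatrix:
    """Dense feature-by-sample quantification with sample metadata.

    Parameters
    ----------
    values
        Features on the index, sample IDs on the columns; ``NaN`` marks a
        missing measurement (never silently zero).
    samples
        Sample sheet indexed by ``sample_id``; one row per column of `values`.
    scale
        ``"raw"`` (strictly positive intensities or counts) or
        ``"log2_ratio"`` (log2 fold change against a stated baseline).
        Downstream operations declare which scale they accept.
    """

    values: pd.DataFrame
    samples: pd.DataFrame
    scale: str = "raw"

    def __post_init__(self) -> None:
        if self.scale not in SCALES:
            raise ValidationError(f"scale must be one of {SCALES}, got {self.scale!r}")
        self.samples = validate_sample_sheet(self.samples)
        if self.values.index.has_duplicates:
            dup = self.values.index[self.values.index.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate feature IDs: {dup}")
        unknown = [c for c in self.values.columns if c not in self.samples.index]
        if unknown:
            raise ValidationError(f"samples absent from sample sheet: {unknown}")
        # keep metadata restricted to, and ordered like, the matrix columns
        self.samples = self.samples.loc[list(self.values.columns)]
        self.values = self.values.astype(float)

    # -- conveniences -------------------------------------------------------

    @property
    def features(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def stages(self) -> list[str]:
        """Stage labels in their configured developmental order."""
        return [s for s in self.samples["stage"].cat.categories
                if s in set(self.samples["stage"])]

    def subset_features(self, features: Iterable[str]) -> "AbundanceMatrix":
        keep = [f for f in features if f in self.values.index]
        return AbundanceMatrix(self.values.loc[keep], self.samples, self.scale)

    def subset_samples(self, sample_ids: Iterable[str]) -> "AbundanceMatrix":
        keep = [s for s in sample_ids if s in self.values.columns]
        return AbundanceMatrix(self.values[keep], self.samples.loc[keep], self.scale)

    def stage_means(self, by: tuple[str, ...] = ("stage",)) -> pd.DataFrame:
        """Per-feature means over sample groups (default: per stage).

        Columns are ordered by stage order, then by the remaining keys.
        """
        keys = [self.samples.loc[c, list(by)] for c in self.values.columns]
        grouped = self.values.T.groupby(
            [self.samples["stage" if b == "stage" else b] for b in by], observed=True
        ).mean().T
        return grouped


@dataclass(frozen=True)
class GeneSet:
    """A named gene set with its source-database category.

    ``detected`` is filled in by preprocessing with the subset of members
    present in the measured data.
    """

    name: str
    members: frozenset[str]
    source: str
    detected: frozenset[str] | None = None

    def __post_init__(self) -> None:
        if not self.members:
            raise ValidationError(f"gene set {self.name!r} is empty")
        if self.source not in GENE_SET_SOURCES:
            raise ValidationError(
                f"gene set {self.name!r}: unknown source {self.source!r}"
            )
        if self.detected is not None and not self.detected <= self.members:
            raise ValidationError(
                f"gene set {self.name!r}: detected subset not within members"
            )


@dataclass
class GeneSetCollection:
    """Mapping of set name -> :class:`GeneSet`."""

    sets: dict[str, GeneSet] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, gs in self.sets.items():
            if name != gs.name:
                raise ValidationError(f"key {name!r} does not match set name {gs.name!r}")

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets.values())

    def __getitem__(self, name: str) -> GeneSet:
        return self.sets[name]

    def by_source(self, source: str) -> "GeneSetCollection":
        return GeneSetCollection(
            {n: s for n, s in self.sets.items() if s.source == source}
        )

    def member_index(self) -> dict[str, set[str]]:
        """Invert the collection: member ID -> names of sets containing it."""
        idx: dict[str, set[str]] = {}
        for gs in self:
            for m in gs.members:
                idx.setdefault(m, set()).add(gs.name)
        return idx


def canonical_edge_order(a: str, b: str) -> tuple[str, str]:
    """Canonical (lexicographic) ordering for an unordered protein pair."""
    return (a, b) if a <= b else (b, a)


@dataclass
class CorrelationNetwork:
    """Undirected network of significant co-regulation edges.

    Every retained edge satisfies ``|r| >= r_min`` and ``p_adj < alpha``
    (BH-adjusted over the full pair universe).  Edges are stored once under
    the canonical lexicographic ordering of their endpoints.
    """

    edges: pd.DataFrame
    r_min: float = 0.95
    alpha: float = 0.01
    n_samples: int | None = None
    nodes: frozenset[str] | None = None

    def __post_init__(self) -> None:
        df = self.edges.copy()
        missing = [c for c in EDGE_COLUMNS if c not in df.columns]
        if missing:
            raise ValidationError(f"edge table missing columns: {missing}")
        df = df[EDGE_COLUMNS]
        if len(df):
            if (df["protein_a"] == df["protein_b"]).any():
                raise ValidationError("self-loops are not allowed")
            swap = df["protein_a"] > df["protein_b"]
            if swap.any():
                a = df.loc[swap, "protein_b"].copy()
                df.loc[swap, "protein_b"] = df.loc[swap, "protein_a"]
                df.loc[swap, "protein_a"] = a
            if df.duplicated(["protein_a", "protein_b"]).any():
                raise ValidationError("duplicate unordered edges")
            r = df["r"].to_numpy(float)
            if np.any(np.abs(r) > 1 + 1e-12):
                raise ValidationError("edge r outside [-1, 1]")
            expected_sign = np.where(r > 0, "positive", "negative")
            if not (df["sign"].to_numpy() == expected_sign).all():
                raise ValidationError("edge sign inconsistent with r")
        self.edges = df.reset_index(drop=True)
        endpoints = set(df["protein_a"]) | set(df["protein_b"])
        if self.nodes is None:
            self.nodes = frozenset(endpoints)
        else:
            self.nodes = frozenset(self.nodes)
            if not endpoints <= self.nodes:
                raise ValidationError("edge endpoints outside declared node set")

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    @property
    def n_positive(self) -> int:
        return int((self.edges["sign"] == "positive").sum())

    def signed(self, edge_sign: str = "positive") -> pd.DataFrame:
        """Edge subset by sign; ``edge_sign`` is 'positive', 'negative' or 'all'."""
        if edge_sign == "all":
            return self.edges
        if edge_sign not in ("positive", "negative"):
            raise ValueError("edge_sign must be 'positive', 'negative' or 'all'")
        return self.edges[self.edges["sign"] == edge_sign]

    def subset_nodes(self, keep: Iterable[str]) -> "CorrelationNetwork":
        """Restrict the network to a node subset; edges touching removed
        nodes are dropped."""
        keep = frozenset(keep)
        mask = self.edges["protein_a"].isin(keep) & self.edges["protein_b"].isin(keep)
        return CorrelationNetwork(
            self.edges[mask], self.r_min, self.alpha, self.n_samples,
            nodes=frozenset(self.nodes) & keep,
        )


@dataclass
class PhosphositeMatrix:
    """Phosphosite quantification plus site identity.

    ``sites`` is indexed by site ID (``PROTEIN_S123`` style) with columns
    ``protein``, ``residue`` (S/T/Y) and ``position``; each site maps to
    exactly one host protein.  ``protein_normalized`` records, per site,
    whether the host-protein log2 ratio has been subtracted.
    """

    values: pd.DataFrame
    samples: pd.DataFrame
    sites: pd.DataFrame
    scale: str = "log2_ratio"

    def __post_init__(self) -> None:
        if self.scale not in SCALES:
            raise ValidationError(f"scale must be one of {SCALES}")
        self.samples = validate_sample_sheet(self.samples)
        if self.values.index.has_duplicates:
            raise ValidationError("duplicate site IDs in value matrix")
        req = ["protein", "residue", "position"]
        missing = [c for c in req if c not in self.sites.columns]
        if missing:
            raise ValidationError(f"site table missing columns: {missing}")
        bad = set(self.values.index) - set(self.sites.index)
        if bad:
            raise ValidationError(f"sites without identity records: {sorted(bad)[:5]}")
        self.sites = self.sites.loc[list(self.values.index)].copy()
        if not self.sites["residue"].isin(RESIDUES).all():
            raise ValidationError("site residues must be S, T or Y")
        self.sites["position"] = self.sites["position"].astype(int)
        if (self.sites["position"] < 1).any():
            raise ValidationError("site positions must be positive")
        trip = self.sites[["protein", "residue", "position"]]
        if trip.duplicated().any():
            raise ValidationError("duplicate (protein, residue, position) sites")
        if "protein_normalized" not in self.sites.columns:
            self.sites["protein_normalized"] = False
        unknown = [c for c in self.values.columns if c not in self.samples.index]
        if unknown:
            raise ValidationError(f"samples absent from sample sheet: {unknown}")
        self.samples = self.samples.loc[list(self.values.columns)]
        self.values = self.values.astype(float)

    @property
    def site_ids(self) -> list[str]:
        return list(self.values.index)


def make_site_id(protein: str, residue: str, position: int) -> str:
    if residue not in RESIDUES:
        raise ValidationError(f"residue must be one of {RESIDUES}")
    return f"{protein}_{residue}{int(position)}"


def parse_site_id(site_id: str) -> tuple[str, str, int]:
    """Parse a ``PROTEIN_S123`` style site ID into (protein, residue, position)."""
    m = _SITE_ID_RE.match(site_id)
    if m is None:
        raise ValidationError(f"malformed site ID: {site_id!r}")
    return m.group("protein"), m.group("residue"), int(m.group("position"))


class OrthologyMap:
    """One-to-one mapping between human and mouse feature IDs.

    Bijectivity over its domain is enforced at construction.
    """

    def __init__(self, pairs: Mapping[str, str] | Iterable[tuple[str, str]]):
        items = list(pairs.items()) if isinstance(pairs, Mapping) else list(pairs)
        fwd: dict[str, str] = {}
        rev: dict[str, str] = {}
        for h, m in items:
            if h in fwd or m in rev:
                raise ValidationError(
                    f"orthology map is not one-to-one at ({h!r}, {m!r})"
                )
            fwd[h] = m
            rev[m] = h
        self.human_to_mouse = fwd
        self.mouse_to_human = rev

    def __len__(self) -> int:
        return len(self.human_to_mouse)

    def items(self):
        return self.human_to_mouse.items()
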