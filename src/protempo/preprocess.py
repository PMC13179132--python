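"""Normalization, cross-species merging and gene-set filtering.

These transformations run before any statistics: raw intensities are
converted to log2 ratios against each feature's per-group geometric mean,
the two species' matrices are merged over one-to-one orthologs
(complete-case), isoform accessions are trimmed to canonical ones, and
gene-set collections are filtered to sets with enough detected members.
"""

from __future__ import annotations

import logging
import re
from typing import Iterable

import numpy as np
import pandas as pd

from .datatypes import (
    GO_SOURCES,
    AbundanceMatrix,
    CorrelationNetwork,
    GeneSet,
    GeneSetCollection,
    OrthologyMap,
    ValidationError,
)

log = logging.getLogger(__name__)

_ISOFORM_SUFFIX = re.compile(r"-[0-9]+$")


def normalize_to_geometric_mean(
    matrix: AbundanceMatrix, group_by: str = "species"
) -> AbundanceMatrix:
    """Normalize each feature to its per-group geometric mean, log2 scale.

    For each feature and each group of samples (default grouping: species),
    ``value := log2(raw / geomean(raw over the group's samples))``, i.e. the
    log2 values are centred per feature within the group.  Zeros and negative
    raw values are treated as missing, and the geometric mean is taken over
    complete cases only: a feature with any missing value in a group is
    dropped from that group (all its group values set to missing, with a
    warning).  The returned matrix carries ``scale='log2_ratio'``.
    """
    if matrix.scale != "raw":
        raise ValidationError(
            "normalize_to_geometric_mean expects a raw-scale matrix; "
            f"got scale={matrix.scale!r} (refusing to normalize twice)"
        )
    if group_by not in matrix.samples.columns:
        raise ValidationError(f"unknown grouping column {group_by!r}")
    vals = matrix.values.to_numpy(float).copy()
    vals[vals <= 0] = np.nan  # zeros are non-detections, not true signal
    with np.errstate(invalid="ignore"):
        logv = np.log2(vals)
    out = np.full_like(logv, np.nan)
    groups = matrix.samples[group_by]
    for g in groups.unique():
        cols = np.flatnonzero((groups == g).to_numpy())
        block = logv[:, cols]
        complete = ~np.isnan(block).any(axis=1)
        n_dropped = int((~complete).sum())
        if n_dropped:
            log.warning(
                "group %r: dropping %d feature(s) with missing values", g, n_dropped
            )
        centred = block - block.mean(axis=1, keepdims=True)
        centred[~complete] = np.nan
        out[:, cols] = centred
    return AbundanceMatrix(
        pd.DataFrame(out, index=matrix.values.index, columns=matrix.values.columns),
        matrix.samples,
        scale="log2_ratio",
    )


def merge_by_orthology(
    human: AbundanceMatrix, mouse: AbundanceMatrix, omap: OrthologyMap
) -> AbundanceMatrix:
    """Merge species matrices over one-to-one orthologs (complete-case).

    Both inputs must already be per-species log2 ratios.  The merged matrix
    is indexed by the human feature ID; its columns are the union of both
    sample sets, and any feature with a missing value in any retained sample
    is dropped.
    """
    for m, name in ((human, "human"), (mouse, "mouse")):
        if m.scale != "log2_ratio":
            raise ValidationError(f"{name} matrix must be normalized (log2_ratio)")
    overlap = set(human.sample_ids) & set(mouse.sample_ids)
    if overlap:
        raise ValidationError(f"sample IDs shared across species: {sorted(overlap)}")
    rows = []
    index = []
    for h, m in omap.items():
        if h in human.values.index and m in mouse.values.index:
            rows.append(
                np.concatenate(
                    [human.values.loc[h].to_numpy(), mouse.values.loc[m].to_numpy()]
                )
            )
            index.append(h)
    cols = human.sample_ids + mouse.sample_ids
    merged = pd.DataFrame(
        np.array(rows).reshape(len(rows), len(cols)) if rows else
        np.empty((0, len(cols))),
        index=index, columns=cols,
    )
    merged = merged.dropna(axis=0, how="any")  # complete-case
    samples = pd.concat([human.samples, mouse.samples.drop(columns=[])])
    samples = samples.drop(columns=["sample_id"]).reset_index()
    return AbundanceMatrix(merged, samples, scale="log2_ratio")


def is_canonical(accession: str) -> bool:
    """True unless the accession carries an isoform suffix (``-<integer>``)."""
    return _ISOFORM_SUFFIX.search(accession) is None


def trim_to_canonical(obj):
    """Retain only canonical-isoform features.

    Accepts a feature iterable, an :class:`AbundanceMatrix` or a
    :class:`CorrelationNetwork`; edges touching removed nodes are removed.
    """
    if isinstance(obj, CorrelationNetwork):
        keep = {n for n in obj.nodes if is_canonical(n)}
        return obj.subset_nodes(keep)
    if isinstance(obj, AbundanceMatrix):
        return obj.subset_features([f for f in obj.features if is_canonical(f)])
    return [f for f in obj if is_canonical(f)]


def filter_gene_sets(
    collection: GeneSetCollection,
    detected: Iterable[str],
    min_detected: int = 3,
    max_go_size: int = 150,
) -> GeneSetCollection:
    """Filter sets to those with more than two detected members.

    Complexes, pathways and every other category are kept iff more than two
    members are detected (``min_detected`` defaults to 3, i.e. ">2").  GO
    sets additionally require a total set size of at most ``max_go_size``
    genes, avoiding overly broad terms.  Each retained set records its
    detected-member subset.
    """
    detected = frozenset(detected)
    kept: dict[str, GeneSet] = {}
    for gs in collection:
        det = gs.members & detected
        if len(det) < min_detected:
            continue
        if gs.source in GO_SOURCES and len(gs.members) > max_go_size:
            continue
        kept[gs.name] = GeneSet(gs.name, gs.members, gs.source, detected=det)
    return GeneSetCollection(kept)
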