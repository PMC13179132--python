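"""Stage-to-stage differential abundance, temporal clustering, enrichment.

Differentially abundant features (DAPs for proteins, DETs when applied to a
transcript matrix) are called between two stages with a two-sided two-sample
t-test across replicates, BH adjustment over all tested features, and the
double threshold |fold change| > 2 with adjusted p < 0.05.  Temporal
clustering cuts an average-linkage hierarchy over correlation distances of
z-scored stage-mean profiles.  Gene-set enrichment of a selection uses the
one-sided hypergeometric tail.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .datatypes import AbundanceMatrix, GeneSetCollection, ValidationError
from .stats import bh_adjust, hypergeom_tail, zscore_rows


def compute_daps(
    matrix: AbundanceMatrix,
    stage_a: str,
    stage_b: str,
    fc_threshold: float = 2.0,
    alpha: float = 0.05,
    equal_var: bool = True,
) -> pd.DataFrame:
    """Differential abundance between two stages.

    Fold change is ``log2(mean_b / mean_a)`` of linear-scale means for a raw
    matrix, or the difference of log2 means for a log2_ratio matrix.  The
    two-sided t-test runs across replicate values per stage (Student's by
    default; Welch via ``equal_var=False``), and BH adjusts over all tested
    features.  A feature is flagged ``is_dap`` iff
    ``|log2_fc| > log2(fc_threshold)`` and ``p_adj < alpha``.

    Features with missing values in either stage are excluded from testing.
    Antisymmetry holds by construction: swapping the stages negates the fold
    change and leaves p-values unchanged.
    """
    stages = matrix.samples["stage"].astype(str)
    cols_a = matrix.samples.index[stages == stage_a]
    cols_b = matrix.samples.index[stages == stage_b]
    for stage, cols in ((stage_a, cols_a), (stage_b, cols_b)):
        if len(cols) < 2:
            raise ValidationError(
                f"stage {stage!r} has {len(cols)} replicate(s); need >= 2"
            )
    xa = matrix.values[cols_a].to_numpy(float)
    xb = matrix.values[cols_b].to_numpy(float)
    complete = ~np.isnan(xa).any(axis=1) & ~np.isnan(xb).any(axis=1)

    if matrix.scale == "raw":
        with np.errstate(divide="ignore", invalid="ignore"):
            log2_fc = np.log2(xb.mean(axis=1) / xa.mean(axis=1))
        ta, tb = xa, xb
    else:
        log2_fc = xb.mean(axis=1) - xa.mean(axis=1)
        ta, tb = xa, xb
    t_res = sps.ttest_ind(tb, ta, axis=1, equal_var=equal_var)
    p_raw = np.asarray(t_res.pvalue, float)
    # identical values in both stages: zero variance makes t undefined -> p=1
    p_raw = np.where(np.isnan(p_raw) & complete, 1.0, p_raw)
    p_raw[~complete] = np.nan
    log2_fc = np.where(complete, log2_fc, np.nan)
    p_adj = bh_adjust(p_raw)
    out = pd.DataFrame({
        "feature": matrix.features,
        "log2_fc": log2_fc,
        "p_raw": p_raw,
        "p_adj": p_adj,
    })
    out["is_dap"] = (
        (np.abs(out["log2_fc"]) > np.log2(fc_threshold))
        & (out["p_adj"] < alpha)
    ).fillna(False)
    return out


def cluster_temporal(
    matrix: AbundanceMatrix,
    k: int = 10,
    metric: str = "correlation",
    linkage: str = "average",
) -> pd.Series:
    """Cut a hierarchy over per-feature stage-mean profiles into k clusters.

    Profiles are stage means (over replicates and groups) z-scored per
    feature; distances default to correlation distance (1 - r) with average
    linkage.  Constant profiles, whose correlation distance is undefined,
    are placed at maximal distance (2.0) from everything.  Deterministic
    given the input; the unordered partition is invariant to feature order.
    """
    if k > len(matrix.features):
        raise ValidationError(f"k={k} exceeds feature count {len(matrix.features)}")
    if k < 1:
        raise ValidationError("k must be >= 1")
    profiles = matrix.stage_means().to_numpy(float)
    if np.isnan(profiles).any():
        raise ValidationError("matrix must be complete over clustered samples")
    z = zscore_rows(profiles)
    if metric == "correlation":
        n = z.shape[1]
        zn = z / np.sqrt(np.maximum((z ** 2).sum(axis=1, keepdims=True), 1e-300))
        r = np.clip(zn @ zn.T, -1.0, 1.0)
        dist = 1.0 - r
        const = (z == 0).all(axis=1)
        dist[const, :] = 2.0
        dist[:, const] = 2.0
        np.fill_diagonal(dist, 0.0)
        condensed = squareform(dist, checks=False)
    else:
        from scipy.spatial.distance import pdist
        condensed = pdist(z, metric=metric)
    tree = hierarchy.linkage(condensed, method=linkage)
    labels = hierarchy.fcluster(tree, t=k, criterion="maxclust")
    return pd.Series(labels, index=matrix.features, name="cluster")


def hypergeometric_enrichment(
    selected: set[str],
    background: set[str],
    sets: GeneSetCollection,
) -> pd.DataFrame:
    """One-sided over-representation test of a selection against gene sets.

    For each set, the overlap with ``selected`` is scored by the upper
    hypergeometric tail P(X >= overlap) with the universe restricted to
    ``background``; BH adjusts across all tested sets.
    """
    selected = set(selected)
    background = set(background)
    if not selected <= background:
        raise ValidationError("selected features must be a subset of the background")
    rows = []
    for gs in sets:
        in_bg = gs.members & background
        overlap = in_bg & selected
        rows.append({
            "set": gs.name,
            "source": gs.source,
            "set_size": len(gs.members),
            "n_in_background": len(in_bg),
            "overlap": len(overlap),
        })
    df = pd.DataFrame(rows, columns=["set", "source", "set_size",
                                     "n_in_background", "overlap"])
    if len(df):
        df["p_raw"] = hypergeom_tail(
            df["overlap"].to_numpy(),
            len(background),
            df["n_in_background"].to_numpy(),
            len(selected),
        )
        df["p_adj"] = bh_adjust(df["p_raw"].to_numpy())
    else:
        df["p_raw"] = df["p_adj"] = np.nan
    return df
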