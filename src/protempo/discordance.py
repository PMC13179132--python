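"""RNA-protein correlation and discordance at gene, complex and stage level.

Discordance D is, per gene and stage, the log2-transformed ratio of the mean
protein fold change to the mean RNA fold change — equivalently ``protein_fc -
rna_fc`` with both fold changes in log2 against each assay's per-species
geometric-mean baseline.  D near 0 means RNA tracks protein; D >= 1 flags a
protein-abundant gene, D <= -1 an RNA-abundant one.  Replication may be
unbalanced between assays (e.g. 3 protein vs 2 RNA replicates): means are
taken within assay before the ratio.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats as sps

from .datatypes import AbundanceMatrix, GeneSetCollection, ValidationError
from .stats import bh_adjust, paired_pearson

log = logging.getLogger(__name__)


def counts_to_tpm(matrix: AbundanceMatrix, pseudocount: float = 1.0,
                  lengths: pd.Series | None = None) -> AbundanceMatrix:
    """Convert raw RNA counts to (length-normalized) transcripts per million.

    A pseudocount is added before scaling.  Without gene lengths the
    length-normalization step is skipped (counts per million of a synthetic
    or pre-normalized matrix).
    """
    if matrix.scale != "raw":
        raise ValidationError("counts_to_tpm expects a raw count matrix")
    x = matrix.values.to_numpy(float) + pseudocount
    if lengths is not None:
        lens = lengths.reindex(matrix.values.index).to_numpy(float)
        x = x / lens[:, None]
    tpm = x / x.sum(axis=0, keepdims=True) * 1e6
    return AbundanceMatrix(
        pd.DataFrame(tpm, index=matrix.values.index, columns=matrix.values.columns),
        matrix.samples, scale="raw",
    )


def _condition_means(matrix: AbundanceMatrix) -> pd.DataFrame:
    """Per-feature means over (cell line, stage) conditions.

    Columns are ``(cell_line, stage)`` tuples ordered by line then stage.
    """
    key = list(zip(matrix.samples["cell_line"], matrix.samples["stage"].astype(str)))
    means = matrix.values.T.groupby(pd.Series(key, index=matrix.values.columns)).mean().T
    return means


def per_gene_rna_protein_correlation(
    protein: AbundanceMatrix,
    rna: AbundanceMatrix,
) -> tuple[pd.Series, float]:
    """Pearson r per gene between paired protein and RNA condition means.

    Both matrices are reduced to per-(cell line, stage) condition means and
    paired on shared conditions; genes missing in either matrix are
    excluded.  Requires at least 3 paired conditions.  Returns the per-gene
    r series and the global mean r over defined values.
    """
    pm = _condition_means(protein)
    rm = _condition_means(rna)
    shared_conditions = [c for c in pm.columns if c in set(rm.columns)]
    if len(shared_conditions) < 3:
        raise ValidationError(
            f"only {len(shared_conditions)} paired condition(s); need >= 3"
        )
    genes = [g for g in pm.index if g in set(rm.index)]
    x = pm.loc[genes, shared_conditions].to_numpy(float)
    y = rm.loc[genes, shared_conditions].to_numpy(float)
    complete = ~np.isnan(x).any(axis=1) & ~np.isnan(y).any(axis=1)
    r = np.full(len(genes), np.nan)
    r[complete] = paired_pearson(x[complete], y[complete])
    series = pd.Series(r, index=genes, name="rna_protein_r")
    return series, float(np.nanmean(r))


def compute_discordance(
    protein: AbundanceMatrix,
    rna: AbundanceMatrix,
    threshold: float = 1.0,
) -> pd.DataFrame:
    """Per gene x stage discordance records.

    Both matrices must be log2 ratios against their per-species
    geometric-mean baseline (the same convention as the normalization step;
    RNA counts go through TPM + pseudocount first).  Per gene and stage,
    ``protein_fc`` and ``rna_fc`` are replicate means within assay, and
    ``discordance = protein_fc - rna_fc``.  Classification uses the
    configured threshold: ``protein_abundant`` (D >= threshold),
    ``rna_abundant`` (D <= -threshold), else ``concordant``.

    Genes present in only one assay are skipped; coverage counts are stored
    in ``result.attrs['coverage']``.
    """
    for m, name in ((protein, "protein"), (rna, "rna")):
        if m.scale != "log2_ratio":
            raise ValidationError(f"{name} matrix must be on the log2_ratio scale")
    p_stage = protein.values.T.groupby(protein.samples["stage"], observed=True).mean().T
    r_stage = rna.values.T.groupby(rna.samples["stage"], observed=True).mean().T
    stages = [s for s in p_stage.columns if s in set(r_stage.columns)]
    genes = [g for g in protein.values.index if g in set(rna.values.index)]
    records = []
    for stage in stages:
        pf = p_stage.loc[genes, stage]
        rf = r_stage.loc[genes, stage]
        d = pf - rf
        cls = np.where(d >= threshold, "protein_abundant",
                       np.where(d <= -threshold, "rna_abundant", "concordant"))
        cls = np.where(np.isnan(d), "missing", cls)
        records.append(pd.DataFrame({
            "gene": genes,
            "stage": stage,
            "protein_fc": pf.to_numpy(),
            "rna_fc": rf.to_numpy(),
            "discordance": d.to_numpy(),
            "class": cls,
        }))
    out = pd.concat(records, ignore_index=True) if records else pd.DataFrame(
        columns=["gene", "stage", "protein_fc", "rna_fc", "discordance", "class"]
    )
    out.attrs["coverage"] = {
        "n_protein_only": len(set(protein.values.index) - set(rna.values.index)),
        "n_rna_only": len(set(rna.values.index) - set(protein.values.index)),
        "n_shared": len(genes),
    }
    return out


def complex_discordance_summary(
    per_gene_r: pd.Series,
    records: pd.DataFrame,
    complexes: GeneSetCollection,
    min_detected: int = 3,
) -> pd.DataFrame:
    """Per-complex medians of RNA-protein correlation and discordance.

    Two statistics are reported per complex with more than two detected
    members: the median per-gene RNA-protein r across members, and the
    median per-stage discordance across members (one row per complex x
    stage for the latter, aggregated wide).  Complexes below the detection
    cutoff are excluded.
    """
    rows = []
    stages = list(records["stage"].unique()) if len(records) else []
    detected_r = set(per_gene_r.index)
    for gs in complexes:
        members = sorted((gs.detected if gs.detected is not None else gs.members)
                         & detected_r)
        if len(members) < min_detected:
            continue
        row = {
            "complex": gs.name,
            "n_members_detected": len(members),
            "median_rna_protein_r": float(per_gene_r.loc[members].median()),
        }
        sub = records[records["gene"].isin(members)]
        for stage in stages:
            vals = sub.loc[sub["stage"] == stage, "discordance"]
            row[f"median_discordance_{stage}"] = (
                float(vals.median()) if len(vals) else np.nan
            )
        rows.append(row)
    return pd.DataFrame(rows)


def stage_transition_discordance_test(
    protein: AbundanceMatrix,
    rna: AbundanceMatrix,
    complexes: GeneSetCollection,
    stage_a: str,
    stage_b: str,
    test: str = "paired_t",
    min_members: int = 3,
) -> pd.DataFrame:
    """Do a complex's protein and RNA fold changes differ across a transition?

    Per member of each complex, the stage_a -> stage_b log2 fold change is
    computed in each assay; the member-wise differences (protein FC - RNA
    FC) are tested against 0 with a two-sided paired t-test (or an unpaired
    two-sample t across the two FC sets with ``test='unpaired'``).  BH
    adjusts across complexes.  Complexes with fewer than ``min_members``
    members measured in both assays are skipped.
    """
    for m, name in ((protein, "protein"), (rna, "rna")):
        if m.scale != "log2_ratio":
            raise ValidationError(f"{name} matrix must be on the log2_ratio scale")
    if test not in ("paired_t", "unpaired"):
        raise ValidationError("test must be 'paired_t' or 'unpaired'")
    p_stage = protein.values.T.groupby(protein.samples["stage"], observed=True).mean().T
    r_stage = rna.values.T.groupby(rna.samples["stage"], observed=True).mean().T
    for stage in (stage_a, stage_b):
        if stage not in p_stage.columns or stage not in r_stage.columns:
            raise ValidationError(f"stage {stage!r} missing from one assay")
    p_fc = p_stage[stage_b] - p_stage[stage_a]
    r_fc = r_stage[stage_b] - r_stage[stage_a]
    rows = []
    for gs in complexes:
        members = sorted(
            (gs.detected if gs.detected is not None else gs.members)
            & set(p_fc.index) & set(r_fc.index)
        )
        members = [m for m in members
                   if np.isfinite(p_fc[m]) and np.isfinite(r_fc[m])]
        if len(members) < min_members:
            continue
        pv = p_fc.loc[members].to_numpy()
        rv = r_fc.loc[members].to_numpy()
        diffs = pv - rv
        if np.all(diffs == 0):
            # protein FC identical to RNA FC for every member: no evidence
            p_val = 1.0
        elif test == "paired_t":
            p_val = float(sps.ttest_rel(pv, rv).pvalue)
        else:
            p_val = float(sps.ttest_ind(pv, rv).pvalue)
        if np.isnan(p_val):  # zero-variance, non-zero shift: maximal evidence
            p_val = 0.0
        rows.append({
            "complex": gs.name,
            "n_members": len(members),
            "mean_protein_fc": float(pv.mean()),
            "mean_rna_fc": float(rv.mean()),
            "mean_diff": float(diffs.mean()),
            "p_raw": p_val,
        })
    out = pd.DataFrame(rows, columns=["complex", "n_members", "mean_protein_fc",
                                      "mean_rna_fc", "mean_diff", "p_raw"])
    if len(out):
        out["p_adj"] = bh_adjust(out["p_raw"].to_numpy())
    else:
        out["p_adj"] = np.nan
    return out


def tf_target_concordance(
    tf: str,
    protein: AbundanceMatrix,
    rna: AbundanceMatrix,
    tf_targets: GeneSetCollection,
    r_min: float = 0.9,
) -> pd.DataFrame:
    """Transcripts of annotated TF targets that track the TF's protein level.

    The TF's protein condition-mean profile is correlated against every
    annotated target's transcript profile over shared conditions; targets
    with ``r >= r_min`` are retained and labelled with their argmax stage
    (the stage of maximum mean transcript abundance).  Flat transcript
    profiles (undefined r) are excluded.
    """
    if tf not in protein.values.index:
        raise ValidationError(f"TF {tf!r} absent from the protein matrix")
    target_sets = [gs for gs in tf_targets if gs.name == tf]
    if not target_sets:
        raise ValidationError(f"no target set named {tf!r} in the collection")
    targets = sorted(target_sets[0].members & set(rna.values.index))
    pm = _condition_means(protein)
    rm = _condition_means(rna)
    shared_conditions = [c for c in pm.columns if c in set(rm.columns)]
    if len(shared_conditions) < 3:
        raise ValidationError("need >= 3 paired conditions")
    tf_profile = pm.loc[tf, shared_conditions].to_numpy(float)
    rows = []
    r_stage = rna.values.T.groupby(rna.samples["stage"], observed=True).mean().T
    for target in targets:
        y = rm.loc[target, shared_conditions].to_numpy(float)
        if np.isnan(y).any():
            continue
        r = float(paired_pearson(tf_profile[None, :], y[None, :])[0])
        if np.isnan(r) or r < r_min:
            continue
        stage_profile = r_stage.loc[target]
        rows.append({
            "tf": tf,
            "target": target,
            "r": r,
            "argmax_stage": str(stage_profile.idxmax()),
        })
    return pd.DataFrame(rows, columns=["tf", "target", "r", "argmax_stage"])


def stage_target_overlap(retained: pd.DataFrame) -> pd.DataFrame:
    """Pairwise overlap counts between stage-labelled target sets of one TF."""
    stages = sorted(retained["argmax_stage"].unique())
    sets = {s: set(retained.loc[retained["argmax_stage"] == s, "target"])
            for s in stages}
    rows = []
    for i, s1 in enumerate(stages):
        for s2 in stages[i:]:
            rows.append({
                "stage_a": s1, "stage_b": s2,
                "n_a": len(sets[s1]), "n_b": len(sets[s2]),
                "n_shared": len(sets[s1] & sets[s2]) if s1 != s2 else len(sets[s1]),
            })
    return pd.DataFrame(rows)
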