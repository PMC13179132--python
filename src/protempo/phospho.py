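"""Protein-normalized phosphosite dynamics and kinase activity inference.

Phosphosite log2 ratios are first corrected by subtracting the host
protein's log2 ratio per sample, isolating protein-independent
phosphorylation changes.  Kinase activities are scored by kinase-substrate
enrichment (KSEA): for a kinase with m mapped substrate sites,

    z = (mean(substrate values) - mean(all site values)) * sqrt(m) / sd(all)

with the sample (n-1) standard deviation and a minimum substrate cutoff
(default 2).  Kinase-substrate pairs whose profiles correlate at
|r| >= 0.5 form the kinase-substrate network.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .datatypes import (
    AbundanceMatrix,
    PhosphositeMatrix,
    ValidationError,
    make_site_id,
)
from .stats import paired_pearson

log = logging.getLogger(__name__)


def collapse_duplicate_sites(values: pd.DataFrame, sites: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Collapse multiple peptides mapping to one (protein, residue, position)
    by the per-sample median."""
    key = sites["protein"] + "_" + sites["residue"] + sites["position"].astype(str)
    collapsed = values.groupby(key).median()
    first = sites.copy()
    first.index = key
    first = first[~first.index.duplicated()]
    out_sites = first.loc[collapsed.index]
    collapsed.index.name = None
    out_sites.index.name = None
    return collapsed, out_sites


def protein_normalize_sites(
    sites: PhosphositeMatrix,
    proteins: AbundanceMatrix,
    sample_map: dict[str, str] | None = None,
) -> PhosphositeMatrix:
    """Subtract host-protein log2 ratios from site log2 ratios, per sample.

    ``sample_map`` maps site-matrix sample IDs to protein-matrix sample IDs
    when the two assays use distinct sheets; by default samples are matched
    by (cell line, stage, replicate).  Sites whose host protein is
    unquantified are retained unnormalized, with ``protein_normalized``
    False.  A sample present in the site matrix but with no protein
    counterpart is an error.
    """
    if sites.scale != "log2_ratio" or proteins.scale != "log2_ratio":
        raise ValidationError("both matrices must be on the log2_ratio scale")
    if sample_map is None:
        prot_key = {
            (row["cell_line"], str(row["stage"]), row["replicate"]): sid
            for sid, row in proteins.samples.iterrows()
        }
        sample_map = {}
        for sid, row in sites.samples.iterrows():
            key = (row["cell_line"], str(row["stage"]), row["replicate"])
            if key not in prot_key:
                raise ValidationError(
                    f"site sample {sid!r} has no protein counterpart {key}"
                )
            sample_map[sid] = prot_key[key]
    missing_cols = [s for s in sites.values.columns if s not in sample_map]
    if missing_cols:
        raise ValidationError(f"sample-axis mismatch: {missing_cols}")
    prot_aligned = proteins.values[[sample_map[s] for s in sites.values.columns]]
    prot_aligned.columns = sites.values.columns

    hosts = sites.sites["protein"]
    quantified = hosts.isin(proteins.values.index)
    out = sites.values.copy()
    host_vals = prot_aligned.reindex(hosts[quantified].to_numpy()).to_numpy()
    out.loc[quantified] = out.loc[quantified].to_numpy() - host_vals
    n_flagged = int((~quantified).sum())
    if n_flagged:
        log.warning("%d site(s) retained unnormalized (host unquantified)",
                    n_flagged)
    site_table = sites.sites.copy()
    site_table["protein_normalized"] = quantified.to_numpy()
    return PhosphositeMatrix(out, sites.samples, site_table, scale="log2_ratio")


def center_rows(sites: PhosphositeMatrix) -> PhosphositeMatrix:
    """Subtract each site's row mean across all samples (log2 fold change to
    the row mean)."""
    vals = sites.values.sub(sites.values.mean(axis=1), axis=0)
    return PhosphositeMatrix(vals, sites.samples, sites.sites, scale="log2_ratio")


def _kinase_site_map(
    ks_map: pd.DataFrame, site_ids: set[str]
) -> dict[str, list[str]]:
    """Resolve the kinase-substrate table against the measured sites."""
    mapping: dict[str, list[str]] = {}
    for kinase, sub in ks_map.groupby("kinase"):
        ids = [
            make_site_id(p, r, int(pos))
            for p, r, pos in zip(sub["substrate"], sub["residue"], sub["position"])
        ]
        present = sorted(set(i for i in ids if i in site_ids))
        if present:
            mapping[str(kinase)] = present
    return mapping


def ksea_zscores(
    sites: PhosphositeMatrix,
    ks_map: pd.DataFrame,
    min_substrates: int = 2,
    contrasts: list[tuple[str, str]] | None = None,
) -> pd.DataFrame:
    """KSEA z-scores per kinase, per sample (or per stage contrast).

    Input site values should be protein-normalized log2 ratios centred to
    the row mean (see :func:`protein_normalize_sites` and
    :func:`center_rows`).  For each column — a sample, or with
    ``contrasts`` the mean difference between two stages — and each kinase
    with at least ``min_substrates`` mapped sites present:

        z = (substrate mean - mean of all sites) * sqrt(m) / sd(all sites)

    with the n-1 standard deviation over all measured site values in that
    column.  Kinases below the cutoff are omitted.  Returns kinases x
    columns with ``n_substrates`` as the first column.
    """
    if sites.values.empty:
        raise ValidationError("empty site matrix")
    vals = sites.values
    if contrasts is not None:
        stage = sites.samples["stage"].astype(str)
        cols = {}
        for a, b in contrasts:
            ca = vals.loc[:, (stage == a).to_numpy()]
            cb = vals.loc[:, (stage == b).to_numpy()]
            if ca.empty or cb.empty:
                raise ValidationError(f"contrast ({a}, {b}): stage missing")
            cols[f"{b}_vs_{a}"] = cb.mean(axis=1) - ca.mean(axis=1)
        vals = pd.DataFrame(cols)
    mapping = _kinase_site_map(ks_map, set(vals.index))
    kinases = [k for k, ids in sorted(mapping.items())
               if len(ids) >= min_substrates]
    rows = []
    arr = vals.to_numpy(float)
    col_mean = np.nanmean(arr, axis=0)
    col_sd = np.nanstd(arr, axis=0, ddof=1)
    for k in kinases:
        idx = [vals.index.get_loc(i) for i in mapping[k]]
        m = len(idx)
        sub_mean = np.nanmean(arr[idx], axis=0)
        with np.errstate(divide="ignore", invalid="ignore"):
            z = (sub_mean - col_mean) * np.sqrt(m) / col_sd
        rows.append([k, m, *z])
    out = pd.DataFrame(rows, columns=["kinase", "n_substrates", *vals.columns])
    return out.set_index("kinase")


def kinase_substrate_network(
    kinase_profiles: AbundanceMatrix,
    sites: PhosphositeMatrix,
    ks_map: pd.DataFrame,
    r_min: float = 0.5,
    sample_map: dict[str, str] | None = None,
) -> pd.DataFrame:
    """Correlation network over annotated kinase-substrate pairs.

    The kinase profile defaults to its protein abundance row (a per-contrast
    KSEA z-series can be supplied instead as an AbundanceMatrix).  Each
    annotated pair with both sides measured is correlated across matched
    samples; pairs with |r| >= r_min are retained with their sign.  Pairs
    with a constant profile on either side are dropped (undefined r).
    """
    if sample_map is None:
        prot_key = {
            (row["cell_line"], str(row["stage"]), row["replicate"]): sid
            for sid, row in kinase_profiles.samples.iterrows()
        }
        sample_map = {}
        for sid, row in sites.samples.iterrows():
            key = (row["cell_line"], str(row["stage"]), row["replicate"])
            if key in prot_key:
                sample_map[sid] = prot_key[key]
    shared = [s for s in sites.values.columns if s in sample_map]
    if len(shared) < 3:
        raise ValidationError("need >= 3 matched samples")
    site_vals = sites.values[shared]
    kin_vals = kinase_profiles.values[[sample_map[s] for s in shared]]
    mapping = _kinase_site_map(ks_map, set(site_vals.index))
    rows = []
    for kinase, site_ids in sorted(mapping.items()):
        if kinase not in kin_vals.index:
            continue
        kp = kin_vals.loc[kinase].to_numpy(float)
        if np.isnan(kp).any() or np.std(kp) == 0:
            continue
        for sid in site_ids:
            sp = site_vals.loc[sid].to_numpy(float)
            if np.isnan(sp).any() or np.std(sp) == 0:
                continue
            r = float(paired_pearson(kp[None, :], sp[None, :])[0])
            if abs(r) >= r_min:
                rows.append({
                    "kinase": kinase, "site": sid, "r": r,
                    "sign": "positive" if r > 0 else "negative",
                })
    return pd.DataFrame(rows, columns=["kinase", "site", "r", "sign"])


def site_protein_correlation(
    sites: PhosphositeMatrix,
    proteins: AbundanceMatrix,
    sample_map: dict[str, str] | None = None,
) -> tuple[pd.Series, float]:
    """Per-site Pearson r between un-normalized site and host protein.

    Returns the per-site r (NaN where the host is unquantified or either
    profile is constant) and the median over defined values.
    """
    if sample_map is None:
        prot_key = {
            (row["cell_line"], str(row["stage"]), row["replicate"]): sid
            for sid, row in proteins.samples.iterrows()
        }
        sample_map = {
            sid: prot_key[(row["cell_line"], str(row["stage"]), row["replicate"])]
            for sid, row in sites.samples.iterrows()
            if (row["cell_line"], str(row["stage"]), row["replicate"]) in prot_key
        }
    shared = [s for s in sites.values.columns if s in sample_map]
    site_vals = sites.values[shared].to_numpy(float)
    hosts = sites.sites["protein"]
    prot_aligned = proteins.values[[sample_map[s] for s in shared]]
    r = np.full(len(sites.values), np.nan)
    quantified = hosts.isin(proteins.values.index).to_numpy()
    host_vals = prot_aligned.reindex(hosts[quantified].to_numpy()).to_numpy(float)
    r[quantified] = paired_pearson(site_vals[quantified], host_vals)
    series = pd.Series(r, index=sites.values.index, name="site_protein_r")
    return series, float(np.nanmedian(r))
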