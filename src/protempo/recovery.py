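"""Parameter-recovery sweep on the default synthetic conditions.

Runs the full pipeline — generation, normalization, network construction,
cooperativity, discordance, KSEA — over independent seeds and measures how
completely the planted structure is recovered: within-module edge recall at
the |r| >= 0.95 / BH p < 0.01 gate, satellite significance and rank,
cross-module contamination of the top edges, background false positives,
discordance-offset RMSE, and the planted kinase's KSEA rank.
"""

from __future__ import annotations

import numpy as np

from . import cooperativity, discordance, network, phospho, preprocess, simulate


def run_seed(seed: int, offset_rng: np.random.Generator) -> dict:
    """One full-pipeline recovery run at the default study conditions."""
    cfg0 = simulate.SyntheticConfig(seed=seed)
    # plant zero-sum discordance offsets on 30 background genes
    offsets: dict[tuple[str, str], float] = {}
    for i in range(1, 31):
        v = offset_rng.normal(0.0, 1.0, cfg0.n_stages)
        v -= v.mean()
        for stage, off in zip(cfg0.stage_names, v):
            offsets[(f"BG_P{i:03d}", stage)] = off
    cfg = simulate.SyntheticConfig(seed=seed, discordance_offsets=offsets)

    prot, truth = simulate.generate_proteome(cfg)
    rna = simulate.generate_transcriptome(cfg, truth)
    sites, truth = simulate.generate_phosphoproteome(cfg, truth)
    norm = preprocess.normalize_to_geometric_mean(prot)
    net = network.correlation_network(norm)

    # within-module edge recall
    pairs = truth.within_module_pairs()
    edges = {frozenset((a, b))
             for a, b in zip(net.edges["protein_a"], net.edges["protein_b"])}
    recall = len(pairs & edges) / len(pairs)

    # cross-module contamination among the top |truth| positive edges
    pos = (net.edges[net.edges["sign"] == "positive"]
           .assign(abs_r=lambda d: d["r"].abs())
           .sort_values(["p_adj", "abs_r"], ascending=[True, False])
           .head(len(pairs)))
    module_of = {g: m for m, gs in truth.module_members.items() for g in gs}
    cross = sum(
        1 for a, b in zip(pos["protein_a"], pos["protein_b"])
        if a in module_of and b in module_of and module_of[a] != module_of[b]
    )

    # cooperativity: satellite rank / significance, background significance
    res = cooperativity.cooperative_proteins(net, truth.module_gmt())
    sat_rank_one = True
    sat_significant = True
    for module, sats in truth.satellites.items():
        sub = res[res["module"] == module].reset_index(drop=True)
        for sat in sats:
            rank = int(sub.index[sub["candidate"] == sat][0]) + 1
            sat_rank_one &= rank == 1
            sat_significant &= bool(
                sub.loc[sub["candidate"] == sat, "significant"].all())
    background = res[res["candidate"].str.startswith(("BG_", "BGC"))]
    bg_sig_rate = float(background["significant"].mean()) if len(background) else 0.0

    # discordance-offset recovery (synthetic RNA is abundance-scale: no TPM)
    rnorm = preprocess.normalize_to_geometric_mean(rna)
    records = discordance.compute_discordance(norm, rnorm)
    est = records.pivot(index="gene", columns="stage", values="discordance")
    tr = truth.discordance
    diff = (est.loc[tr.index, tr.columns] - tr).to_numpy()
    rmse = float(np.sqrt(np.nanmean(diff ** 2)))

    # KSEA: planted active kinase vs the null kinase
    normalized = phospho.protein_normalize_sites(sites, norm)
    centred = phospho.center_rows(normalized)
    ks = simulate.kinase_substrate_table(truth)
    z = phospho.ksea_zscores(
        centred, ks, contrasts=[(cfg.stage_names[0], cfg.stage_names[-1])])
    contrast = [c for c in z.columns if c != "n_substrates"][0]
    kinase_rank_one = bool(z[contrast].idxmax() == "KIN_ACTIVE")

    return {
        "recall": recall,
        "cross_module_top_edges": cross,
        "satellites_rank_one": sat_rank_one,
        "satellites_significant": sat_significant,
        "background_significant_rate": bg_sig_rate,
        "discordance_rmse": rmse,
        "kinase_rank_one": kinase_rank_one,
    }


def recovery_sweep(n_seeds: int = 20, base_seed: int = 0) -> dict:
    """Aggregate recovery metrics over ``n_seeds`` independent datasets."""
    offset_rng = np.random.default_rng((base_seed + 1) * 1_000_003 % (2 ** 31))
    runs = [run_seed((base_seed + k) % (2 ** 31), offset_rng)
            for k in range(n_seeds)]
    return {
        "n_seeds": n_seeds,
        "edge_recall_pooled": float(np.mean([r["recall"] for r in runs])),
        "edge_recall_min": float(min(r["recall"] for r in runs)),
        "cross_module_top_edges_total": int(
            sum(r["cross_module_top_edges"] for r in runs)),
        "satellite_rank_one_fraction": float(
            np.mean([r["satellites_rank_one"] for r in runs])),
        "satellite_significant_fraction": float(
            np.mean([r["satellites_significant"] for r in runs])),
        "background_significant_rate_max": float(
            max(r["background_significant_rate"] for r in runs)),
        "discordance_rmse_mean": float(
            np.mean([r["discordance_rmse"] for r in runs])),
        "discordance_rmse_max": float(
            max(r["discordance_rmse"] for r in runs)),
        "kinase_rank_one_fraction": float(
            np.mean([r["kinase_rank_one"] for r in runs])),
    }
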