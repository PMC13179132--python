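# protempo

Temporal multi-omics co-regulation analysis for stage-resolved differentiation
studies — the kind of design used to profile proteins, transcripts and
phosphosites across stem-cell-derived embryo models (gastruloids) at a handful
of developmental stages in replicate, across cell lines and species.

`protempo` is aimed at computational biologists who have feature-by-sample
abundance matrices (TMT reporter intensities, RNA counts, phosphosite ratios)
plus gene-set resources (CORUM/ComplexPortal-style complexes, pathways, GO,
kinase–substrate tables) and want to:

1. **Build a protein co-regulation network.** Each protein's abundance is
   normalized to its per-species geometric mean (log2 ratios), Pearson
   *r* is computed over all C(*n*, 2) unordered protein pairs (blocked, so
   ~6,300 proteins / 19.6 M pairs fit in ordinary memory), two-sided p-values
   come from the *t* transform of *r* with *n* − 2 df, and edges are kept at
   |*r*| ≥ 0.95 with Benjamini–Hochberg adjusted *p* < 0.01 over the **full**
   pair universe. A permutation null (each protein's samples shuffled
   independently; 50,000 random pairs × 10 shuffles) is produced as a
   diagnostic distribution and empirical-FDR estimate.
2. **Detect cooperative proteins.** For a candidate protein and a known
   module (complex or pathway with ≥3 detected subunits), the network's edge
   set is partitioned into a 2×2 table — edges candidate↔module (*a*), edges
   touching the module but not the candidate (*b*), edges touching the
   candidate but not the module (*c*), and the rest (*d*); *a*+*b*+*c*+*d* =
   |E| always — and scored with a one-sided Fisher exact test, BH-adjusted
   over all (candidate, module) pairs. Withheld-member validation and Jaccard
   overlap of cooperative sets between modules are built in.
3. **Quantify RNA–protein discordance.** Per gene and stage,
   *D* = protein log2 fold change − RNA log2 fold change (both against the
   per-assay geometric-mean baseline); *D* ≥ 1 flags protein-abundant genes,
   *D* ≤ −1 RNA-abundant ones. Per-gene RNA–protein correlation, per-complex
   medians, paired stage-transition tests and TF-target concordance
   (transcripts tracking a TF's protein at *r* ≥ 0.9) are included.
4. **Infer kinase activities.** Phosphosite log2 ratios are corrected by
   subtracting the host protein's log2 ratio, then scored by
   kinase–substrate enrichment: *z* = (s̄ − p̄)·√m / δ, with s̄ the mean of a
   kinase's *m* ≥ 2 mapped substrate sites, p̄ and δ the mean and (n−1) sd of
   all site values. Kinase–substrate pairs with |*r*| ≥ 0.5 form a
   kinase–substrate network.

A first-class synthetic-data generator plants all of this structure —
co-regulated modules, anticorrelated module pairs, cooperative satellites,
per-gene discordance offsets, kinase-driven phosphosite programs — with
recorded ground truth, so every stage of the pipeline has a recoverable
target and the whole pipeline is testable end to end.

## Worked example

```sh
protempo simulate --seed 3 --out-dir demo
protempo normalize --matrix demo/protein.tsv --samples demo/protein_samples.tsv --out-dir demo
protempo network --matrix demo/normalized.tsv --samples demo/protein_samples.tsv \
    --null-pairs 200 --null-shuffles 2 --seed 1 --out-dir demo
protempo cooperativity --edges demo/edges.tsv --modules demo/modules.gmt --out-dir demo
```

The `network` step prints the summary JSON, e.g. (seed 3):

```json
{
  "n_nodes": 108,
  "n_connected_nodes": 81,
  "n_edges": 445,
  "n_positive": 282,
  "n_negative": 163,
  "pct_positive": 63.37078651685393,
  "mean_degree": 8.24074074074074,
  "sd_degree": 7.387264278836735,
  "empirical_fdr_at_r_min": 0.0
}
```

108 simulated proteins; 445 edges pass |r| ≥ 0.95 & BH p < 0.01, 63% of them
positive (the two planted 10-protein modules are anticorrelated with each
other, contributing the negative cross-module edges; background clusters add
positive structure), and no permuted pair reaches the r gate (empirical FDR
0). The `cooperativity` step then reports the planted satellite of each
module as its top-ranked significant cooperative protein:

```
2 significant hits -> demo/cooperativity.tsv
candidate          module       a  b   c  d    p_raw     p_adj     significant
module_down_SAT01  module_down  10 41  0  231  1.71e-08  2.43e-06  True
module_up_SAT01    module_up    10 45  0  227  3.92e-08  2.78e-06  True
```

Each satellite is linked to all 10 members of its module (*a* = 10) and to
nothing else (*c* = 0), exactly as planted.

The same operations are importable as a library (`protempo.network`,
`protempo.cooperativity`, `protempo.discordance`, `protempo.phospho`, ...),
and every threshold above is a config default that can be overridden per
call or via `--config` YAML.

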