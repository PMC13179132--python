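"""Shared fixtures: small hand-checkable matrices and a default synthetic run."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from protempo import preprocess, simulate

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")
from protempo.datatypes import AbundanceMatrix


def make_sheet(n_stages=3, n_reps=3, n_groups=1, assay="protein",
               stages=("primed", "early", "late"), species="synthetic"):
    rows = []
    for g in range(1, n_groups + 1):
        for stage in stages[:n_stages]:
            for rep in range(1, n_reps + 1):
                rows.append({
                    "sample_id": f"{assay}_g{g}_{stage}_r{rep}",
                    "species": species,
                    "cell_line": f"line{g}",
                    "stage": stage,
                    "replicate": rep,
                    "assay": assay,
                })
    return pd.DataFrame(rows)


def make_matrix(values: np.ndarray, features=None, scale="raw", **sheet_kwargs):
    sheet = make_sheet(**sheet_kwargs)
    features = features or [f"P{i + 1:03d}" for i in range(values.shape[0])]
    return AbundanceMatrix(
        pd.DataFrame(values, index=features, columns=sheet["sample_id"].tolist()),
        sheet, scale=scale,
    )


@pytest.fixture(scope="session")
def default_run():
    """One default synthetic dataset, generated once, with its normalized
    proteome and co-regulation network."""
    from protempo import network

    cfg = simulate.SyntheticConfig(seed=7)
    prot, truth = simulate.generate_proteome(cfg)
    rna = simulate.generate_transcriptome(cfg, truth)
    sites, truth = simulate.generate_phosphoproteome(cfg, truth)
    norm = preprocess.normalize_to_geometric_mean(prot)
    net = network.correlation_network(norm)
    return {
        "cfg": cfg, "proteome": prot, "rna": rna, "sites": sites,
        "truth": truth, "norm": norm, "net": net,
    }
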