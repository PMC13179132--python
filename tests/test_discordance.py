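"""RNA-protein correlation, discordance records, complex and stage tests."""

import numpy as np
import pandas as pd
import pytest

from protempo import discordance, preprocess, simulate
from protempo.datatypes import (
    AbundanceMatrix,
    GeneSet,
    GeneSetCollection,
    ValidationError,
)
from protempo.simulate import ModuleSpec, SyntheticConfig

from conftest import make_matrix, make_sheet


def _assay_matrix(features, values, assay, n_reps, scale="log2_ratio",
                  n_groups=1):
    sheet = make_sheet(n_stages=3, n_reps=n_reps, n_groups=n_groups,
                       assay=assay)
    return AbundanceMatrix(
        pd.DataFrame(values, index=features, columns=sheet["sample_id"].tolist()),
        sheet, scale=scale,
    )


class TestPerGeneCorrelation:
    def test_identical_profiles_r_one(self):
        prof = np.array([0.0, 1.0, 2.0])
        prot = _assay_matrix(["G1"], np.repeat(prof, 3)[None, :], "protein", 3)
        rna = _assay_matrix(["G1"], np.repeat(prof, 2)[None, :], "rna", 2)
        r, mean_r = discordance.per_gene_rna_protein_correlation(prot, rna)
        assert r["G1"] == pytest.approx(1.0)
        assert mean_r == pytest.approx(1.0)

    def test_negated_profile_r_minus_one(self):
        prof = np.array([0.0, 1.0, 2.0])
        prot = _assay_matrix(["G1"], np.repeat(prof, 3)[None, :], "protein", 3)
        rna = _assay_matrix(["G1"], np.repeat(-prof, 2)[None, :], "rna", 2)
        r, _ = discordance.per_gene_rna_protein_correlation(prot, rna)
        assert r["G1"] == pytest.approx(-1.0)

    def test_matches_direct_formula_on_toy_genes(self):
        rng = np.random.default_rng(0)
        genes = [f"G{i}" for i in range(5)]
        pv = rng.normal(size=(5, 9))
        rv = rng.normal(size=(5, 6))
        prot = _assay_matrix(genes, pv, "protein", 3)
        rna = _assay_matrix(genes, rv, "rna", 2)
        r, _ = discordance.per_gene_rna_protein_correlation(prot, rna)
        for i, g in enumerate(genes):
            pm = pv[i].reshape(3, 3).mean(axis=1)
            rm = rv[i].reshape(3, 2).mean(axis=1)
            naive = np.corrcoef(pm, rm)[0, 1]
            assert r[g] == pytest.approx(naive, abs=1e-12)

    def test_too_few_conditions_rejected(self):
        sheet_kwargs = dict(n_stages=2, n_reps=2, stages=("primed", "early"))
        prot = make_matrix(np.ones((1, 4)), scale="log2_ratio", **sheet_kwargs)
        rna = make_matrix(np.ones((1, 4)), scale="log2_ratio", **sheet_kwargs)
        with pytest.raises(ValidationError):
            discordance.per_gene_rna_protein_correlation(prot, rna)


class TestComputeDiscordance:
    def test_equal_fold_changes_concordant(self):
        vals = np.repeat([1.7, 0.3, -2.0], 3)[None, :]
        prot = _assay_matrix(["G1"], vals, "protein", 3)
        rna = _assay_matrix(["G1"], np.repeat([1.7, 0.3, -2.0], 2)[None, :],
                            "rna", 2)
        rec = discordance.compute_discordance(prot, rna)
        assert (rec["discordance"] == 0).all()
        assert (rec["class"] == "concordant").all()

    def test_threshold_classification(self):
        prot = _assay_matrix(["G1"], np.repeat([2.0, 0.0, -2.0], 3)[None, :],
                             "protein", 3)
        rna = _assay_matrix(["G1"], np.repeat([0.0, 0.0, 0.0], 2)[None, :],
                            "rna", 2)
        rec = discordance.compute_discordance(prot, rna).set_index("stage")
        assert rec.loc["primed", "discordance"] == pytest.approx(2.0)
        assert rec.loc["primed", "class"] == "protein_abundant"
        assert rec.loc["late", "class"] == "rna_abundant"
        assert rec.loc["early", "class"] == "concordant"

    def test_antisymmetric_under_assay_exchange(self):
        rng = np.random.default_rng(1)
        genes = [f"G{i}" for i in range(4)]
        prot = _assay_matrix(genes, rng.normal(size=(4, 9)), "protein", 3)
        rna = _assay_matrix(genes, rng.normal(size=(4, 9)), "protein", 3)
        fwd = discordance.compute_discordance(prot, rna)
        rev = discordance.compute_discordance(rna, prot)
        np.testing.assert_allclose(fwd["discordance"], -rev["discordance"],
                                   atol=1e-12)

    def test_gene_missing_from_one_assay_counted_in_coverage(self):
        prot = _assay_matrix(["G1", "G2"], np.zeros((2, 9)), "protein", 3)
        rna = _assay_matrix(["G1"], np.zeros((1, 6)), "rna", 2)
        rec = discordance.compute_discordance(prot, rna)
        assert set(rec["gene"]) == {"G1"}
        assert rec.attrs["coverage"]["n_protein_only"] == 1

    def test_planted_offset_recovered_exactly_noiseless(self):
        cfg = SyntheticConfig(
            modules=[ModuleSpec("m", 3, (0.0, 1.0, 2.0), 0.0)],
            anticorrelated_pairs=[], cooperative=[],
            n_background=5, n_background_clusters=0,
            replicate_sd=0.0, rna_sd=0.0,
            discordance_offsets={("BG_P001", "primed"): 2.0,
                                 ("BG_P001", "early"): -2.0},
            seed=0)
        prot, truth = simulate.generate_proteome(cfg)
        rna = simulate.generate_transcriptome(cfg, truth)
        pnorm = preprocess.normalize_to_geometric_mean(prot)
        rnorm = preprocess.normalize_to_geometric_mean(rna)
        rec = discordance.compute_discordance(pnorm, rnorm)
        est = rec.pivot(index="gene", columns="stage", values="discordance")
        np.testing.assert_allclose(
            est.loc["BG_P001", ["primed", "early", "late"]],
            [2.0, -2.0, 0.0], atol=1e-9)

    def test_offset_recovery_rmse_under_noise(self):
        """Planted zero-sum offsets recovered with RMSE well under 0.3 log2
        units at 0.1 noise (spec-level recovery bound, single seed here; the
        20-seed sweep lives in the acceptance suite)."""
        rng = np.random.default_rng(2)
        cfg0 = SyntheticConfig(seed=0)
        offsets = {}
        for i in range(1, 31):
            v = rng.normal(0, 1, 3)
            v -= v.mean()
            for s, off in zip(cfg0.stage_names, v):
                offsets[(f"BG_P{i:03d}", s)] = off
        cfg = SyntheticConfig(seed=0, discordance_offsets=offsets)
        prot, truth = simulate.generate_proteome(cfg)
        rna = simulate.generate_transcriptome(cfg, truth)
        pnorm = preprocess.normalize_to_geometric_mean(prot)
        rnorm = preprocess.normalize_to_geometric_mean(rna)
        rec = discordance.compute_discordance(pnorm, rnorm)
        est = rec.pivot(index="gene", columns="stage", values="discordance")
        diff = (est.loc[truth.discordance.index, truth.discordance.columns]
                - truth.discordance).to_numpy()
        assert np.sqrt(np.nanmean(diff ** 2)) < 0.3


class TestComplexSummaries:
    def _complexes(self, **sets):
        return GeneSetCollection({
            n: GeneSet(n, frozenset(m), "complex") for n, m in sets.items()
        })

    def test_median_r_of_three(self):
        r = pd.Series({"A": 0.1, "B": 0.5, "C": 0.9})
        rec = pd.DataFrame(columns=["gene", "stage", "discordance"])
        out = discordance.complex_discordance_summary(
            r, rec, self._complexes(cpx={"A", "B", "C"}))
        assert out.loc[0, "median_rna_protein_r"] == pytest.approx(0.5)

    def test_two_member_complex_excluded(self):
        r = pd.Series({"A": 0.1, "B": 0.5})
        rec = pd.DataFrame(columns=["gene", "stage", "discordance"])
        out = discordance.complex_discordance_summary(
            r, rec, self._complexes(cpx={"A", "B"}))
        assert len(out) == 0

    def test_median_matches_sort_oracle(self):
        rng = np.random.default_rng(3)
        genes = [f"G{i}" for i in range(9)]
        r = pd.Series(rng.uniform(-1, 1, 9), index=genes)
        out = discordance.complex_discordance_summary(
            r, pd.DataFrame(columns=["gene", "stage", "discordance"]),
            self._complexes(cpx=set(genes[:7])))
        vals = sorted(r[genes[:7]])
        assert out.loc[0, "median_rna_protein_r"] == pytest.approx(vals[3])


class TestStageTransitionTest:
    def _complexes(self, members):
        return GeneSetCollection({
            "cpx": GeneSet("cpx", frozenset(members), "complex")
        })

    def test_equal_fold_changes_not_significant(self):
        genes = [f"G{i}" for i in range(5)]
        vals = np.tile(np.repeat([0.0, 1.0, 2.0], 3), (5, 1))
        prot = _assay_matrix(genes, vals, "protein", 3)
        rna = _assay_matrix(genes, np.tile(np.repeat([0.0, 1.0, 2.0], 2),
                                           (5, 1)), "rna", 2)
        out = discordance.stage_transition_discordance_test(
            prot, rna, self._complexes(genes), "early", "late")
        assert out.loc[0, "p_raw"] == pytest.approx(1.0)

    def test_planted_complex_offset_significant(self):
        rng = np.random.default_rng(4)
        genes = [f"G{i}" for i in range(8)]
        base = np.tile(np.repeat([0.0, 1.0, 2.0], 3), (8, 1))
        # protein FC early->late exceeds RNA FC by 2 log2 units per member
        prot_vals = base + rng.normal(0, 0.05, base.shape)
        rna_base = np.tile(np.repeat([0.0, 1.0, 0.0], 2), (8, 1))
        rna_vals = rna_base + rng.normal(0, 0.05, rna_base.shape)
        prot = _assay_matrix(genes, prot_vals, "protein", 3)
        rna = _assay_matrix(genes, rna_vals, "rna", 2)
        out = discordance.stage_transition_discordance_test(
            prot, rna, self._complexes(genes), "early", "late")
        assert out.loc[0, "p_adj"] < 0.05
        assert out.loc[0, "mean_diff"] == pytest.approx(2.0, abs=0.1)

    def test_swapping_assays_flips_sign_keeps_p(self):
        rng = np.random.default_rng(5)
        genes = [f"G{i}" for i in range(6)]
        prot = _assay_matrix(genes, rng.normal(size=(6, 9)), "protein", 3)
        rna = _assay_matrix(genes, rng.normal(size=(6, 9)), "protein", 3)
        fwd = discordance.stage_transition_discordance_test(
            prot, rna, self._complexes(genes), "primed", "late")
        rev = discordance.stage_transition_discordance_test(
            rna, prot, self._complexes(genes), "primed", "late")
        assert fwd.loc[0, "mean_diff"] == pytest.approx(-rev.loc[0, "mean_diff"])
        assert fwd.loc[0, "p_raw"] == pytest.approx(rev.loc[0, "p_raw"])

    def test_type_one_error_controlled_under_null(self):
        """No planted offset: the paired test rejects at ~nominal rate."""
        rng = np.random.default_rng(6)
        genes = [f"G{i}" for i in range(8)]
        rejections = 0
        n_sim = 400
        for _ in range(n_sim):
            prot_vals = rng.normal(0, 0.2, (8, 9))
            rna_vals = rng.normal(0, 0.2, (8, 6))
            prot = _assay_matrix(genes, prot_vals, "protein", 3)
            rna = _assay_matrix(genes, rna_vals, "rna", 2)
            out = discordance.stage_transition_discordance_test(
                prot, rna, self._complexes(genes), "early", "late")
            rejections += int(out.loc[0, "p_raw"] < 0.05)
        assert rejections / n_sim <= 0.075  # 0.05 + 3 binomial sds


class TestTfTargets:
    def test_planted_target_retained_with_argmax_stage(self):
        prof = np.array([0.0, 1.0, 3.0])
        prot = _assay_matrix(["TF1"], np.repeat(prof, 3)[None, :], "protein", 3)
        rna = _assay_matrix(["t1", "t2"],
                            np.vstack([np.repeat(prof, 2),
                                       np.zeros(6)]), "rna", 2)
        targets = GeneSetCollection({
            "TF1": GeneSet("TF1", frozenset({"t1", "t2"}), "tf_targets")
        })
        out = discordance.tf_target_concordance("TF1", prot, rna, targets)
        assert list(out["target"]) == ["t1"]  # flat t2 excluded (undefined r)
        assert out.loc[0, "argmax_stage"] == "late"

    def test_absent_tf_rejected(self):
        prot = _assay_matrix(["X"], np.zeros((1, 9)), "protein", 3)
        rna = _assay_matrix(["t1"], np.zeros((1, 6)), "rna", 2)
        targets = GeneSetCollection({
            "TF1": GeneSet("TF1", frozenset({"t1"}), "tf_targets")
        })
        with pytest.raises(ValidationError):
            discordance.tf_target_concordance("TF1", prot, rna, targets)

    def test_retained_set_matches_brute_force(self):
        rng = np.random.default_rng(7)
        tf_prof = rng.normal(size=9)
        targets = [f"t{i}" for i in range(12)]
        rna_vals = rng.normal(size=(12, 6))
        prot = _assay_matrix(["TF1"], tf_prof[None, :], "protein", 3)
        rna = _assay_matrix(targets, rna_vals, "rna", 2)
        coll = GeneSetCollection({
            "TF1": GeneSet("TF1", frozenset(targets), "tf_targets")
        })
        out = discordance.tf_target_concordance("TF1", prot, rna, coll,
                                                r_min=0.5)
        tf_means = tf_prof.reshape(3, 3).mean(axis=1)
        expect = set()
        for i, t in enumerate(targets):
            tm = rna_vals[i].reshape(3, 2).mean(axis=1)
            if np.corrcoef(tf_means, tm)[0, 1] >= 0.5:
                expect.add(t)
        assert set(out["target"]) == expect
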