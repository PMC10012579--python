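"""Design building, per-gene OLS, variance moderation, BH, call gates."""

import subprocess

import numpy as np
import pandas as pd
import pytest

import imprintatlas as ia
from imprintatlas.parental_effect_model import moderated_tests


def _records(gene_values, crosses=("AxB", "BxA"), reps=2, tissue="EPC"):
    """Minimal annotated record table; gene_values maps gene ->
    (maternal_rpm, paternal_rpm) or a callable of (cross, rep)."""
    rows = []
    for gene, val in gene_values.items():
        for cross in crosses:
            for rep in range(1, reps + 1):
                m, p = val(cross, rep) if callable(val) else val
                rows.append((gene, f"{tissue}_{cross}_r{rep}", cross, tissue,
                             m, p))
    return pd.DataFrame(rows, columns=[
        "transcript_id", "sample_id", "cross", "tissue",
        "maternal_rpm", "paternal_rpm"])


class TestBuildDesign:
    def test_two_rows_per_passing_sample(self):
        design = ia.build_design(_records({"g1": (4.0, 16.0)}))
        assert len(design) == 8  # 2 crosses x 2 reps x 2 alleles
        assert set(design["x_parent"]) == {-1.0, 1.0}
        # strain flips with cross for a fixed parent
        pat = design[design["allele_parent"] == "paternal"]
        assert set(pat.groupby("cross")["x_strain"].first()) == {-1.0, 1.0}

    def test_gene_covered_in_one_cross_excluded(self):
        def val(cross, rep):
            return (4.0, 16.0) if cross == "AxB" else (0.1, 0.2)
        design = ia.build_design(_records({"g1": val}))
        assert design.empty

    def test_pseudocount_on_zero_rpm(self):
        design = ia.build_design(_records({"g1": (0.0, 16.0)}))
        mat = design[design["allele_parent"] == "maternal"]
        assert (mat["log2_expr"] == np.log2(0.5)).all()


class TestFitParentalModel:
    def test_pure_parental_effect_exact(self):
        def val(cross, rep):
            return (4.0, 16.0)  # paternal uniformly +2 log2
        design = ia.build_design(_records({"g1": val}), pseudocount=0.0)
        fit = ia.fit_parental_model(design)
        assert fit.beta_parent == pytest.approx(2.0, abs=1e-12)
        assert fit.beta_strain == pytest.approx(0.0, abs=1e-12)
        assert fit.s2 == pytest.approx(0.0, abs=1e-20)

    def test_pure_strain_effect_exact(self):
        def val(cross, rep):
            # strain B allele is 4x; B is the sire in AxB, the dam in BxA
            return (4.0, 16.0) if cross == "AxB" else (16.0, 4.0)
        design = ia.build_design(_records({"g1": val}), pseudocount=0.0)
        fit = ia.fit_parental_model(design)
        assert fit.beta_parent == pytest.approx(0.0, abs=1e-12)
        assert fit.beta_strain == pytest.approx(2.0, abs=1e-12)

    def test_matches_normal_equations_oracle(self):
        rng = np.random.default_rng(4)

        def val(cross, rep):
            return tuple(np.exp(rng.normal(2, 1, 2)))
        design = ia.build_design(_records({"g1": val}, reps=4))
        fit = ia.fit_parental_model(design)
        X = np.column_stack([np.ones(len(design)), design["x_parent"],
                             design["x_strain"]])
        y = design["log2_expr"].to_numpy()
        beta = np.linalg.solve(X.T @ X, X.T @ y)
        resid = y - X @ beta
        assert fit.beta_parent == pytest.approx(2 * beta[1], abs=1e-10)
        assert fit.beta_strain == pytest.approx(2 * beta[2], abs=1e-10)
        assert fit.s2 == pytest.approx(resid @ resid / (len(y) - 3), abs=1e-10)

    def test_single_cross_is_rank_deficient(self):
        design = ia.build_design(_records({"g1": (4.0, 16.0)}), min_reps_per_cross=2)
        sub = design[design["cross"] == "AxB"]
        fit = ia.fit_parental_model(sub)
        assert not fit.testable


class TestModerateVariances:
    def test_identical_variances_collapse_to_common_value(self):
        d0, s0, post = ia.moderate_variances(np.full(20, 3.0), 9)
        assert np.isinf(d0)
        assert s0 == pytest.approx(3.0)
        assert post == pytest.approx(np.full(20, 3.0))

    def test_posterior_lies_between_prior_and_sample(self):
        rng = np.random.default_rng(2)
        s2 = rng.chisquare(5, 200) / 5
        d0, s0, post = ia.moderate_variances(s2, 9)
        lo = np.minimum(s0, s2)
        hi = np.maximum(s0, s2)
        assert ((post >= lo - 1e-12) & (post <= hi + 1e-12)).all()

    def test_hyperparameter_recovery(self):
        """s2 ~ scaled-inv-chi2(d0=4, s0^2=2) x chi2_9/9 sampling: the
        moment estimator recovers d0 within +/-1 and s0^2 within 10%."""
        rng = np.random.default_rng(7)
        d0_true, s0_true, d = 4.0, 2.0, 9
        sigma2 = s0_true * d0_true / rng.chisquare(d0_true, 5000)
        s2 = sigma2 * rng.chisquare(d, 5000) / d
        d0, s0, _ = ia.moderate_variances(s2, d)
        assert abs(d0 - d0_true) < 1.0
        assert abs(s0 - s0_true) / s0_true < 0.10

    def test_agrees_with_limma_squeezevar(self, tmp_path):
        """Independent oracle: limma::squeezeVar on the same variances."""
        rng = np.random.default_rng(42)
        sigma2 = 2.0 * 4.0 / rng.chisquare(4.0, 200)
        s2 = sigma2 * rng.chisquare(9, 200) / 9
        d0, s0, post = ia.moderate_variances(s2, 9)
        s2_file = tmp_path / "s2.txt"
        np.savetxt(s2_file, s2)
        out = subprocess.run(
            ["Rscript", "-e",
             f's<-scan("{s2_file}",quiet=TRUE);'
             'sv<-limma::squeezeVar(s,df=9);'
             'cat(sv$df.prior, sv$var.prior, sv$var.post[1])'],
            capture_output=True, text=True)
        if out.returncode != 0:
            pytest.skip("Rscript/limma unavailable")
        d0_r, s0_r, post_r = map(float, out.stdout.split())
        assert d0 == pytest.approx(d0_r, rel=1e-4)
        assert s0 == pytest.approx(s0_r, rel=1e-4)
        assert post[0] == pytest.approx(post_r, rel=1e-4)

    def test_no_shrinkage_limit_equals_ordinary_t(self):
        """With d0 = 0 the moderated statistic is the ordinary t."""
        beta, lev, s2, d = 1.4, 0.5, 0.9, 9.0
        post = (0.0 * 1.0 + d * s2) / (0.0 + d)   # d0 -> 0 limit
        assert post == pytest.approx(s2)
        assert beta / np.sqrt(post * lev) == pytest.approx(
            beta / np.sqrt(s2 * lev))


class TestBhAdjust:
    @pytest.mark.parametrize("p,expected", [
        ([0.01, 0.02, 0.03], [0.03, 0.03, 0.03]),
        ([0.001, 0.5], [0.002, 0.5]),
        ([0.2], [0.2]),
    ])
    def test_worked_examples(self, p, expected):
        assert ia.bh_adjust(p) == pytest.approx(expected)

    def test_monotone_in_rank(self):
        rng = np.random.default_rng(0)
        p = rng.random(100)
        adj = ia.bh_adjust(p)
        order = np.argsort(p)
        assert (np.diff(adj[order]) >= -1e-12).all()
        assert adj.max() <= 1.0


class TestCallGates:
    def _tests_frame(self, beta, adj_p):
        return pd.DataFrame({"gene_id": [f"g{i}" for i in range(len(beta))],
                             "beta_parent": beta, "adj_p": adj_p})

    def test_fold_change_and_significance_gates(self):
        tests = self._tests_frame([2.1, 1.9, -2.5], [0.01, 1e-6, 0.2])
        calls = ia.call_imprinted_lm(tests)
        assert list(calls["status"]) == ["paternal", "biallelic", "biallelic"]

    def test_direction_by_sign(self):
        tests = self._tests_frame([-2.2], [0.001])
        assert ia.call_imprinted_lm(tests).iloc[0].status == "maternal"


class TestOnSimulation:
    def test_strain_biased_centred_and_never_called(self, expr_sim):
        rec = ia.annotate_expression(
            expr_sim.counts[expr_sim.counts.tissue == "EPC"],
            expr_sim.annotation)
        tests = moderated_tests(ia.fit_all_genes(ia.build_design(rec)))
        calls = ia.call_imprinted_lm(tests)
        truth = expr_sim.truth.genes.set_index("gene_id")
        merged = calls.merge(truth, left_on="gene_id", right_index=True)
        strain = merged[merged["class"] == "strain_biased"]
        assert abs(strain["beta_parent"].mean()) < 0.15
        assert (strain["status"] == "biallelic").all()
        imp = merged[merged["class"].isin(["paternal_imprint",
                                           "maternal_imprint"])]
        assert (imp["status"] != "biallelic").mean() >= 0.95

    def test_parental_effect_recovery_at_effect_two(self):
        """A configured 4-fold (2.0 log2) parental effect, 12 samples at
        concentration 200, is recovered with |bias| < 0.1."""
        cfg = ia.SimConfig(seed=23, n_biallelic=50, n_paternal_imprint=60,
                           n_maternal_imprint=0, n_strain_biased=0,
                           n_decidua_contaminated=0, n_chrx=0,
                           ratio_paternal_imprint=0.8,  # log2(0.8/0.2) = 2
                           replicates_per_cross=6, nb_mean=3000.0)
        sim = ia.simulate_reciprocal_expression(cfg)
        rec = ia.annotate_expression(sim.counts[sim.counts.tissue == "EPC"],
                                     sim.annotation)
        tests = moderated_tests(ia.fit_all_genes(ia.build_design(rec)))
        truth = sim.truth.genes.set_index("gene_id")
        merged = tests.merge(truth, left_on="gene_id", right_index=True)
        pat = merged[merged["class"] == "paternal_imprint"]
        assert abs(pat["beta_parent"].mean() - 2.0) < 0.1
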