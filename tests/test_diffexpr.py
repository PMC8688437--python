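"""TMM normalization, dispersion estimation, NB exact test, BH, DE calls."""

import subprocess
import tempfile
from pathlib import Path

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from mirpipe import diffexpr as de
from mirpipe import synthetic as syn

from .oracles import bh_adjust_stepup


def _matrix(counts, groups=None, sample_ids=None):
    counts = np.asarray(counts)
    n = counts.shape[1]
    return de.CountMatrix(
        feature_ids=[f"g{i}" for i in range(counts.shape[0])],
        sample_ids=sample_ids or [f"s{j}" for j in range(n)],
        counts=counts,
        groups=groups or (["a"] * (n // 2) + ["b"] * (n - n // 2)),
    )


class TestTMM:
    def test_identical_columns_give_unit_factors(self, rng):
        col = rng.poisson(50, size=500)
        f = de.tmm_factors(_matrix(np.column_stack([col, col])))
        assert np.allclose(f.factors, 1.0)

    def test_uniform_scaling_leaves_factors_unchanged(self, rng):
        c1 = rng.poisson(60, size=800)
        c2 = rng.poisson(60, size=800)
        base = de.tmm_factors(_matrix(np.column_stack([c1, c2])))
        scaled = de.tmm_factors(_matrix(np.column_stack([c1, c2 * 10])))
        assert np.max(np.abs(base.factors - scaled.factors)) <= 1e-6

    def test_composition_bias_recovered(self, rng):
        """5% of features 8-fold up in one sample: factor compensates the
        known library inflation (constructed truth) within 5%."""
        n = 5000
        base = np.exp(rng.normal(4, 1, n))
        up = rng.choice(n, size=n // 20, replace=False)
        mult = np.ones(n)
        mult[up] = 8.0
        counts = np.column_stack([rng.poisson(base), rng.poisson(base * mult)])
        f = de.tmm_factors(_matrix(counts))
        inflation = (base * mult).sum() / base.sum()
        assert f.factors[0] == pytest.approx(np.sqrt(inflation), rel=0.05)
        assert f.factors[1] == pytest.approx(1 / np.sqrt(inflation), rel=0.05)

    def test_geometric_mean_is_one(self, rng):
        counts = rng.poisson(40, size=(400, 5))
        f = de.tmm_factors(_matrix(counts, groups=["a", "a", "a", "b", "b"]))
        assert np.exp(np.mean(np.log(f.factors))) == pytest.approx(1.0, abs=1e-9)

    def test_no_shared_nonzero_feature_warns_factor_one(self):
        counts = np.array([[10, 0], [20, 0], [0, 5], [0, 7]])
        with pytest.warns(UserWarning):
            f = de.tmm_factors(_matrix(counts))
        assert np.allclose(f.factors, 1.0)

    def test_matches_edger_with_same_trim_fractions(self):
        """Cross-check against Bioconductor edgeR's calcNormFactors."""
        truth = syn.default_expression_truth(
            n_genes=300, dispersion=0.15, frac_de=0.2, de_lfc=1.5, seed=3
        )
        m, _ = syn.simulate_count_matrix(truth)
        mine = de.tmm_factors(m).factors
        with tempfile.TemporaryDirectory() as td:
            cf = Path(td) / "c.tsv"
            pd.DataFrame(m.counts, index=m.feature_ids, columns=m.sample_ids).to_csv(cf, sep="\t")
            script = (
                'suppressMessages(library(edgeR));'
                f'x <- as.matrix(read.delim("{cf}", row.names=1));'
                'y <- DGEList(counts=x);'
                'y <- calcNormFactors(y, logratioTrim=0.15, sumTrim=0.025);'
                'cat(y$samples$norm.factors, sep="\\n")'
            )
            proc = subprocess.run(["Rscript", "-e", script], capture_output=True, text=True)
            if proc.returncode != 0:
                pytest.skip(f"Rscript/edgeR unavailable: {proc.stderr[:200]}")
            ref = np.array([float(v) for v in proc.stdout.split()])
        assert np.max(np.abs(mine / ref - 1)) < 0.025


class TestDispersion:
    def test_poisson_null_estimate_near_zero(self):
        truth = syn.default_expression_truth(n_genes=10_000, dispersion=0.0, frac_de=0.0, seed=8)
        m, _ = syn.simulate_count_matrix(truth)
        phi = de.estimate_common_dispersion(m, de.tmm_factors(m))
        assert phi <= 0.01

    def test_recovery_at_phi_02(self):
        truth = syn.default_expression_truth(n_genes=10_000, dispersion=0.2, frac_de=0.0, seed=7)
        m, _ = syn.simulate_count_matrix(truth)
        phi = de.estimate_common_dispersion(m, de.tmm_factors(m))
        assert 0.15 <= phi <= 0.25

    def test_constant_counts_give_zero(self):
        counts = np.full((50, 6), 37)
        m = _matrix(counts)
        assert de.estimate_common_dispersion(m, de.tmm_factors(m)) == 0.0

    def test_no_replicates_warns_poisson_fallback(self, rng):
        counts = rng.poisson(30, size=(100, 2))
        m = _matrix(counts, groups=["a", "b"])
        with pytest.warns(UserWarning):
            assert de.estimate_common_dispersion(m, de.tmm_factors(m)) == 0.0


class TestExactTest:
    def test_poisson_limit_matches_conditional_binomial(self, rng):
        for _ in range(200):
            n1, n2 = int(rng.integers(1, 5)), int(rng.integers(1, 5))
            t = int(rng.integers(0, 300))
            s1 = int(rng.integers(0, t + 1)) if t else 0
            mine = de._exact_test_pvalue(s1, t, n1, n2, 0.0)
            ref = stats.binomtest(s1, t, n1 / (n1 + n2)).pvalue if t else 1.0
            assert mine == pytest.approx(ref, abs=1e-9)

    def test_symmetric_null_p_one(self):
        assert de._exact_test_pvalue(25, 50, 3, 3, 0.1) == pytest.approx(1.0)

    def test_zero_total_feature_p_one_lfc_zero(self, rng):
        counts = rng.poisson(50, size=(20, 6))
        counts[:3] = 0  # features with zero total across all samples
        m = _matrix(counts)
        res = de.nb_exact_test(m, de.tmm_factors(m), 0.1)
        assert (res.PValue[:3] == 1.0).all()
        assert (res.logFC[:3] == 0.0).all()

    def test_null_calibration_at_005(self):
        truth = syn.default_expression_truth(n_genes=10_000, dispersion=0.1, frac_de=0.0, seed=42)
        m, _ = syn.simulate_count_matrix(truth)
        res = de.nb_exact_test(m, de.tmm_factors(m), 0.1)
        assert (res.PValue <= 0.05).mean() == pytest.approx(0.05, abs=0.01)

    def test_null_p_distribution_calibrated_at_all_quantiles(self):
        """The exact test is discrete, hence conservative: P(p<=q) never
        exceeds q by more than sampling noise and never falls far below."""
        truth = syn.default_expression_truth(n_genes=10_000, dispersion=0.1, frac_de=0.0, seed=43)
        m, _ = syn.simulate_count_matrix(truth)
        p = de.nb_exact_test(m, de.tmm_factors(m), 0.1).PValue.to_numpy()
        for q in (0.01, 0.05, 0.1, 0.25, 0.5, 0.75):
            frac = (p <= q).mean()
            assert frac <= q + 0.015
            assert frac >= q - 0.03

    def test_swapping_groups_negates_lfc_preserves_p(self, rng):
        counts = rng.poisson(80, size=(200, 6))
        m1 = _matrix(counts, groups=["a"] * 3 + ["b"] * 3)
        m2 = _matrix(counts, groups=["b"] * 3 + ["a"] * 3)
        f1, f2 = de.tmm_factors(m1), de.tmm_factors(m2)
        r1 = de.nb_exact_test(m1, f1, 0.1)
        r2 = de.nb_exact_test(m2, f2, 0.1)
        assert np.allclose(r1.logFC, -r2.logFC, atol=1e-12)
        assert np.allclose(r1.PValue, r2.PValue, atol=1e-12)

    def test_permuting_samples_changes_nothing(self, rng):
        counts = rng.poisson(80, size=(200, 6))
        groups = ["a", "b", "a", "b", "a", "b"]
        m1 = _matrix(counts, groups=groups)
        perm = [3, 1, 4, 0, 5, 2]
        m2 = de.CountMatrix(
            feature_ids=m1.feature_ids,
            sample_ids=[m1.sample_ids[j] for j in perm],
            counts=counts[:, perm],
            groups=[groups[j] for j in perm],
        )
        r1 = de.nb_exact_test(m1, de.tmm_factors(m1), 0.1)
        r2 = de.nb_exact_test(m2, de.tmm_factors(m2), 0.1)
        assert np.allclose(r1.PValue, r2.PValue, atol=1e-12)
        assert np.allclose(r1.logFC, r2.logFC, atol=1e-12)


class TestBHAndCalls:
    def test_hand_example_step_up(self):
        adj = de.bh_fdr([0.01, 0.02, 0.03])
        assert np.allclose(adj, [0.03, 0.03, 0.03])

    def test_single_and_boundary(self):
        assert de.bh_fdr([0.2])[0] == pytest.approx(0.2)
        assert (de.bh_fdr([1.0, 1.0, 1.0]) == 1.0).all()

    def test_matches_textbook_oracle(self, rng):
        p = rng.uniform(size=100)
        assert np.allclose(de.bh_fdr(p), bh_adjust_stepup(p))

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            de.bh_fdr([0.5, 1.5])

    def test_call_signs_and_strict_threshold(self):
        frame = pd.DataFrame(
            {
                "feature_id": ["a", "b", "c"],
                "logFC": [-1.0, 2.0, 1.0],
                "PValue": [0.001, 0.001, 0.5],
                "FDR": [0.04, 0.05, 0.9],
            }
        )
        out, summary = de.call_de(frame, 0.05)
        assert list(out.call) == ["down", "ns", "ns"]
        assert summary == {"total": 1, "up": 0, "down": 1}

    def test_planted_power_and_fdr_control(self):
        """10% planted |LFC|=2 at 3v3, phi=0.1: >=80% recovered, FDR <= 0.07."""
        truth = syn.default_expression_truth(
            n_genes=5000, dispersion=0.1, frac_de=0.10, de_lfc=2.0, seed=10
        )
        m, truth = syn.simulate_count_matrix(truth)
        res, summary, _, _ = de.de_pipeline(m, fdr_threshold=0.05, dispersion=0.1)
        called = res.call != "ns"
        planted = truth.lfc != 0
        power = (called & planted).sum() / planted.sum()
        fdr = (called & ~planted).sum() / max(1, called.sum())
        assert power >= 0.8
        assert fdr <= 0.07
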