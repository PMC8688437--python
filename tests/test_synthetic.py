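"""Generator contracts: determinism, planted-truth consistency, distributional sanity."""

import numpy as np
import pytest
from scipy import stats

from mirpipe import synthetic as syn


class TestToyGenome:
    def test_deterministic_per_seed(self):
        a = syn.make_toy_genome(1, 1000, seed=7)
        b = syn.make_toy_genome(1, 1000, seed=7)
        assert a.sequences == b.sequences

    def test_seed_sensitivity(self):
        a = syn.make_toy_genome(2, 500, seed=1)
        b = syn.make_toy_genome(2, 500, seed=2)
        assert a.sequences != b.sequences

    def test_base_composition_uniform(self):
        g = syn.make_toy_genome(1, 100_000, seed=3)
        seq = g.sequences["chr1"]
        for base in "ACGT":
            assert seq.count(base) / len(seq) == pytest.approx(0.25, abs=0.01)

    def test_invalid_dimensions_rejected(self):
        with pytest.raises(ValueError):
            syn.make_toy_genome(0, 1000, seed=1)
        with pytest.raises(ValueError):
            syn.make_toy_genome(1, 100, seed=1)


class TestPlantedLoci:
    def test_construction_contract(self, genome):
        loci = syn.plant_mirna_loci(genome, 10, lengths=(20, 22), seed=3)
        assert len(loci) == 10
        for loc in loci:
            assert syn._count_occurrences(genome, loc.mature_seq) == 1

    def test_strand_five_prime_convention(self):
        loc = syn.MiRNALocus("x", "c", "-", 101, 122, 122, "A" * 22)
        assert loc.five_prime_pos == loc.end
        with pytest.raises(ValueError):
            syn.MiRNALocus("x", "c", "-", 101, 122, 101, "A" * 22)

    def test_mature_seq_round_trip(self, genome, loci):
        for loc in loci:
            sub = genome.sequences[loc.chrom][loc.start - 1 : loc.end]
            expected = sub if loc.strand == "+" else syn.revcomp(sub)
            assert loc.mature_seq == expected

    def test_both_strands_used(self, loci):
        strands = {loc.strand for loc in loci}
        assert strands == {"+", "-"}


class TestSmallRNAReads:
    def test_point_mass_offset_reads_match_mature(self, genome, loci):
        spec = syn.SmallRNASimSpec(
            expected_counts={"s": {l.mirna_id: 50 for l in loci}},
            offset_probs={0: 1.0},
            tail_probs={0: 1.0},
            error_rate=0.0,
            seed=9,
        )
        reads, truth = syn.simulate_smallrna_reads(loci, spec, genome)
        mature = {l.mature_seq for l in loci}
        for _, seq in reads["s"]:
            insert = seq[: seq.find(spec.adapter)]
            assert insert in mature
        assert (truth.loc[truth.offset != 0, "n_total"] == 0).all()

    def test_offset_counts_within_binomial_sd(self, genome, loci):
        spec = syn.SmallRNASimSpec(
            expected_counts={"s": {loci[0].mirna_id: 1000}},
            offset_probs={0: 0.8, 1: 0.2},
            tail_probs={0: 1.0},
            seed=5,
        )
        _, truth = syn.simulate_smallrna_reads(loci, spec, genome)
        sub = truth[truth.mirna_id == loci[0].mirna_id].set_index("offset")
        n = sub.n_total.sum()
        sd = np.sqrt(n * 0.8 * 0.2)
        assert abs(sub.loc[0, "n_total"] - 0.8 * n) <= 3 * sd

    def test_error_free_fraction_matches_independence(self, genome, loci):
        e = 0.01
        spec = syn.SmallRNASimSpec(
            expected_counts={"s": {l.mirna_id: 400 for l in loci}},
            offset_probs={0: 1.0},
            tail_probs={0: 1.0},
            error_rate=e,
            seed=6,
        )
        _, truth = syn.simulate_smallrna_reads(loci, spec, genome)
        frac = truth.n_error_free.sum() / truth.n_total.sum()
        read_len = 21 + len(spec.adapter)  # mean mature length + adapter
        expected = (1 - e) ** read_len
        assert frac == pytest.approx(expected, abs=0.02)

    def test_short_adapter_rejected(self, loci):
        with pytest.raises(ValueError):
            syn.SmallRNASimSpec(expected_counts={"s": {}}, adapter="ACGTACG")

    def test_truth_marginals_match_expectation(self, genome, loci):
        expected = 500
        spec = syn.SmallRNASimSpec(
            expected_counts={"s": {l.mirna_id: expected for l in loci}}, seed=8
        )
        _, truth = syn.simulate_smallrna_reads(loci, spec, genome)
        per_mirna = truth.groupby("mirna_id").n_total.sum()
        sd = np.sqrt(expected)
        assert (np.abs(per_mirna - expected) <= 3 * sd).all()


class TestCountMatrix:
    def test_poisson_limit_variance_ratio(self):
        truth = syn.ExpressionSimTruth(
            gene_ids=[f"g{i}" for i in range(10_000)],
            base_mean=np.full(10_000, 50.0),
            lfc=np.zeros(10_000),
            dispersion=0.0,
            group_sizes=(5, 5),
            lib_sizes=np.ones(10),
            seed=1,
        )
        m, _ = syn.simulate_count_matrix(truth)
        ratio = m.counts.var(axis=1, ddof=1) / m.counts.mean(axis=1)
        assert ratio.mean() == pytest.approx(1.0, abs=0.05)

    def test_nb_variance_identity(self):
        phi, mu = 0.2, 100.0
        truth = syn.ExpressionSimTruth(
            gene_ids=[f"g{i}" for i in range(10_000)],
            base_mean=np.full(10_000, mu),
            lfc=np.zeros(10_000),
            dispersion=phi,
            group_sizes=(5, 5),
            lib_sizes=np.ones(10),
            seed=2,
        )
        m, _ = syn.simulate_count_matrix(truth)
        pooled_var = m.counts.var(axis=1, ddof=1).mean()
        assert pooled_var == pytest.approx(mu + phi * mu**2, rel=0.10)

    def test_null_group_means_exchangeable(self):
        truth = syn.ExpressionSimTruth(
            gene_ids=[f"g{i}" for i in range(2000)],
            base_mean=np.full(2000, 80.0),
            lfc=np.zeros(2000),
            dispersion=0.1,
            group_sizes=(3, 3),
            lib_sizes=np.ones(6),
            seed=3,
        )
        m, _ = syn.simulate_count_matrix(truth)
        t, p = stats.ttest_ind(m.counts[:, :3].T, m.counts[:, 3:].T)
        assert stats.kstest(p, "uniform").pvalue > 0.01

    def test_planted_shift_applied_to_targets(self):
        genes = [f"g{i}" for i in range(2000)]
        targets = set(genes[:200])
        truth = syn.ExpressionSimTruth(
            gene_ids=genes,
            base_mean=np.full(2000, 200.0),
            lfc=np.zeros(2000),
            dispersion=0.0,
            group_sizes=(20, 20),
            lib_sizes=np.ones(40),
            target_map={"mirX": targets},
            delta={"mirX": 1.0},
            seed=4,
        )
        m, _ = syn.simulate_count_matrix(truth)
        is_t = np.array([g in targets for g in genes])
        ratio = m.counts[:, 20:].mean(axis=1) / m.counts[:, :20].mean(axis=1)
        assert np.median(ratio[is_t]) == pytest.approx(2.0, rel=0.05)
        assert np.median(ratio[~is_t]) == pytest.approx(1.0, rel=0.05)

    def test_invalid_dispersion_rejected(self):
        with pytest.raises(ValueError):
            syn.ExpressionSimTruth(
                gene_ids=["g1"],
                base_mean=np.array([1.0]),
                lfc=np.array([0.0]),
                dispersion=-0.1,
                group_sizes=(1, 1),
                lib_sizes=np.ones(2),
            )


class TestClinical:
    def test_full_separation_limit(self):
        tab = syn.simulate_clinical(200, 1.0, 1.0, seed=1)
        lo = tab.loc[tab.label == 1, "expression"].min()
        hi = tab.loc[tab.label == 0, "expression"].max()
        assert lo > hi  # binormal means ~14.7 SD apart: empirical AUC = 1

    def test_null_auc_half(self):
        tab = syn.simulate_clinical(10_000, 0.5, 1.0, seed=2)
        from mirpipe.clinstats import roc_auc

        assert roc_auc(tab.expression, tab.label).auc == pytest.approx(0.5, abs=0.02)

    def test_invalid_auc_target_rejected(self):
        with pytest.raises(ValueError):
            syn.simulate_clinical(100, 0.4, 1.0, seed=1)
        with pytest.raises(ValueError):
            syn.simulate_clinical(100, 1.2, 1.0, seed=1)

    def test_reproducible(self):
        a = syn.simulate_clinical(100, 0.8, 2.0, seed=5)
        b = syn.simulate_clinical(100, 0.8, 2.0, seed=5)
        assert a.equals(b)
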