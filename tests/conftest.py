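import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from mirpipe import synthetic as syn

settings.register_profile(
    "ci", derandomize=True, max_examples=30, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def genome():
    return syn.make_toy_genome(2, 3000, seed=11)


@pytest.fixture(scope="session")
def loci(genome):
    return syn.plant_mirna_loci(genome, 12, seed=4)


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)


def random_quant_instance(rng, max_loci=50, max_seqs=5000):
    """Random alignments/counts/loci for quantifier oracle-equivalence checks.

    Sequences are synthetic labels with random lengths; alignments cluster
    around locus 5' ends (window-relevant) with a fraction placed far away.
    """
    from mirpipe.quant import SequenceAlignment
    from mirpipe.synthetic import MiRNALocus

    n_loci = int(rng.integers(1, max_loci + 1))
    n_seqs = int(rng.integers(1, max_seqs + 1))
    chroms = ["c1", "c2"]
    loci = []
    for i in range(n_loci):
        strand = "+" if rng.random() < 0.5 else "-"
        length = int(rng.integers(20, 23))
        start = int(rng.integers(100, 100000))
        end = start + length - 1
        loci.append(
            MiRNALocus(
                mirna_id=f"m{i}",
                chrom=chroms[int(rng.integers(2))],
                strand=strand,
                start=start,
                end=end,
                five_prime_pos=start if strand == "+" else end,
                mature_seq="A" * length,
            )
        )
    alignments, counts = [], {}
    bases = "ACGT"
    for j in range(n_seqs):
        length = int(rng.integers(18, 29))
        seq = "".join(bases[b] for b in rng.integers(0, 4, size=length))
        if seq in counts:
            continue
        counts[seq] = int(rng.integers(1, 100))
        for _ in range(int(rng.integers(1, 4))):
            if rng.random() < 0.8 and loci:
                loc = loci[int(rng.integers(len(loci)))]
                delta = int(rng.integers(-5, 6))
                pos5 = loc.five_prime_pos + delta
                chrom, strand = loc.chrom, loc.strand
            else:
                chrom = chroms[int(rng.integers(2))]
                strand = "+" if rng.random() < 0.5 else "-"
                pos5 = int(rng.integers(100, 100000))
            start = pos5 if strand == "+" else pos5 - length + 1
            end = start + length - 1
            alignments.append(
                SequenceAlignment(seq, chrom, strand, start, end, pos5 if strand == "+" else end)
            )
    return alignments, counts, loci
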