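"""Synthetic data generators for every pipeline stage.

The generators emulate the statistical structure of a two-cell-line
knockdown-vs-control small-RNA/mRNA sequencing study: mature miRNA loci
planted on a random genome, isomiR-structured read populations concentrated
at the annotated 5' ends, negative-binomial count matrices with a minority
of truly changed genes, miRNA→target maps whose member genes carry a
repression-release shift, and clinical biomarker/survival tables.  Each
generator returns a truth object sufficient to compute every downstream
expected value, and is bit-reproducible for a fixed seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import ndtri

_COMPLEMENT = str.maketrans("ACGT", "TGCA")
BASES = np.array(list("ACGT"))

# fixed per-component offsets for cascading one global seed
SEED_GENOME = 11
SEED_LOCI = 23
SEED_READS = 37
SEED_COUNTS = 53
SEED_CLINICAL = 71


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def _rng(seed: int, offset: int) -> np.random.Generator:
    return np.random.default_rng([int(seed), int(offset)])


@dataclass(frozen=True)
class ToyGenome:
    chrom_names: tuple[str, ...]
    sequences: dict[str, str]
    seed: int

    def __post_init__(self):
        for name in self.chrom_names:
            seq = self.sequences[name]
            if not seq or set(seq) - set("ACGT"):
                raise ValueError(f"chromosome {name} is empty or not A/C/G/T")


@dataclass(frozen=True)
class MiRNALocus:
    """Genomic placement of one mature miRNA, strand-aware.

    ``five_prime_pos`` is the genomic coordinate of the mature 5' nucleotide:
    ``start`` on the plus strand, ``end`` on the minus strand (1-based
    inclusive coordinates throughout).
    """

    mirna_id: str
    chrom: str
    strand: str
    start: int
    end: int
    five_prime_pos: int
    mature_seq: str

    def __post_init__(self):
        if self.strand not in "+-":
            raise ValueError("strand must be '+' or '-'")
        expected_5p = self.start if self.strand == "+" else self.end
        if self.five_prime_pos != expected_5p:
            raise ValueError("five_prime_pos inconsistent with strand convention")
        if self.mature_seq and self.end - self.start + 1 != len(self.mature_seq):
            raise ValueError("coordinates inconsistent with mature sequence length")


@dataclass
class SmallRNASimSpec:
    """Parameters of the isomiR read simulator.

    ``expected_counts`` maps sample name → (miRNA id → expected read count);
    ``offset_probs`` is the 5'-offset distribution over -3..+3 in mature-RNA
    orientation, ``tail_probs`` the 3'-length-variation distribution over
    -2..+2 (template-extended).  Defaults concentrate mass at the annotated
    5' end while exercising every window slot.
    """

    expected_counts: dict[str, dict[str, float]]
    offset_probs: dict[int, float] = field(
        default_factory=lambda: {-3: 0.005, -2: 0.015, -1: 0.08, 0: 0.80, 1: 0.08, 2: 0.015, 3: 0.005}
    )
    tail_probs: dict[int, float] = field(default_factory=lambda: {t: 0.2 for t in range(-2, 3)})
    adapter: str = "TGGAATTCTCGGGTGCCAAGG"
    error_rate: float = 0.0
    seed: int = 0

    def __post_init__(self):
        for probs, rng_ in ((self.offset_probs, range(-3, 4)), (self.tail_probs, range(-2, 3))):
            if any(k not in rng_ for k in probs):
                raise ValueError("offsets outside the allowed range")
            if abs(sum(probs.values()) - 1.0) > 1e-9:
                raise ValueError("offset distribution must sum to 1")
        if not 0.0 <= self.error_rate <= 1.0:
            raise ValueError("error rate must be in [0, 1]")
        if len(self.adapter) < 8:
            raise ValueError("adapter must be at least 8 nt")
        if any(v < 0 for per in self.expected_counts.values() for v in per.values()):
            raise ValueError("expected counts must be nonnegative")


@dataclass
class ExpressionSimTruth:
    """Ground truth behind one simulated count matrix.

    ``base_mean``/``lfc``/``dispersion`` are per-gene; group 2 means are
    multiplied by ``2**lfc``.  Genes listed in ``target_map`` additionally
    receive the cognate miRNA's repression-release shift ``delta`` (log2
    units) on top of their own fold change.
    """

    gene_ids: list[str]
    base_mean: np.ndarray
    lfc: np.ndarray
    dispersion: float
    group_sizes: tuple[int, int]
    lib_sizes: np.ndarray
    target_map: dict[str, set[str]] = field(default_factory=dict)
    delta: dict[str, float] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self):
        self.base_mean = np.asarray(self.base_mean, dtype=float)
        self.lfc = np.asarray(self.lfc, dtype=float)
        self.lib_sizes = np.asarray(self.lib_sizes, dtype=float)
        if self.dispersion < 0:
            raise ValueError("dispersion must be nonnegative")
        if np.any(self.base_mean < 0):
            raise ValueError("negative base means")
        if np.any(self.lib_sizes <= 0):
            raise ValueError("library sizes must be positive")


def make_toy_genome(n_chrom: int, chrom_len: int, seed: int) -> ToyGenome:
    """Uniform-random A/C/G/T genome, deterministic per seed."""
    if n_chrom < 1 or chrom_len < 200:
        raise ValueError("need n_chrom >= 1 and chrom_len >= 200")
    rng = _rng(seed, SEED_GENOME)
    names = tuple(f"chr{i + 1}" for i in range(n_chrom))
    seqs = {name: "".join(rng.choice(BASES, size=chrom_len)) for name in names}
    return ToyGenome(chrom_names=names, sequences=seqs, seed=seed)


def _count_occurrences(genome: ToyGenome, seq: str) -> int:
    """Occurrences of ``seq`` as a perfect match on either genomic strand."""
    total = 0
    rc = revcomp(seq)
    for chrom_seq in genome.sequences.values():
        for probe in (seq, rc) if rc != seq else (seq,):
            start = chrom_seq.find(probe)
            while start != -1:
                total += 1
                start = chrom_seq.find(probe, start + 1)
    return total


def plant_mirna_loci(
    genome: ToyGenome,
    n_mirna: int,
    lengths: tuple[int, int] = (20, 22),
    seed: int = 0,
    min_gap: int = 30,
    edge_margin: int = 10,
    max_tries_per_locus: int = 200,
) -> list[MiRNALocus]:
    """Place non-overlapping mature-miRNA loci whose sequences are unique.

    Each candidate placement is rejected unless the mature sequence occurs
    exactly once in the genome across both strands, so downstream
    perfect-match mapping is unambiguous.  Loci keep ``min_gap`` nt apart so
    that ±3 nt quantification windows (and template-extended isomiR tails)
    never bleed into a neighbour, and ``edge_margin`` nt from chromosome
    ends so offset reads stay on-chromosome.
    """
    rng = _rng(seed, SEED_LOCI)
    lo, hi = lengths
    if not (18 <= lo <= hi <= 24):
        raise ValueError("mature lengths must lie within 18..24")
    occupied: dict[str, list[tuple[int, int]]] = {c: [] for c in genome.chrom_names}
    loci: list[MiRNALocus] = []
    for i in range(n_mirna):
        placed = False
        for _ in range(max_tries_per_locus):
            chrom = genome.chrom_names[rng.integers(len(genome.chrom_names))]
            chrom_seq = genome.sequences[chrom]
            length = int(rng.integers(lo, hi + 1))
            max_start = len(chrom_seq) - length + 1 - edge_margin
            if max_start <= edge_margin + 1:
                continue
            start = int(rng.integers(edge_margin + 1, max_start))
            end = start + length - 1
            if any(start - min_gap <= e and end + min_gap >= s for s, e in occupied[chrom]):
                continue
            strand = "+" if rng.random() < 0.5 else "-"
            mature = chrom_seq[start - 1 : end]
            if strand == "-":
                mature = revcomp(mature)
            if _count_occurrences(genome, mature) != 1:
                continue
            occupied[chrom].append((start, end))
            loci.append(
                MiRNALocus(
                    mirna_id=f"mir-{i + 1}",
                    chrom=chrom,
                    strand=strand,
                    start=start,
                    end=end,
                    five_prime_pos=start if strand == "+" else end,
                    mature_seq=mature,
                )
            )
            placed = True
            break
        if not placed:
            raise RuntimeError(f"could not place locus {i + 1} after {max_tries_per_locus} tries")
    return loci


def simulate_smallrna_reads(
    loci: list[MiRNALocus], spec: SmallRNASimSpec, genome: ToyGenome
) -> tuple[dict[str, list[tuple[str, str]]], pd.DataFrame]:
    """Simulate adapter-carrying isomiR reads and their truth table.

    Per sample and miRNA, a Poisson number of reads is drawn around the
    expected count.  Each read takes a 5' offset (mature-RNA orientation;
    positive = downstream into the mature body) and a 3' tail variation,
    both template-extended from the genome, then the 3' adapter is appended
    and per-base errors applied across the whole read.  The truth table
    counts, per (miRNA, sample, offset), the reads that carry no error.
    """
    rng = _rng(spec.seed, SEED_READS)
    offsets = np.array(sorted(spec.offset_probs))
    offset_p = np.array([spec.offset_probs[o] for o in offsets])
    tails = np.array(sorted(spec.tail_probs))
    tail_p = np.array([spec.tail_probs[t] for t in tails])
    reads_per_sample: dict[str, list[tuple[str, str]]] = {}
    truth_rows = []
    for sample in sorted(spec.expected_counts):
        reads: list[tuple[str, str]] = []
        for locus in loci:
            expected = spec.expected_counts[sample].get(locus.mirna_id, 0.0)
            n_reads = int(rng.poisson(expected))
            if n_reads == 0:
                continue
            read_offsets = rng.choice(offsets, size=n_reads, p=offset_p)
            read_tails = rng.choice(tails, size=n_reads, p=tail_p)
            error_free = np.zeros(n_reads, dtype=bool)
            chrom_seq = genome.sequences[locus.chrom]
            for j, (off, tail) in enumerate(zip(read_offsets, read_tails)):
                if locus.strand == "+":
                    s, e = locus.start + off, locus.end + tail
                    insert = chrom_seq[s - 1 : e]
                else:
                    s, e = locus.start - tail, locus.end - off
                    insert = revcomp(chrom_seq[s - 1 : e])
                read = insert + spec.adapter
                if spec.error_rate > 0:
                    arr = np.frombuffer(read.encode(), dtype="S1").copy()
                    hit = rng.random(len(arr)) < spec.error_rate
                    if hit.any():
                        for pos in np.flatnonzero(hit):
                            choices = [b for b in b"ACGT" if bytes([b]) != arr[pos]]
                            arr[pos] = bytes([choices[rng.integers(3)]])
                        read = arr.tobytes().decode()
                    error_free[j] = not hit.any()
                else:
                    error_free[j] = True
                reads.append((f"{sample}:{locus.mirna_id}:{len(reads)}", read))
            for off in offsets:
                n_ef = int(np.sum((read_offsets == off) & error_free))
                truth_rows.append(
                    {
                        "mirna_id": locus.mirna_id,
                        "sample": sample,
                        "offset": int(off),
                        "n_error_free": n_ef,
                        "n_total": int(np.sum(read_offsets == off)),
                    }
                )
        reads_per_sample[sample] = reads
    truth = pd.DataFrame(truth_rows, columns=["mirna_id", "sample", "offset", "n_error_free", "n_total"])
    return reads_per_sample, truth


def simulate_count_matrix(truth: ExpressionSimTruth):
    """Draw a genes × samples NB count matrix from the planted truth.

    Counts are NB with mean = library-size-scaled gene mean (the fold change,
    plus any repression-release shift delta, applied to group 2) and the
    given dispersion; dispersion 0 degenerates to Poisson.  Returns the
    CountMatrix and the truth unchanged.
    """
    from .diffexpr import CountMatrix

    rng = _rng(truth.seed, SEED_COUNTS)
    n1, n2 = truth.group_sizes
    n_samples = n1 + n2
    if len(truth.lib_sizes) != n_samples:
        raise ValueError("lib_sizes length must equal total sample number")
    shift = np.zeros(len(truth.gene_ids))
    gene_index = {g: i for i, g in enumerate(truth.gene_ids)}
    for mirna, targets in truth.target_map.items():
        d = truth.delta.get(mirna, 0.0)
        for g in targets:
            shift[gene_index[g]] += d
    group2_mult = 2.0 ** (truth.lfc + shift)
    scale = truth.lib_sizes / np.exp(np.mean(np.log(truth.lib_sizes)))
    counts = np.empty((len(truth.gene_ids), n_samples), dtype=np.int64)
    for j in range(n_samples):
        mean_j = truth.base_mean * scale[j]
        if j >= n1:
            mean_j = mean_j * group2_mult
        if truth.dispersion == 0:
            counts[:, j] = rng.poisson(mean_j)
        else:
            r = 1.0 / truth.dispersion
            p = r / (r + mean_j)
            counts[:, j] = rng.negative_binomial(r, p)
    samples = [f"ctrl_{i + 1}" for i in range(n1)] + [f"kd_{i + 1}" for i in range(n2)]
    groups = ["control"] * n1 + ["knockdown"] * n2
    matrix = CountMatrix(
        feature_ids=list(truth.gene_ids), sample_ids=samples, counts=counts, groups=groups
    )
    return matrix, truth


def default_expression_truth(
    n_genes: int = 10000,
    base_mean_log_mu: float = 4.0,
    base_mean_log_sd: float = 1.0,
    dispersion: float = 0.1,
    group_sizes: tuple[int, int] = (3, 3),
    frac_de: float = 0.10,
    de_lfc: float = 1.0,
    lib_size_cv: float = 0.15,
    target_map: dict[str, set[str]] | None = None,
    delta: dict[str, float] | None = None,
    seed: int = 0,
) -> ExpressionSimTruth:
    """Typical bulk RNA-seq regime: log-normal gene means, NB dispersion 0.1,
    3 vs 3 replicates, 10% of genes truly changed at |LFC| = 1."""
    rng = _rng(seed, SEED_COUNTS + 1)
    gene_ids = [f"gene_{i + 1}" for i in range(n_genes)]
    base_mean = np.exp(rng.normal(base_mean_log_mu, base_mean_log_sd, size=n_genes))
    lfc = np.zeros(n_genes)
    n_de = int(round(frac_de * n_genes))
    de_idx = rng.choice(n_genes, size=n_de, replace=False)
    lfc[de_idx] = rng.choice([-de_lfc, de_lfc], size=n_de)
    n_total = sum(group_sizes)
    lib_sizes = np.exp(rng.normal(0.0, lib_size_cv, size=n_total))
    lib_sizes *= 1e6 / lib_sizes.mean()
    return ExpressionSimTruth(
        gene_ids=gene_ids,
        base_mean=base_mean,
        lfc=lfc,
        dispersion=dispersion,
        group_sizes=group_sizes,
        lib_sizes=lib_sizes,
        target_map=target_map or {},
        delta=delta or {},
        seed=seed,
    )


def simulate_clinical(
    n: int,
    auc_target: float,
    hr_target: float,
    seed: int,
    baseline_hazard: float = 0.03,
    follow_up: float = 60.0,
) -> pd.DataFrame:
    """Clinical table under a binormal score model and exponential survival.

    Cases score N(mu, 1) with mu = sqrt(2) * Phi^{-1}(AUC), controls N(0, 1),
    so the population AUC equals ``auc_target``.  Survival times are
    exponential with the hazard multiplied by ``hr_target`` for samples above
    the median expression, administratively censored at ``follow_up`` months.
    """
    if not 0.5 <= auc_target <= 1.0:
        raise ValueError("auc_target must lie in [0.5, 1.0]")
    if hr_target <= 0:
        raise ValueError("hr_target must be positive")
    rng = _rng(seed, SEED_CLINICAL)
    n_case = n // 2
    n_ctrl = n - n_case
    mu = math.sqrt(2.0) * float(ndtri(min(auc_target, 1 - 1e-12)))
    expr = np.concatenate([rng.normal(mu, 1.0, n_case), rng.normal(0.0, 1.0, n_ctrl)])
    label = np.array([1] * n_case + [0] * n_ctrl)
    high = expr > np.median(expr)
    hazard = baseline_hazard * np.where(high, hr_target, 1.0)
    t_event = rng.exponential(1.0 / hazard)
    event = (t_event <= follow_up).astype(int)
    time = np.minimum(t_event, follow_up)
    return pd.DataFrame(
        {
            "sample_id": [f"s{i + 1}" for i in range(n)],
            "expression": expr,
            "label": label,
            "time": time,
            "event": event,
        }
    )
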