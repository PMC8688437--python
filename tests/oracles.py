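"""Independent brute-force oracles used by the test suite.

Each oracle recomputes a quantity by direct enumeration or exact
arithmetic, sharing no code path with the package implementation.
"""

from __future__ import annotations

from fractions import Fraction
from math import comb

import numpy as np

from mirpipe.quant import MiRNAQuantRecord


def quantify_brute_force(alignments, counts, loci, window=3):
    """All-pairs scan over (alignment, locus); no indexing, explicit rules."""
    records = []
    for loc in loci:
        # collect every in-window (sequence, offset, genomic 5' pos) pair
        pairs = []
        for aln in alignments:
            if aln.chrom != loc.chrom or aln.strand != loc.strand:
                continue
            off = aln.five_prime_pos - loc.five_prime_pos
            if loc.strand == "-":
                off = -off
            if -window <= off <= window:
                pairs.append((aln.sequence, off, aln.five_prime_pos))
        # representative placement per sequence: closest to the annotated end,
        # upstream (more negative) on ties
        rep = {}
        for seq, off, pos in pairs:
            if seq not in rep:
                rep[seq] = (off, pos)
            else:
                old_off, _ = rep[seq]
                if abs(off) < abs(old_off) or (abs(off) == abs(old_off) and off < old_off):
                    rep[seq] = (off, pos)
        if not rep:
            records.append(MiRNAQuantRecord(loc.mirna_id, None, None, 0, []))
            continue
        # reference sequence: max count; ties to smaller |offset|, longer
        # sequence, lexicographically smaller sequence
        best = None
        for seq, (off, pos) in rep.items():
            key = (-counts[seq], abs(off), -len(seq), seq)
            if best is None or key < best[0]:
                best = (key, seq, off, pos)
        _, ref_seq, _, ref_pos = best
        abundance = sum(counts[s] for s, (_, p) in rep.items() if p == ref_pos)
        window_sequences = sorted(
            ((s, counts[s], off) for s, (off, _) in rep.items()),
            key=lambda t: (-t[1], abs(t[2]), -len(t[0]), t[0]),
        )
        records.append(
            MiRNAQuantRecord(loc.mirna_id, ref_seq, ref_pos, abundance, window_sequences)
        )
    return records


def hypergeom_upper_tail_exact(n_a: int, n_b: int, k: int, universe: int) -> float:
    """P(X >= k) by exact rational summation of the hypergeometric mass."""
    denom = comb(universe, n_b)
    total = Fraction(0)
    for j in range(max(k, max(0, n_a + n_b - universe)), min(n_a, n_b) + 1):
        total += Fraction(comb(n_a, j) * comb(universe - n_a, n_b - j), denom)
    return float(min(total, Fraction(1)))


def auc_pair_counting(scores, labels) -> float:
    """AUC as (concordant + half-tied) case/control pairs, enumerated."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    cases = scores[labels == 1]
    controls = scores[labels == 0]
    num = 0.0
    for a in cases:
        for b in controls:
            if a > b:
                num += 1.0
            elif a == b:
                num += 0.5
    return num / (len(cases) * len(controls))


def ks_statistic_brute_force(x, y) -> float:
    """sup |F1 - F2| evaluated at every data point of either sample."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    best = 0.0
    for t in np.concatenate([x, y]):
        f1 = np.mean(x <= t)
        f2 = np.mean(y <= t)
        best = max(best, abs(f1 - f2))
    return best


def bh_adjust_stepup(pvals):
    """Textbook BH step-up with monotone enforcement."""
    p = np.asarray(pvals, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    adj = np.empty(m)
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, p[i] * m / rank)
        adj[i] = running
    return adj
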