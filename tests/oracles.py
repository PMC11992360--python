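"""Independent brute-force oracles used by the test suite.

These re-derive pair-genotype probabilities by explicit enumeration of
the founders' ordered gametes, the IBD assignment, and the per-member
error channel — sharing no code with the package implementation.
"""

from __future__ import annotations

import numpy as np


def unordered_genotypes(k: int) -> list[tuple[int, int]]:
    return [(i, j) for i in range(k) for j in range(i, k)]


def hwe_prob(g: tuple[int, int], p: np.ndarray) -> float:
    i, j = g
    return float(p[i] * p[j] * (2.0 if i != j else 1.0))


def oracle_true_pair_probs(p: np.ndarray, kappa) -> dict:
    """P(T1, T2 | kappa) by enumerating ordered parental alleles and IBD states."""
    k = len(p)
    k0, k1, k2 = kappa
    out: dict[tuple, float] = {}

    def add(t1, t2, pr):
        out[(t1, t2)] = out.get((t1, t2), 0.0) + pr

    for a in range(k):
        for b in range(k):
            t1 = tuple(sorted((a, b)))
            pt1 = float(p[a] * p[b])
            if k0:
                for c in range(k):
                    for d in range(k):
                        add(t1, tuple(sorted((c, d))), k0 * pt1 * float(p[c] * p[d]))
            if k1:
                for shared in (a, b):
                    for x in range(k):
                        add(t1, tuple(sorted((shared, x))), k1 * pt1 * 0.5 * float(p[x]))
            if k2:
                add(t1, t1, k2 * pt1)
    return out


def oracle_observed_matrix(p: np.ndarray, kappa, eps: float) -> np.ndarray:
    """Observed-pair probability matrix by explicit error-channel enumeration."""
    genos = unordered_genotypes(len(p))
    gi = {g: i for i, g in enumerate(genos)}
    true = oracle_true_pair_probs(p, kappa)

    def err(o, t) -> float:
        return (1.0 - eps) * (1.0 if o == t else 0.0) + eps * hwe_prob(o, p)

    out = np.zeros((len(genos), len(genos)))
    for (t1, t2), pr in true.items():
        for o1 in genos:
            e1 = err(o1, t1)
            if e1 == 0.0:
                continue
            for o2 in genos:
                e2 = err(o2, t2)
                if e2:
                    out[gi[o1], gi[o2]] += pr * e1 * e2
    return out


def oracle_pair_probability(g1, g2, p, kappa, eps: float) -> float:
    genos = unordered_genotypes(len(p))
    gi = {g: i for i, g in enumerate(genos)}
    mat = oracle_observed_matrix(p, kappa, eps)
    return float(mat[gi[tuple(sorted(g1))], gi[tuple(sorted(g2))]])


def oracle_tail_probability_exact(
    freq_vectors: list[np.ndarray],
    kappa_num,
    kappa_den,
    eps: float,
    eta: float,
) -> float:
    """Exact P(Lambda > eta | denominator) by full enumeration over loci.

    Enumerates the Cartesian product of per-locus genotype pairs;
    feasible for one or two small loci.
    """
    per_locus = []
    for p in freq_vectors:
        num = oracle_observed_matrix(p, kappa_num, eps).ravel()
        den = oracle_observed_matrix(p, kappa_den, eps).ravel()
        with np.errstate(divide="ignore", invalid="ignore"):
            lam = np.log(num) - np.log(den)
        lam[np.isnan(lam)] = 0.0
        per_locus.append((lam, den))
    total = 0.0
    idx = [0] * len(per_locus)

    def rec(depth, lam_sum, prob):
        nonlocal total
        if prob == 0.0:
            return
        if depth == len(per_locus):
            if lam_sum > eta:
                total += prob
            return
        lam, den = per_locus[depth]
        for c in range(lam.size):
            rec(depth + 1, lam_sum + lam[c], prob * den[c])

    rec(0, 0.0, 1.0)
    return total
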