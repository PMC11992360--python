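"""Exact multiallelic genotype-pair probabilities under IBD relationship models.

A pairwise relationship is summarized by its Cotterman coefficients
(kappa0, kappa1, kappa2) — the probabilities that the pair shares 0, 1 or
2 alleles identical by descent at a locus.  The probability of a pair of
*true* genotypes at one locus is

    P(T1, T2 | kappa) = k0 P(T1) P(T2)
                      + k1 P(T1) Trans(T2 | T1)
                      + k2 P(T1) 1[T2 = T1]

with Hardy-Weinberg genotype frequencies P(.) and the one-shared-gamete
transmission kernel Trans.  Genotyping error uses the true-genotype-
independent channel: with probability epsilon an observed genotype is an
independent Hardy-Weinberg redraw,

    P(O | T) = (1 - eps) 1[O = T] + eps P_HWE(O),

applied independently to each member of the pair.  Log-likelihood ratios
sum the per-locus log ratio of the observed-pair probabilities under two
competing relationship hypotheses (e.g. PO/U), skipping loci where
either genotype is missing.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np

from .containers import MISSING, GenotypeMatrix
from .freqs import AlleleFrequencySet, LocusFrequencies


@dataclass(frozen=True)
class RelationshipModel:
    """A named relationship with Cotterman IBD coefficients."""

    name: str
    kappa: tuple[float, float, float]

    def __post_init__(self) -> None:
        k = np.asarray(self.kappa, dtype=float)
        if k.size != 3 or np.any(k < 0) or abs(k.sum() - 1.0) > 1e-9:
            raise ValueError(f"invalid kappa coefficients {self.kappa}")


SELF = RelationshipModel("SELF", (0.0, 0.0, 1.0))
PO = RelationshipModel("PO", (0.0, 1.0, 0.0))
FS = RelationshipModel("FS", (0.25, 0.5, 0.25))
HS = RelationshipModel("HS", (0.5, 0.5, 0.0))
U = RelationshipModel("U", (1.0, 0.0, 0.0))

RELATIONSHIPS: dict[str, RelationshipModel] = {
    m.name: m for m in (SELF, PO, FS, HS, U)
}


@dataclass
class LLRConfig:
    """Numerator/denominator hypotheses and error rate for a log-likelihood ratio."""

    numerator: RelationshipModel
    denominator: RelationshipModel
    epsilon: float = 0.005
    log_base: str = "e"  # "e" or "10"

    def __post_init__(self) -> None:
        if not 0.0 <= self.epsilon < 1.0:
            raise ValueError("epsilon must be in [0, 1)")
        if self.log_base not in ("e", "10"):
            raise ValueError("log_base must be 'e' or '10'")

    @property
    def log_scale(self) -> float:
        """Multiplier converting natural-log LLRs to the configured base."""
        return 1.0 if self.log_base == "e" else 1.0 / np.log(10.0)

    @property
    def name(self) -> str:
        return f"{self.numerator.name}/{self.denominator.name}"


# ---------------------------------------------------------------------------
# genotype indexing
# ---------------------------------------------------------------------------

@lru_cache(maxsize=64)
def genotype_pairs(n_alleles: int) -> tuple[tuple[int, int], ...]:
    """Unordered genotypes (i <= j) for a locus with ``n_alleles`` alleles."""
    return tuple(
        (i, j) for i in range(n_alleles) for j in range(i, n_alleles)
    )


@lru_cache(maxsize=64)
def genotype_index_table(n_alleles: int) -> np.ndarray:
    """(K, K) array mapping an allele pair to its unordered genotype index."""
    table = np.zeros((n_alleles, n_alleles), dtype=np.int32)
    for g, (i, j) in enumerate(genotype_pairs(n_alleles)):
        table[i, j] = g
        table[j, i] = g
    return table


def genotype_indices(a1: np.ndarray, a2: np.ndarray, n_alleles: int) -> np.ndarray:
    """Vectorized unordered genotype index; MISSING propagates."""
    table = genotype_index_table(n_alleles)
    out = np.full(a1.shape, MISSING, dtype=np.int32)
    called = a1 != MISSING
    out[called] = table[a1[called], a2[called]]
    return out


# ---------------------------------------------------------------------------
# per-locus probability matrices
# ---------------------------------------------------------------------------

def hwe_genotype_frequencies(p: np.ndarray) -> np.ndarray:
    """Hardy-Weinberg frequencies over unordered genotypes."""
    p = np.asarray(p, dtype=float)
    pairs = genotype_pairs(p.size)
    return np.array(
        [p[i] ** 2 if i == j else 2 * p[i] * p[j] for i, j in pairs]
    )


def transmission_matrix(p: np.ndarray) -> np.ndarray:
    """Trans[t1, t2] = P(T2 = t2 | one gamete shared IBD with genotype t1).

    The shared allele is a uniform pick of t1's two alleles; the other
    allele of t2 is an independent draw from the frequency vector.
    """
    p = np.asarray(p, dtype=float)
    pairs = genotype_pairs(p.size)
    g = len(pairs)
    index = genotype_index_table(p.size)
    trans = np.zeros((g, g))
    for t1, (a, b) in enumerate(pairs):
        for shared in (a, b):
            for x in range(p.size):
                trans[t1, index[shared, x]] += 0.5 * p[x]
    return trans


def true_pair_matrix(p: np.ndarray, model: RelationshipModel) -> np.ndarray:
    """Joint probability of unordered true-genotype pairs under a kappa model."""
    k0, k1, k2 = model.kappa
    hwe = hwe_genotype_frequencies(p)
    out = k0 * np.outer(hwe, hwe)
    if k1:
        out = out + k1 * hwe[:, None] * transmission_matrix(p)
    if k2:
        out = out + k2 * np.diag(hwe)
    return out


def observation_error_matrix(p: np.ndarray, epsilon: float) -> np.ndarray:
    """E[o, t] = P(observe genotype o | true genotype t)."""
    hwe = hwe_genotype_frequencies(p)
    g = hwe.size
    return (1.0 - epsilon) * np.eye(g) + epsilon * np.tile(hwe[:, None], (1, g))


def observed_pair_matrix(
    p: np.ndarray, model: RelationshipModel, epsilon: float = 0.0
) -> np.ndarray:
    """Joint probability of *observed* genotype pairs: error channel on each member."""
    truth = true_pair_matrix(p, model)
    if epsilon == 0.0:
        return truth
    err = observation_error_matrix(p, epsilon)
    return err @ truth @ err.T


def genotype_pair_probability(
    g1: tuple[int, int],
    g2: tuple[int, int],
    locus: LocusFrequencies | np.ndarray,
    model: RelationshipModel,
    epsilon: float = 0.0,
) -> float:
    """Probability of one observed unordered genotype pair at a locus."""
    p = locus.freqs if isinstance(locus, LocusFrequencies) else np.asarray(locus)
    index = genotype_index_table(p.size)
    mat = observed_pair_matrix(p, model, epsilon)
    return float(mat[index[g1[0], g1[1]], index[g2[0], g2[1]]])


# ---------------------------------------------------------------------------
# multilocus log-likelihood ratios
# ---------------------------------------------------------------------------

def locus_llr_table(p: np.ndarray, cfg: LLRConfig) -> np.ndarray:
    """(G, G) per-locus log ratio log[P(pair|num)/P(pair|den)] in cfg's base.

    Entries may be +/-inf when epsilon = 0 makes a pair impossible under
    one hypothesis.
    """
    num = observed_pair_matrix(p, cfg.numerator, cfg.epsilon)
    den = observed_pair_matrix(p, cfg.denominator, cfg.epsilon)
    with np.errstate(divide="ignore", invalid="ignore"):
        table = np.log(num) - np.log(den)
    # 0/0 pairs are impossible under both hypotheses; they never occur in
    # data drawn from either model, so carry 0 contribution.
    table[np.isnan(table)] = 0.0
    return table * cfg.log_scale


def llr_tables(freqs: AlleleFrequencySet, cfg: LLRConfig) -> list[np.ndarray]:
    return [locus_llr_table(l.freqs, cfg) for l in freqs]


def pair_llr(
    geno1: list[tuple[int, int] | None],
    geno2: list[tuple[int, int] | None],
    freqs: AlleleFrequencySet,
    cfg: LLRConfig,
) -> tuple[float, int]:
    """Multilocus LLR for one pair of genotype vectors.

    Genotype vectors are per-locus unordered allele-index pairs, with
    ``None`` (or a MISSING index) marking missing loci, aligned with
    ``freqs``.  Returns (Lambda, number of loci used).  Raises
    ``ValueError`` when no locus is callable in both samples.
    """
    total = 0.0
    used = 0
    for g1, g2, locus in zip(geno1, geno2, freqs):
        if g1 is None or g2 is None:
            continue
        if MISSING in g1 or MISSING in g2:
            continue
        table = locus_llr_table(locus.freqs, cfg)
        index = genotype_index_table(locus.n_alleles)
        total += table[index[g1[0], g1[1]], index[g2[0], g2[1]]]
        used += 1
    if used == 0:
        raise ValueError("no shared non-missing loci: LLR undefined")
    return float(total), used


def matrix_pair_llr(
    matrix: GenotypeMatrix,
    i: int,
    j: int,
    freqs: AlleleFrequencySet,
    cfg: LLRConfig,
    tables: list[np.ndarray] | None = None,
) -> tuple[float, int]:
    """LLR between matrix rows i and j (loci aligned with ``freqs`` by id)."""
    if tables is None:
        tables = llr_tables(freqs, cfg)
    cols = {l: c for c, l in enumerate(matrix.locus_ids)}
    total = 0.0
    used = 0
    for col, locus in enumerate(freqs):
        jcol = cols[locus.locus_id]
        a1i, a2i = matrix.a1[i, jcol], matrix.a2[i, jcol]
        a1j, a2j = matrix.a1[j, jcol], matrix.a2[j, jcol]
        if MISSING in (a1i, a1j):
            continue
        index = genotype_index_table(locus.n_alleles)
        total += tables[col][index[a1i, a2i], index[a1j, a2j]]
        used += 1
    if used == 0:
        raise ValueError("no shared non-missing loci: LLR undefined")
    return float(total), used


def count_mismatches(
    a1_i: np.ndarray,
    a2_i: np.ndarray,
    a1_j: np.ndarray,
    a2_j: np.ndarray,
) -> tuple[int, int]:
    """(mismatching loci, loci called in both) for two genotype rows."""
    both = (a1_i != MISSING) & (a1_j != MISSING)
    mism = both & ((a1_i != a1_j) | (a2_i != a2_j))
    return int(mism.sum()), int(both.sum())
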