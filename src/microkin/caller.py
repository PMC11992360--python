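"""Microhaplotype genotype calling from aligned amplicon reads, plus QC filters.

Per read r and haplotype allele a the likelihood is a product over SNP
sites of (1 - e_i) for a matching base and e_i/3 for a mismatch, with
e_i the phred-implied error probability; an N base is uninformative.
An unordered genotype {a, b} has per-read likelihood (P(r|a)+P(r|b))/2
and the call is the maximum-posterior genotype under a uniform prior.
Calls revert to missing when depth <= 20 reads, when the posterior is
below the acceptance cutoff, or when a heterozygote's minor/major
allelic depth ratio falls below 0.4.  Locus/sample filters follow the
panel-validation rules: loci missing everywhere or out of HWE in every
sample collection are dropped, then samples with more than 20% missing
genotypes are removed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import pysam
from scipy.special import gammaln, logsumexp

from .catalog import MicrohapLocus
from .containers import MISSING, GenotypeMatrix
from .kinship import genotype_pairs

_BASE_INDEX = {b: i for i, b in enumerate("ACGTN")}
N_CODE = 4


@dataclass
class CallConfig:
    """Thresholds for genotype calling and matrix QC."""

    min_depth: int = 21          # "greater than 20 reads"
    min_allele_ratio: float = 0.4
    posterior_min: float = 0.99
    max_individual_missing: float = 0.20
    min_mapq: int = 30
    hwe_alpha: float = 1e-4
    hwe_permutations: int = 10000
    ratio_filter: str = "genotype"  # or "haplotype": drop minor, keep major homozygote

    def __post_init__(self) -> None:
        if self.min_depth < 1:
            raise ValueError("min_depth must be >= 1")
        if not 0 < self.min_allele_ratio <= 1:
            raise ValueError("min_allele_ratio must be in (0, 1]")
        if self.ratio_filter not in ("genotype", "haplotype"):
            raise ValueError("ratio_filter must be 'genotype' or 'haplotype'")


@dataclass
class GenotypeCall:
    """One sample x locus call with depths and the posterior of the call."""

    a1: int
    a2: int
    depth: int
    depth_a1: int
    depth_a2: int
    posterior: float
    novel_reads: int = 0
    reason: str | None = None  # set when the call is MISSING

    @property
    def is_missing(self) -> bool:
        return self.a1 == MISSING


@dataclass
class ReadObservations:
    """Bases and phred qualities at the SNP offsets of one locus."""

    locus_id: str
    bases: np.ndarray   # (n_reads, n_snps) uint8 codes into ACGTN
    quals: np.ndarray   # (n_reads, n_snps) int16

    @property
    def n_reads(self) -> int:
        return self.bases.shape[0]


def extract_read_observations(
    sam_path,
    catalog: list[MicrohapLocus],
    cfg: CallConfig,
) -> tuple[dict[str, ReadObservations], pd.Series, int]:
    """Collect per-locus SNP-site observations from one sample's SAM file.

    Returns (observations by locus, aligned-read counts per reference
    including references absent from the catalog, count of reads whose
    reference was not in the catalog).  Reads that are unmapped, below
    the mapping-quality cutoff, or that do not cover every SNP offset
    are discarded from the observations (but mapped reads still count
    toward the per-reference totals used for sex calling).
    """
    by_id = {loc.locus_id: loc for loc in catalog}
    bases: dict[str, list[list[int]]] = {l: [] for l in by_id}
    quals: dict[str, list[list[int]]] = {l: [] for l in by_id}
    aligned = {}
    unknown_ref = 0
    with pysam.AlignmentFile(str(sam_path), "r", check_sq=False) as sam:
        for read in sam:
            if read.is_unmapped:
                continue
            ref = read.reference_name
            aligned[ref] = aligned.get(ref, 0) + 1
            if ref not in by_id:
                unknown_ref += 1
                continue
            if read.mapping_quality < cfg.min_mapq:
                continue
            loc = by_id[ref]
            seq = read.query_sequence
            qual = read.query_qualities
            start = read.reference_start
            cig = read.cigartuples
            row_b: list[int] = []
            row_q: list[int] = []
            if cig is not None and len(cig) == 1 and cig[0][0] == 0:
                # full-match fast path
                end = start + cig[0][1]
                ok = True
                for off in loc.snp_offsets:
                    if not start <= off < end:
                        ok = False
                        break
                    q = off - start
                    row_b.append(_BASE_INDEX.get(seq[q], N_CODE))
                    row_q.append(qual[q] if qual is not None else 30)
                if not ok:
                    continue
            else:
                pairs = {
                    r: q
                    for q, r in read.get_aligned_pairs(matches_only=True)
                }
                ok = True
                for off in loc.snp_offsets:
                    q = pairs.get(off)
                    if q is None:
                        ok = False
                        break
                    row_b.append(_BASE_INDEX.get(seq[q], N_CODE))
                    row_q.append(qual[q] if qual is not None else 30)
                if not ok:
                    continue
            bases[ref].append(row_b)
            quals[ref].append(row_q)
    obs = {}
    for locus_id, loc in by_id.items():
        n = len(bases[locus_id])
        obs[locus_id] = ReadObservations(
            locus_id=locus_id,
            bases=np.array(bases[locus_id], dtype=np.uint8).reshape(n, len(loc.snp_offsets)),
            quals=np.array(quals[locus_id], dtype=np.int16).reshape(n, len(loc.snp_offsets)),
        )
    return obs, pd.Series(aligned, dtype=int), unknown_ref


def call_genotype(
    obs: ReadObservations,
    locus: MicrohapLocus,
    cfg: CallConfig,
) -> GenotypeCall:
    """Maximum-posterior microhaplotype genotype for one sample x locus."""
    n = obs.n_reads
    if n < cfg.min_depth:
        return GenotypeCall(MISSING, MISSING, n, 0, 0, 0.0, reason="low_depth")

    allele_codes = np.array(
        [[_BASE_INDEX[b] for b in a] for a in locus.alleles], dtype=np.uint8
    )  # (A, s)
    e = 10.0 ** (-obs.quals / 10.0)  # (n, s)
    b = obs.bases[:, None, :]  # (n, 1, s)
    match = b == allele_codes[None, :, :]
    informative = b != N_CODE
    site = np.where(~informative, 1.0, np.where(match, 1.0 - e[:, None, :], e[:, None, :] / 3.0))
    read_allele_lik = site.prod(axis=2)  # (n, A)

    # novel haplotypes: fully observed reads whose string is not in the catalog
    full = informative[:, 0, :].all(axis=1)
    catalog_keys = {tuple(row) for row in allele_codes}
    novel = sum(
        1
        for i in range(n)
        if full[i] and tuple(obs.bases[i]) not in catalog_keys
    )

    pairs = genotype_pairs(len(locus.alleles))
    loglik = np.array(
        [
            np.log(0.5 * read_allele_lik[:, i] + 0.5 * read_allele_lik[:, j]).sum()
            for i, j in pairs
        ]
    )
    post = np.exp(loglik - logsumexp(loglik))
    best = int(np.argmax(post))
    a1, a2 = pairs[best]
    posterior = float(post[best])

    assign = np.argmax(read_allele_lik, axis=1)
    d1 = int(np.sum(assign == a1))
    d2 = d1 if a2 == a1 else int(np.sum(assign == a2))

    if posterior < cfg.posterior_min:
        return GenotypeCall(
            MISSING, MISSING, n, d1, d2, posterior, novel, reason="low_posterior"
        )
    if a1 != a2:
        hi, lo = max(d1, d2), min(d1, d2)
        ratio = lo / hi if hi > 0 else 0.0
        if ratio < cfg.min_allele_ratio:
            if cfg.ratio_filter == "haplotype":
                major = a1 if d1 >= d2 else a2
                dmaj = max(d1, d2)
                return GenotypeCall(major, major, n, dmaj, dmaj, posterior, novel)
            return GenotypeCall(
                MISSING, MISSING, n, d1, d2, posterior, novel, reason="allele_ratio"
            )
    return GenotypeCall(a1, a2, n, d1, d2, posterior, novel)


def call_sample(
    sam_path,
    catalog: list[MicrohapLocus],
    cfg: CallConfig,
) -> tuple[dict[str, GenotypeCall], pd.Series]:
    """Extract observations and call every catalog locus for one sample."""
    obs, aligned, _ = extract_read_observations(sam_path, catalog, cfg)
    calls = {loc.locus_id: call_genotype(obs[loc.locus_id], loc, cfg) for loc in catalog}
    return calls, aligned


def call_genotype_matrix(
    sam_paths: dict[str, object],
    catalog: list[MicrohapLocus],
    cfg: CallConfig | None = None,
    groups: dict[str, str] | None = None,
) -> tuple[GenotypeMatrix, pd.DataFrame]:
    """Call genotypes for a cohort of per-sample SAM files.

    Returns the genotype matrix over all catalog loci plus a read-count
    table (sample_id, locus_id, n_reads of aligned reads) usable for
    sex calling.
    """
    cfg = cfg or CallConfig()
    sample_ids = list(sam_paths)
    locus_ids = [loc.locus_id for loc in catalog]
    shape = (len(sample_ids), len(locus_ids))
    a1 = np.full(shape, MISSING, dtype=np.int32)
    a2 = np.full(shape, MISSING, dtype=np.int32)
    dt = np.zeros(shape, dtype=np.int32)
    d1 = np.zeros(shape, dtype=np.int32)
    d2 = np.zeros(shape, dtype=np.int32)
    count_rows = []
    for i, sample in enumerate(sample_ids):
        calls, aligned = call_sample(sam_paths[sample], catalog, cfg)
        for j, locus_id in enumerate(locus_ids):
            call = calls[locus_id]
            a1[i, j], a2[i, j] = call.a1, call.a2
            dt[i, j] = call.depth
            d1[i, j], d2[i, j] = call.depth_a1, call.depth_a2
            count_rows.append((sample, locus_id, int(aligned.get(locus_id, 0))))
    matrix = GenotypeMatrix(
        sample_ids=sample_ids,
        locus_ids=locus_ids,
        a1=a1,
        a2=a2,
        allele_labels=[list(loc.alleles) for loc in catalog],
        groups=groups,
        depth_total=dt,
        depth_a1=d1,
        depth_a2=d2,
    )
    counts = pd.DataFrame(count_rows, columns=["sample_id", "locus_id", "n_reads"])
    return matrix, counts


# ---------------------------------------------------------------------------
# Hardy-Weinberg Monte-Carlo exact test
# ---------------------------------------------------------------------------

def hwe_exact_test_mc(
    a1: np.ndarray,
    a2: np.ndarray,
    n_perm: int = 10000,
    seed: int = 0,
) -> float:
    """Monte-Carlo exact test of Hardy-Weinberg proportions.

    The test statistic is the conditional probability of the genotype
    table given the allele counts (multivariate hypergeometric form);
    the null is sampled by pooling the 2N alleles, shuffling, and
    re-pairing.  p = (1 + #{permuted tables at most as probable}) /
    (n_perm + 1).  Monomorphic input returns 1 by convention.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    a1 = np.asarray(a1)
    a2 = np.asarray(a2)
    called = (a1 != MISSING) & (a2 != MISSING)
    a1, a2 = a1[called], a2[called]
    n = a1.size
    if n < 2:
        return 1.0
    pool = np.concatenate([a1, a2])
    if np.unique(pool).size < 2:
        return 1.0

    k = int(pool.max()) + 1

    def log_stat(x1: np.ndarray, x2: np.ndarray) -> float:
        # log conditional probability up to terms fixed by the allele counts
        lo = np.minimum(x1, x2)
        hi = np.maximum(x1, x2)
        codes = lo * k + hi
        _, counts = np.unique(codes, return_counts=True)
        het = int(np.sum(lo != hi))
        return float(het * np.log(2.0) - gammaln(counts + 1).sum())

    obs = log_stat(a1, a2)
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_perm):
        perm = rng.permutation(pool)
        if log_stat(perm[:n], perm[n:]) <= obs + 1e-12:
            hits += 1
    return (1 + hits) / (n_perm + 1)


def filter_genotype_matrix(
    matrix: GenotypeMatrix,
    cfg: CallConfig | None = None,
    groups: dict[str, str] | None = None,
    seed: int = 0,
) -> tuple[GenotypeMatrix, pd.DataFrame, pd.DataFrame]:
    """Locus-then-sample QC filtering.

    Removes loci missing in every sample, then loci out of HWE
    (p < ``hwe_alpha``) in *every* sample collection, then samples with
    more than ``max_individual_missing`` missing genotypes.  Returns the
    filtered matrix, a removal report, and the per-locus x group HWE
    p-value table.
    """
    cfg = cfg or CallConfig()
    groups = groups or matrix.groups or {s: "all" for s in matrix.sample_ids}
    group_names = sorted(set(groups.values()))
    group_rows = {
        g: [i for i, s in enumerate(matrix.sample_ids) if groups[s] == g]
        for g in group_names
    }
    report = []
    keep_loci = []
    hwe_rows = []
    for j, locus_id in enumerate(matrix.locus_ids):
        if (matrix.a1[:, j] == MISSING).all():
            report.append({"kind": "locus", "id": locus_id, "reason": "all_missing"})
            continue
        pvals = {}
        for gi, g in enumerate(group_names):
            rows = group_rows[g]
            pvals[g] = hwe_exact_test_mc(
                matrix.a1[rows, j],
                matrix.a2[rows, j],
                n_perm=cfg.hwe_permutations,
                seed=seed + 7919 * j + gi,
            )
        hwe_rows.append({"locus_id": locus_id, **pvals})
        if all(p < cfg.hwe_alpha for p in pvals.values()):
            report.append({"kind": "locus", "id": locus_id, "reason": "hwe_all_groups"})
            continue
        keep_loci.append(locus_id)
    filtered = matrix.subset(loci=keep_loci)
    keep_samples = []
    for s, frac in filtered.missing_fraction_per_sample().items():
        if frac > cfg.max_individual_missing:
            report.append(
                {"kind": "sample", "id": s, "reason": f"missing_{frac:.3f}"}
            )
        else:
            keep_samples.append(s)
    filtered = filtered.subset(samples=keep_samples)
    if filtered.n_samples == 0 or filtered.n_loci == 0:
        report.append({"kind": "status", "id": "", "reason": "empty_after_filtering"})
    return filtered, pd.DataFrame(report), pd.DataFrame(hwe_rows)
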