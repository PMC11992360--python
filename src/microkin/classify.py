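"""Hierarchical relationship classification, duplicate detection, sex calling.

The decision procedure mirrors the panel-validation workflow: samples
with nearly identical genotypes (at most a fixed number of mismatching
loci) are collapsed into individuals; individual pairs passing either
the PO/U or FS/U threshold are flagged as related; related pairs with
PO/FS above the fixed cutoff are parent-offspring, otherwise FS/HS
above its threshold makes them full siblings, and the remainder are
left as ambiguous second-order relatives.  Sex is called from the
fraction of reads aligning to the male-specific SRY amplicon.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .containers import MISSING, GenotypeMatrix
from .freqs import AlleleFrequencySet
from .kinship import (
    RELATIONSHIPS,
    LLRConfig,
    count_mismatches,
    genotype_indices,
    llr_tables,
)
from .power import COMPARISONS, ThresholdTable

LABELS = (
    "SAME_INDIVIDUAL",
    "PO",
    "FS",
    "AMBIGUOUS_SECOND_ORDER",
    "UNRELATED",
    "UNEVALUABLE",
)


@dataclass
class ClassifierConfig:
    """Thresholds and guards for duplicate detection and classification."""

    thresholds: ThresholdTable
    max_mismatches: int = 10
    po_fs_threshold: float = 3.0
    min_overlap_fraction: float = 0.5
    epsilon: float = 0.005
    log_base: str = "e"

    def __post_init__(self) -> None:
        if self.max_mismatches < 0:
            raise ValueError("max_mismatches must be >= 0")


@dataclass
class PairResult:
    id1: str
    id2: str
    n_loci: int
    mismatches: int
    llrs: dict[str, float]
    label: str


# ---------------------------------------------------------------------------
# duplicates -> individuals
# ---------------------------------------------------------------------------

@dataclass
class DuplicateResult:
    sample_to_individual: dict[str, str]
    individuals: list[str]
    consensus: GenotypeMatrix
    low_overlap_pairs: list[tuple[str, str]]
    mismatch_table: pd.DataFrame


def find_duplicates(
    matrix: GenotypeMatrix, cfg: ClassifierConfig
) -> DuplicateResult:
    """Collapse samples into individuals by close genotype matching.

    Sample pairs with at most ``max_mismatches`` mismatching loci are
    joined; individuals are the connected components.  Pairs below the
    shared-loci overlap guard are flagged instead of joined.  Consensus
    genotypes take the per-locus majority across an individual's
    samples, with ties set to missing.
    """
    n = matrix.n_samples
    graph = nx.Graph()
    graph.add_nodes_from(matrix.sample_ids)
    low_overlap = []
    rows = []
    for i in range(n):
        for j in range(i + 1, n):
            mism, shared = count_mismatches(
                matrix.a1[i], matrix.a2[i], matrix.a1[j], matrix.a2[j]
            )
            if mism <= cfg.max_mismatches:
                overlap = shared / matrix.n_loci if matrix.n_loci else 0.0
                if overlap < cfg.min_overlap_fraction:
                    low_overlap.append((matrix.sample_ids[i], matrix.sample_ids[j]))
                else:
                    graph.add_edge(matrix.sample_ids[i], matrix.sample_ids[j])
                rows.append(
                    (matrix.sample_ids[i], matrix.sample_ids[j], mism, shared)
                )
    mapping = {}
    individuals = []
    components = sorted(nx.connected_components(graph), key=lambda c: min(
        matrix.sample_ids.index(s) for s in c
    ))
    for k, comp in enumerate(components, start=1):
        ind = f"IND{k:03d}"
        individuals.append(ind)
        for s in comp:
            mapping[s] = ind
    consensus = consensus_genotypes(matrix, mapping, individuals)
    return DuplicateResult(
        sample_to_individual=mapping,
        individuals=individuals,
        consensus=consensus,
        low_overlap_pairs=low_overlap,
        mismatch_table=pd.DataFrame(
            rows, columns=["sample1", "sample2", "mismatches", "shared_loci"]
        ),
    )


def consensus_genotypes(
    matrix: GenotypeMatrix,
    mapping: dict[str, str],
    individuals: list[str] | None = None,
) -> GenotypeMatrix:
    """Per-locus majority genotype across each individual's samples (ties -> missing)."""
    if individuals is None:
        individuals = sorted(set(mapping.values()))
    members = {ind: [] for ind in individuals}
    for i, s in enumerate(matrix.sample_ids):
        members[mapping[s]].append(i)
    shape = (len(individuals), matrix.n_loci)
    a1 = np.full(shape, MISSING, dtype=np.int32)
    a2 = np.full(shape, MISSING, dtype=np.int32)
    for r, ind in enumerate(individuals):
        rows = members[ind]
        for j in range(matrix.n_loci):
            votes = Counter(
                (int(matrix.a1[i, j]), int(matrix.a2[i, j]))
                for i in rows
                if matrix.a1[i, j] != MISSING
            )
            if not votes:
                continue
            ranked = votes.most_common()
            if len(ranked) > 1 and ranked[0][1] == ranked[1][1]:
                continue  # tie -> missing
            a1[r, j], a2[r, j] = ranked[0][0]
    return GenotypeMatrix(
        sample_ids=list(individuals),
        locus_ids=list(matrix.locus_ids),
        a1=a1,
        a2=a2,
        allele_labels=matrix.allele_labels,
    )


# ---------------------------------------------------------------------------
# relationship classification
# ---------------------------------------------------------------------------

def apply_decision_rule(
    llrs: dict[str, np.ndarray],
    thresholds: ThresholdTable,
    po_fs_threshold: float = 3.0,
) -> np.ndarray:
    """Vectorized hierarchical labels from per-comparison LLR arrays.

    ``llrs`` maps comparison names ("PO/U", "FS/U", "FS/HS", "PO/FS")
    to aligned arrays.  The relatedness gate is an OR of the PO/U and
    FS/U exceedances.
    """
    po_u = np.asarray(llrs["PO/U"], dtype=float)
    fs_u = np.asarray(llrs["FS/U"], dtype=float)
    po_fs = np.asarray(llrs["PO/FS"], dtype=float)
    fs_hs = np.asarray(llrs["FS/HS"], dtype=float)
    related = (po_u > thresholds.eta("PO/U")) | (fs_u > thresholds.eta("FS/U"))
    labels = np.full(po_u.shape, "UNRELATED", dtype=object)
    is_po = related & (po_fs > po_fs_threshold)
    is_fs = related & ~is_po & (fs_hs > thresholds.eta("FS/HS"))
    ambiguous = related & ~is_po & ~is_fs
    labels[is_po] = "PO"
    labels[is_fs] = "FS"
    labels[ambiguous] = "AMBIGUOUS_SECOND_ORDER"
    return labels


def classify_relationships(
    matrix: GenotypeMatrix,
    freqs: AlleleFrequencySet,
    cfg: ClassifierConfig,
) -> list[PairResult]:
    """Classify every pair of individuals in a genotype matrix.

    Records all five LLRs per pair; pairs with no shared called locus
    are labeled UNEVALUABLE, and pairs within the duplicate mismatch
    allowance are labeled SAME_INDIVIDUAL before the LLR rules apply.
    """
    order = [l for l in freqs.locus_ids if l in set(matrix.locus_ids)]
    fsub = freqs.subset(order)
    msub = matrix.subset(loci=order)

    comparisons = ["/".join(c) for c in COMPARISONS]
    tables = {}
    for comp in comparisons:
        num, den = comp.split("/")
        llr_cfg = LLRConfig(
            RELATIONSHIPS[num],
            RELATIONSHIPS[den],
            epsilon=cfg.epsilon,
            log_base=cfg.log_base,
        )
        tables[comp] = llr_tables(fsub, llr_cfg)

    # per-locus genotype indices and flattened lookup tables
    n_loci = len(fsub)
    gidx = np.zeros((msub.n_samples, n_loci), dtype=np.int64)
    sizes = np.zeros(n_loci, dtype=np.int64)
    for j, locus in enumerate(fsub):
        gidx[:, j] = genotype_indices(msub.a1[:, j], msub.a2[:, j], locus.n_alleles)
        sizes[j] = len(tables[comparisons[0]][j])
    offsets = np.concatenate([[0], np.cumsum(sizes**2)[:-1]])
    flat = {c: np.concatenate([t.ravel() for t in tables[c]]) for c in comparisons}

    results = []
    for i in range(msub.n_samples):
        for j in range(i + 1, msub.n_samples):
            both = (gidx[i] != MISSING) & (gidx[j] != MISSING)
            n_used = int(both.sum())
            mism, _ = count_mismatches(
                msub.a1[i], msub.a2[i], msub.a1[j], msub.a2[j]
            )
            if n_used == 0:
                results.append(
                    PairResult(
                        msub.sample_ids[i], msub.sample_ids[j],
                        0, mism, {}, "UNEVALUABLE",
                    )
                )
                continue
            idx = offsets[both] + gidx[i, both] * sizes[both] + gidx[j, both]
            llrs = {c: float(flat[c][idx].sum()) for c in comparisons}
            overlap = n_used / msub.n_loci
            if mism <= cfg.max_mismatches and overlap >= cfg.min_overlap_fraction:
                label = "SAME_INDIVIDUAL"
            else:
                label = str(
                    apply_decision_rule(
                        {c: np.array([llrs[c]]) for c in comparisons if c != "SELF/U"},
                        cfg.thresholds,
                        cfg.po_fs_threshold,
                    )[0]
                )
            results.append(
                PairResult(
                    msub.sample_ids[i], msub.sample_ids[j],
                    n_used, mism, llrs, label,
                )
            )
    return results


def pair_results_frame(results: list[PairResult]) -> pd.DataFrame:
    rows = []
    for r in results:
        row = {"id1": r.id1, "id2": r.id2, "n_loci": r.n_loci,
               "mismatches": r.mismatches, "label": r.label}
        for comp, v in r.llrs.items():
            row[f"llr_{comp.replace('/', '_')}"] = v
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# sex calling
# ---------------------------------------------------------------------------

@dataclass
class SexCallConfig:
    """Male iff strictly more than this fraction of reads align to SRY."""

    sry_fraction_threshold: float = 1e-4
    sry_locus_id: str = "SRY"

    def __post_init__(self) -> None:
        if not 0.0 < self.sry_fraction_threshold < 1.0:
            raise ValueError("sry_fraction_threshold must be in (0, 1)")


def call_sex(
    totals: pd.DataFrame, cfg: SexCallConfig | None = None
) -> dict[str, str]:
    """Sex per sample from total and SRY-aligned read counts.

    ``totals`` needs columns sample_id, total_reads, sry_reads.  Samples
    with zero total reads are UNKNOWN; the threshold is a strict
    inequality ("more than").
    """
    cfg = cfg or SexCallConfig()
    out = {}
    for rec in totals.itertuples(index=False):
        if rec.total_reads <= 0:
            out[rec.sample_id] = "UNKNOWN"
        elif rec.sry_reads / rec.total_reads > cfg.sry_fraction_threshold:
            out[rec.sample_id] = "M"
        else:
            out[rec.sample_id] = "F"
    return out


# ---------------------------------------------------------------------------
# family networks
# ---------------------------------------------------------------------------

def build_family_network(
    results: list[PairResult],
    metadata: dict[str, dict] | None = None,
) -> nx.Graph:
    """Undirected graph of PO and FS edges; nodes carry sex and sample counts.

    Connected components are the families; the component list is stored
    on ``graph.graph["families"]``.
    """
    graph = nx.Graph()
    ids = set()
    for r in results:
        ids.update((r.id1, r.id2))
    for ind in sorted(ids):
        attrs = (metadata or {}).get(ind, {})
        graph.add_node(ind, **attrs)
    for r in results:
        if r.label in ("PO", "FS"):
            graph.add_edge(r.id1, r.id2, relationship=r.label)
    graph.graph["families"] = [sorted(c) for c in nx.connected_components(graph) if len(c) > 1]
    return graph
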