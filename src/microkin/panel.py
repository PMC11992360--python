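"""Candidate microhaplotype locus selection from a population VCF.

Selection keeps biallelic SNPs with high global and per-group minor
allele frequency, high call rate, and positions away from the ends of
their source (RAD) reads; surviving SNPs within a short window on one
scaffold are bundled into one candidate microhaplotype locus; loci are
then spaced along each scaffold to limit physical linkage.  A consensus
amplicon (major alleles substituted into the reference) is extracted
around each locus.  The module also hosts the individual-multilocus-
heterozygosity contamination screen applied to the discovery cohort.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from cyvcf2 import VCF
from pyfaidx import Fasta

from .catalog import MicrohapLocus
from .containers import MISSING, GenotypeMatrix


class ConsistencyError(ValueError):
    """VCF and reference FASTA disagree at a SNP position."""


@dataclass
class PanelCriteria:
    """Frequency, call-rate, proximity and spacing rules for SNP selection."""

    maf_global_min: float = 0.35
    maf_group_min: float = 0.25
    call_rate_min: float = 0.95
    snp_cluster_window: int = 20
    end_avoid_margin: int = 10
    flank: int = 50
    min_locus_spacing: int = 30000
    read_length: int = 140

    def __post_init__(self) -> None:
        for name in ("maf_global_min", "maf_group_min"):
            v = getattr(self, name)
            if not 0.0 < v <= 0.5:
                raise ValueError(f"{name} must be in (0, 0.5]")
        if not 0.0 < self.call_rate_min <= 1.0:
            raise ValueError("call_rate_min must be in (0, 1]")
        for name in ("snp_cluster_window", "flank", "min_locus_spacing", "read_length"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class HetScreenConfig:
    """Contamination screen: flag samples with outlying multilocus heterozygosity."""

    sd_multiplier: float = 2.0
    side: str = "above"  # or "two_sided"

    def __post_init__(self) -> None:
        if self.sd_multiplier <= 0:
            raise ValueError("sd_multiplier must be > 0")
        if self.side not in ("above", "two_sided"):
            raise ValueError("side must be 'above' or 'two_sided'")


@dataclass
class HetScreenResult:
    retained: list[str]
    flagged: list[str]
    uncomputable: list[str]
    h_i: pd.Series
    mean: float
    sd: float


def screen_heterozygosity(
    matrix: GenotypeMatrix, cfg: HetScreenConfig | None = None
) -> HetScreenResult:
    """Individual multilocus heterozygosity H_I screen.

    H_I = heterozygous calls / non-missing calls per sample; samples
    beyond ``sd_multiplier`` standard deviations of the overall mean
    (computed over all samples before any removal) are flagged.  Samples
    with no called locus are reported as uncomputable, not flagged.
    """
    cfg = cfg or HetScreenConfig()
    called = matrix.a1 != MISSING
    het = called & (matrix.a1 != matrix.a2)
    n_called = called.sum(axis=1)
    uncomputable = [s for s, n in zip(matrix.sample_ids, n_called) if n == 0]
    with np.errstate(invalid="ignore", divide="ignore"):
        h = np.where(n_called > 0, het.sum(axis=1) / n_called, np.nan)
    h_i = pd.Series(h, index=matrix.sample_ids, name="H_I")
    valid = h_i.dropna()
    if valid.size < 3:
        raise ValueError("need >= 3 samples with at least one called locus")
    mean, sd = float(valid.mean()), float(valid.std(ddof=0))
    if cfg.side == "above":
        out = valid.index[valid > mean + cfg.sd_multiplier * sd]
    else:
        out = valid.index[np.abs(valid - mean) > cfg.sd_multiplier * sd]
    flagged = list(out)
    retained = [s for s in matrix.sample_ids if s not in set(flagged) and s not in set(uncomputable)]
    return HetScreenResult(
        retained=retained,
        flagged=flagged,
        uncomputable=uncomputable,
        h_i=h_i,
        mean=mean,
        sd=sd,
    )


# ---------------------------------------------------------------------------
# MAF table
# ---------------------------------------------------------------------------

_STACKS_ID = re.compile(r"^\d+:(\d+)(?::[+-])?$")


def _read_offset_from_id(vcf_id: str | None) -> float:
    """Within-read 0-based column parsed from a Stacks-style ID, else NaN."""
    if not vcf_id:
        return float("nan")
    m = _STACKS_ID.match(vcf_id)
    return float(m.group(1)) if m else float("nan")


def compute_maf_table(
    vcf_path, group_labels: dict[str, str]
) -> pd.DataFrame:
    """Per-SNP global MAF, per-group MAF, and call rate from a VCF.

    Only biallelic SNP records are tabulated.  MAF is computed from
    called alleles only; call rate is called samples / total samples.
    Every VCF sample must appear in ``group_labels``.
    """
    vcf = VCF(str(vcf_path))
    samples = vcf.samples
    missing_labels = [s for s in samples if s not in group_labels]
    if missing_labels:
        raise ValueError(f"samples missing from group map: {missing_labels}")
    group_names = sorted(set(group_labels[s] for s in samples))
    group_cols = {
        g: np.array([i for i, s in enumerate(samples) if group_labels[s] == g])
        for g in group_names
    }
    rows = []
    for var in vcf:
        if len(var.ALT) != 1:
            continue
        if len(var.REF) != 1 or len(var.ALT[0]) != 1:
            continue
        if var.REF not in "ACGT" or var.ALT[0] not in "ACGT":
            continue
        gt = np.asarray(var.gt_types)  # 0 hom-ref, 1 het, 2 unknown, 3 hom-alt
        called = gt != 2
        alt_counts = np.where(gt == 1, 1, np.where(gt == 3, 2, 0))

        def maf(mask: np.ndarray) -> float:
            n = int(mask.sum())
            if n == 0:
                return float("nan")
            f = alt_counts[mask].sum() / (2 * n)
            return float(min(f, 1 - f))

        row = {
            "scaffold": var.CHROM,
            "pos": var.POS,
            "id": var.ID,
            "ref": var.REF,
            "alt": var.ALT[0],
            "alt_freq": (
                float(alt_counts[called].sum() / (2 * called.sum()))
                if called.any()
                else float("nan")
            ),
            "global_maf": maf(called),
            "call_rate": float(called.mean()),
            "read_offset": _read_offset_from_id(var.ID),
        }
        for g, cols in group_cols.items():
            gmask = np.zeros(len(samples), dtype=bool)
            gmask[cols] = True
            row[f"maf_{g}"] = maf(gmask & called)
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# locus selection
# ---------------------------------------------------------------------------

@dataclass
class CandidateLocus:
    """A cluster of nearby selected SNPs forming one candidate amplicon."""

    scaffold: str
    snp_positions: list[int]           # 1-based VCF coordinates, increasing
    snp_refs: list[str]
    snp_alts: list[str]
    snp_major: list[str]
    global_mafs: list[float]
    group_mafs: dict[str, list[float]]
    consensus_sequence: str | None = None
    snp_offsets: list[int] | None = None  # 0-based within the amplicon
    amplicon_start: int | None = None     # 1-based scaffold coordinate
    truncated: bool = False

    @property
    def locus_id(self) -> str:
        return f"{self.scaffold}_{self.snp_positions[0]}"

    @property
    def span(self) -> tuple[int, int]:
        return self.snp_positions[0], self.snp_positions[-1]

    @property
    def min_group_maf(self) -> float:
        return min(min(v) for v in self.group_mafs.values())


def snp_pass_table(maf_table: pd.DataFrame, criteria: PanelCriteria) -> pd.DataFrame:
    """Per-SNP pass/fail flags for each selection criterion."""
    df = maf_table.copy()
    group_cols = [c for c in df.columns if c.startswith("maf_")]
    df["pass_global"] = df["global_maf"] > criteria.maf_global_min
    df["pass_group"] = (df[group_cols] > criteria.maf_group_min).all(axis=1)
    df["pass_call_rate"] = df["call_rate"] >= criteria.call_rate_min
    off = df["read_offset"]
    end_dist = np.minimum(off, criteria.read_length - 1 - off)
    # SNPs without a parseable read offset cannot be end-filtered; they pass
    df["pass_ends"] = np.where(off.isna(), True, end_dist > criteria.end_avoid_margin)
    df["pass_all"] = (
        df["pass_global"] & df["pass_group"] & df["pass_call_rate"] & df["pass_ends"]
    )
    return df


def select_panel_loci(
    maf_table: pd.DataFrame, criteria: PanelCriteria | None = None
) -> list[CandidateLocus]:
    """Apply the SNP predicates, cluster survivors, and enforce locus spacing.

    Surviving SNPs on one scaffold whose pairwise span is at most the
    cluster window merge into one candidate locus (greedy left-to-right);
    spacing conflicts are resolved keeping the locus with the highest
    minimum per-group MAF, leftmost on ties.
    """
    criteria = criteria or PanelCriteria()
    flagged = snp_pass_table(maf_table, criteria)
    passed = flagged[flagged["pass_all"]]
    group_cols = [c for c in maf_table.columns if c.startswith("maf_")]

    loci: list[CandidateLocus] = []
    for scaffold, sub in passed.groupby("scaffold", sort=True):
        sub = sub.sort_values("pos")
        cluster: list[pd.Series] = []

        def flush():
            if not cluster:
                return
            loci.append(
                CandidateLocus(
                    scaffold=scaffold,
                    snp_positions=[int(r["pos"]) for r in cluster],
                    snp_refs=[r["ref"] for r in cluster],
                    snp_alts=[r["alt"] for r in cluster],
                    snp_major=[
                        r["alt"] if r["alt_freq"] > 0.5 else r["ref"] for r in cluster
                    ],
                    global_mafs=[float(r["global_maf"]) for r in cluster],
                    group_mafs={
                        c[len("maf_"):]: [float(r[c]) for r in cluster]
                        for c in group_cols
                    },
                )
            )

        for _, row in sub.iterrows():
            if cluster and row["pos"] - cluster[0]["pos"] > criteria.snp_cluster_window:
                flush()
                cluster = []
            cluster.append(row)
        flush()

    # greedy spacing: best min-group-MAF first, leftmost on ties
    selected: list[CandidateLocus] = []
    order = sorted(loci, key=lambda l: (-l.min_group_maf, l.scaffold, l.span[0]))
    for loc in order:
        lo, hi = loc.span
        conflict = any(
            o.scaffold == loc.scaffold
            and max(0, max(lo, o.span[0]) - min(hi, o.span[1])) < criteria.min_locus_spacing
            for o in selected
        )
        if not conflict:
            selected.append(loc)
    selected.sort(key=lambda l: (l.scaffold, l.span[0]))
    return selected


def extract_amplicon_consensus(
    fasta_path, locus: CandidateLocus, criteria: PanelCriteria | None = None
) -> CandidateLocus:
    """Reference subsequence around the locus with major alleles substituted.

    The amplicon spans [min_pos - flank, max_pos + flank] (1-based,
    inclusive), clipped with a truncation flag at scaffold edges.
    Raises :class:`ConsistencyError` when the reference base at a SNP
    differs from the VCF REF allele.
    """
    criteria = criteria or PanelCriteria()
    fasta = fasta_path if isinstance(fasta_path, Fasta) else Fasta(str(fasta_path))
    if locus.scaffold not in fasta:
        raise KeyError(f"scaffold {locus.scaffold} absent from reference")
    scaffold_len = len(fasta[locus.scaffold])
    lo, hi = locus.span
    start = lo - criteria.flank
    end = hi + criteria.flank
    truncated = start < 1 or end > scaffold_len
    start = max(1, start)
    end = min(scaffold_len, end)
    seq = list(str(fasta[locus.scaffold][start - 1 : end]).upper())
    offsets = []
    for pos, ref, major in zip(locus.snp_positions, locus.snp_refs, locus.snp_major):
        off = pos - start
        if seq[off] != ref.upper():
            raise ConsistencyError(
                f"{locus.scaffold}:{pos} reference base {seq[off]} != VCF REF {ref}"
            )
        seq[off] = major
        offsets.append(off)
    return replace(
        locus,
        consensus_sequence="".join(seq),
        snp_offsets=offsets,
        amplicon_start=start,
        truncated=truncated,
    )


def candidate_to_catalog_locus(locus: CandidateLocus) -> MicrohapLocus:
    """Convert a consensus-bearing candidate into a catalog entry.

    Haplotype alleles are the Cartesian product of each SNP's two
    alleles — the observable haplotype catalog before any read-based
    pruning.
    """
    if locus.consensus_sequence is None:
        raise ValueError("extract consensus before building a catalog entry")
    alleles = [""]
    for ref, alt in zip(locus.snp_refs, locus.snp_alts):
        alleles = [a + b for a in alleles for b in (ref, alt)]
    return MicrohapLocus(
        locus_id=locus.locus_id,
        scaffold=locus.scaffold,
        amplicon_start=int(locus.amplicon_start),
        snp_offsets=list(locus.snp_offsets),
        alleles=alleles,
        amplicon_length=len(locus.consensus_sequence),
        sequence=locus.consensus_sequence,
    )


def design_panel(
    vcf_path,
    fasta_path,
    group_labels: dict[str, str],
    criteria: PanelCriteria | None = None,
) -> tuple[list[MicrohapLocus], pd.DataFrame]:
    """VCF + reference -> amplicon catalog and a per-SNP selection report."""
    criteria = criteria or PanelCriteria()
    maf_table = compute_maf_table(vcf_path, group_labels)
    report = snp_pass_table(maf_table, criteria)
    loci = select_panel_loci(maf_table, criteria)
    fasta = Fasta(str(fasta_path))
    catalog = [
        candidate_to_catalog_locus(extract_amplicon_consensus(fasta, loc, criteria))
        for loc in loci
    ]
    return catalog, report
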