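"""Synthetic GT-seq data with the statistical structure the analysis assumes.

The generator produces, in order of the pipeline: (1) per-locus allele
frequencies for a microhaplotype panel calibrated to a target mean
expected heterozygosity; (2) pedigrees with Mendelian transmission and
a ground-truth table of pairwise relationships; (3) a true-genotype-
independent genotyping-error layer; (4) amplicon reads in SAM, with
negative-binomial depth, phred-scaled substitution errors, and a
male-specific SRY amplicon; (5) a bundled validation scenario shaped
like a small urban bear study (82 samples from 36 individuals with
recaptures, a matriarch-centred multigenerational family, and an
unrelated harvest-like cohort).
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import gammaincinv

from .catalog import MicrohapLocus, write_catalog
from .containers import MISSING, GenotypeMatrix
from .freqs import AlleleFrequencySet, LocusFrequencies

BASES = "ACGT"


class CalibrationError(ValueError):
    """Target mean heterozygosity not achievable under the panel constraints."""


# ---------------------------------------------------------------------------
# allele frequencies
# ---------------------------------------------------------------------------

@dataclass
class PanelSpec:
    """Specification of a synthetic microhaplotype panel.

    Defaults reflect a GT-seq kinship panel: 170 loci carrying 2-8
    haplotype alleles each, with mean expected heterozygosity 0.46.
    """

    n_loci: int = 170
    allele_count_range: tuple[int, int] = (2, 8)
    target_mean_he: float = 0.46
    he_tolerance: float = 0.02
    concentration: float | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.allele_count_range
        if self.n_loci < 1:
            raise ValueError("n_loci must be >= 1")
        if not (2 <= lo <= hi <= 32):
            raise ValueError("allele_count_range must lie within [2, 32]")
        if not 0.0 < self.target_mean_he < 1.0:
            raise ValueError("target_mean_he must be in (0, 1)")
        if self.concentration is not None and self.concentration <= 0:
            raise ValueError("concentration must be > 0")


def _haplotype_labels(n_alleles: int, rng: np.random.Generator) -> list[str]:
    """Distinct haplotype strings over ACGT, one base per SNP site."""
    n_snps = max(1, math.ceil(math.log(n_alleles, 4)))
    # use enough sites that 4**n_snps >= n_alleles, preferring >=2 variants/site
    while 4**n_snps < n_alleles:
        n_snps += 1
    codes = rng.choice(4**n_snps, size=n_alleles, replace=False)
    labels = []
    for c in codes:
        s = ""
        for _ in range(n_snps):
            s = BASES[c % 4] + s
            c //= 4
        labels.append(s)
    return labels


def _dirichlet_from_uniforms(u: np.ndarray, v: np.ndarray, alpha: float) -> np.ndarray:
    """Symmetric Dirichlet draw via inverse-CDF gammas on fixed uniforms.

    Uses Gamma(a) = Gamma(a+1) * V^(1/a) in log space, which stays
    stable for very small concentrations.  Keeping the uniforms fixed
    makes the realized frequencies a smooth, increasing-evenness
    function of alpha, so the heterozygosity calibration can bisect on
    a single scalar.
    """
    log_g = np.log(gammaincinv(alpha + 1.0, u)) + np.log(v) / alpha
    log_g -= log_g.max()
    g = np.clip(np.exp(log_g), 1e-12, None)  # keep every frequency positive
    return g / g.sum()


def simulate_allele_frequencies(spec: PanelSpec) -> AlleleFrequencySet:
    """Generate panel allele frequencies calibrated to the target mean He.

    Allele counts are uniform over the configured range; frequencies are
    symmetric-Dirichlet with a single concentration scalar tuned by
    bisection until the realized mean expected heterozygosity (mean over
    loci of 1 - sum p^2) is within ``he_tolerance`` of the target.
    """
    rng = np.random.default_rng(spec.seed)
    lo, hi = spec.allele_count_range
    counts = rng.integers(lo, hi + 1, size=spec.n_loci)
    uniforms = [
        (
            np.clip(rng.random(k), 1e-12, 1 - 1e-12),
            np.clip(rng.random(k), 1e-12, 1 - 1e-12),
        )
        for k in counts
    ]

    def realized_he(alpha: float) -> float:
        he = [
            1.0 - np.sum(_dirichlet_from_uniforms(u, v, alpha) ** 2)
            for u, v in uniforms
        ]
        return float(np.mean(he))

    if spec.concentration is not None:
        alpha = spec.concentration
    else:
        a_lo, a_hi = 1e-4, 1e7
        he_lo, he_hi = realized_he(a_lo), realized_he(a_hi)
        if not he_lo - spec.he_tolerance <= spec.target_mean_he <= he_hi + spec.he_tolerance:
            raise CalibrationError(
                f"target mean He {spec.target_mean_he} outside achievable range "
                f"[{he_lo:.4f}, {he_hi:.4f}] for allele counts in {spec.allele_count_range}"
            )
        for _ in range(200):
            alpha = math.sqrt(a_lo * a_hi)  # bisect in log space
            he = realized_he(alpha)
            if abs(he - spec.target_mean_he) <= 0.5 * spec.he_tolerance:
                break
            if he < spec.target_mean_he:
                a_lo = alpha
            else:
                a_hi = alpha

    loci = []
    for i, (k, (u, v)) in enumerate(zip(counts, uniforms)):
        p = _dirichlet_from_uniforms(u, v, alpha)
        loci.append(
            LocusFrequencies(
                locus_id=f"L{i + 1:03d}",
                alleles=_haplotype_labels(int(k), rng),
                freqs=p,
            )
        )
    out = AlleleFrequencySet(loci)
    realized = out.mean_expected_heterozygosity()
    if abs(realized - spec.target_mean_he) > spec.he_tolerance:
        raise CalibrationError(
            f"calibration failed: realized mean He {realized:.4f} vs "
            f"target {spec.target_mean_he} +/- {spec.he_tolerance}"
        )
    return out


# ---------------------------------------------------------------------------
# pedigrees and truth
# ---------------------------------------------------------------------------

@dataclass
class PedigreeSpec:
    """Founders, matings, per-individual sample counts and sexes.

    ``matings`` entries are ``(parent1, parent2, offspring)`` where
    ``offspring`` is either a count (ids auto-generated as ``M{i}O{j}``)
    or an explicit list of ids; parents may be founders or offspring of
    earlier matings.  ``recapture_counts`` defaults to one sample per
    individual.
    """

    founders: list[str]
    matings: list[tuple[str, str, int | list[str]]] = field(default_factory=list)
    sex_assignment: dict[str, str] = field(default_factory=dict)
    recapture_counts: dict[str, int] = field(default_factory=dict)
    group_assignment: dict[str, str] = field(default_factory=dict)

    def resolved_matings(self) -> list[tuple[str, str, list[str]]]:
        out = []
        for i, (p1, p2, off) in enumerate(self.matings):
            if isinstance(off, int):
                off = [f"M{i}O{j}" for j in range(off)]
            out.append((p1, p2, list(off)))
        return out

    def individuals(self) -> list[str]:
        ids = list(self.founders)
        for _, _, off in self.resolved_matings():
            ids.extend(off)
        return ids

    def parent_map(self) -> dict[str, tuple[str, str]]:
        return {
            c: (p1, p2) for p1, p2, off in self.resolved_matings() for c in off
        }

    def validate(self) -> None:
        known = set(self.founders)
        if len(known) != len(self.founders):
            raise ValueError("duplicate founder ids")
        for p1, p2, off in self.resolved_matings():
            if p1 == p2:
                raise ValueError(f"self-mating of {p1}")
            for p in (p1, p2):
                if p not in known:
                    raise ValueError(f"mating references unknown individual {p}")
            for c in off:
                if c in known:
                    raise ValueError(f"duplicate individual id {c}")
                known.add(c)
        for ind, n in self.recapture_counts.items():
            if ind not in known:
                raise ValueError(f"recapture count for unknown individual {ind}")
            if n < 1:
                raise ValueError("recapture counts must be >= 1")
        for ind, s in self.sex_assignment.items():
            if s not in ("M", "F"):
                raise ValueError(f"invalid sex {s!r} for {ind}")


RELATIONSHIP_LABELS = ("SELF", "PO", "FS", "HS", "U", "OTHER")


def _ancestors(parents: dict[str, tuple[str, str]], ind: str) -> set[str]:
    out: set[str] = set()
    stack = [ind]
    while stack:
        cur = stack.pop()
        for p in parents.get(cur, ()):  # founders have no parents
            if p not in out:
                out.add(p)
                stack.append(p)
    return out


def pedigree_relationship(
    parents: dict[str, tuple[str, str]], a: str, b: str
) -> str:
    """Pairwise relationship label implied by a pedigree."""
    if a == b:
        return "SELF"
    pa, pb = parents.get(a), parents.get(b)
    if (pa and b in pa) or (pb and a in pb):
        return "PO"
    if pa and pb:
        shared = set(pa) & set(pb)
        if len(shared) == 2:
            return "FS"
        if len(shared) == 1:
            return "HS"
    anc_a = _ancestors(parents, a) | {a}
    anc_b = _ancestors(parents, b) | {b}
    if anc_a & anc_b:
        return "OTHER"
    return "U"


@dataclass
class TruthTable:
    """Ground truth for simulated data: sample->individual map, sexes, pedigree."""

    individual_of_sample: dict[str, str]
    true_sex: dict[str, str]
    parents: dict[str, tuple[str, str]]
    individuals: list[str]

    def relationship(self, a: str, b: str) -> str:
        """Relationship between two individuals (or samples thereof)."""
        a = self.individual_of_sample.get(a, a)
        b = self.individual_of_sample.get(b, b)
        return pedigree_relationship(self.parents, a, b)

    def pair_relationships(self) -> dict[tuple[str, str], str]:
        """All unordered individual pairs with their labels."""
        out = {}
        for i, a in enumerate(self.individuals):
            for b in self.individuals[i + 1 :]:
                out[(a, b)] = self.relationship(a, b)
        return out

    def recapture_multiset(self) -> Counter:
        counts = Counter(self.individual_of_sample.values())
        return Counter(counts.values())

    def sample_sex(self, sample: str) -> str:
        return self.true_sex[self.individual_of_sample.get(sample, sample)]

    def to_json_dict(self) -> dict:
        return {
            "individual_of_sample": self.individual_of_sample,
            "true_sex": self.true_sex,
            "parents": {k: list(v) for k, v in self.parents.items()},
            "individuals": self.individuals,
        }


def simulate_pedigree_genotypes(
    freqs: AlleleFrequencySet,
    ped: PedigreeSpec,
    seed: int = 0,
    return_ibd: bool = False,
):
    """Error-free genotypes for every sample implied by the pedigree.

    Founders are drawn from Hardy-Weinberg proportions; offspring
    receive one uniformly chosen allele from each parent, independently
    per locus.  Returns ``(GenotypeMatrix, TruthTable)``, plus a
    ``(gamete-tag array, individual order)`` pair when ``return_ibd`` —
    tags are unique per founder gamete, so allele sharing identical by
    descent can be read off exactly.
    """
    ped.validate()
    rng = np.random.default_rng(seed)
    individuals = ped.individuals()
    idx = {ind: i for i, ind in enumerate(individuals)}
    n_ind, n_loci = len(individuals), len(freqs)

    alleles = np.zeros((n_ind, n_loci, 2), dtype=np.int32)
    tags = np.zeros((n_ind, n_loci, 2), dtype=np.int64)

    for f, ind in enumerate(ped.founders):
        i = idx[ind]
        for j, locus in enumerate(freqs):
            alleles[i, j] = rng.choice(locus.n_alleles, size=2, p=locus.freqs)
        tags[i, :, 0] = 2 * f
        tags[i, :, 1] = 2 * f + 1

    for p1, p2, off in ped.resolved_matings():
        i1, i2 = idx[p1], idx[p2]
        for child in off:
            c = idx[child]
            for par_slot, par in enumerate((i1, i2)):
                pick = rng.integers(0, 2, size=n_loci)
                cols = np.arange(n_loci)
                alleles[c, :, par_slot] = alleles[par, cols, pick]
                tags[c, :, par_slot] = tags[par, cols, pick]

    # expand individuals to samples
    sample_ids = []
    individual_of_sample = {}
    rows = []
    groups = {} if ped.group_assignment else None
    for ind in individuals:
        n = ped.recapture_counts.get(ind, 1)
        for k in range(1, n + 1):
            sid = f"{ind}_s{k}"
            sample_ids.append(sid)
            individual_of_sample[sid] = ind
            rows.append(idx[ind])
            if groups is not None:
                groups[sid] = ped.group_assignment.get(ind, "default")

    a = alleles[rows]
    matrix = GenotypeMatrix(
        sample_ids=sample_ids,
        locus_ids=freqs.locus_ids,
        a1=np.minimum(a[:, :, 0], a[:, :, 1]),
        a2=np.maximum(a[:, :, 0], a[:, :, 1]),
        allele_labels=[list(l.alleles) for l in freqs],
        groups=groups,
    )
    truth = TruthTable(
        individual_of_sample=individual_of_sample,
        true_sex=dict(ped.sex_assignment),
        parents=ped.parent_map(),
        individuals=individuals,
    )
    if return_ibd:
        return matrix, truth, (tags, individuals)
    return matrix, truth


def apply_genotyping_error(
    matrix: GenotypeMatrix,
    freqs: AlleleFrequencySet,
    epsilon: float,
    seed: int = 0,
) -> GenotypeMatrix:
    """True-genotype-independent error: with probability epsilon a call is
    replaced by an independent Hardy-Weinberg redraw; missing stays missing."""
    if not 0.0 <= epsilon <= 1.0:
        raise ValueError("epsilon must be in [0, 1]")
    out = matrix.copy()
    if epsilon == 0.0:
        return out
    rng = np.random.default_rng(seed)
    cols = {l: j for j, l in enumerate(matrix.locus_ids)}
    for locus in freqs:
        j = cols[locus.locus_id]
        called = out.a1[:, j] != MISSING
        hit = called & (rng.random(out.n_samples) < epsilon)
        m = int(hit.sum())
        if m == 0:
            continue
        draw = rng.choice(locus.n_alleles, size=(m, 2), p=locus.freqs)
        out.a1[hit, j] = draw.min(axis=1)
        out.a2[hit, j] = draw.max(axis=1)
    return out


# ---------------------------------------------------------------------------
# catalog and reads
# ---------------------------------------------------------------------------

def build_catalog(
    freqs: AlleleFrequencySet,
    seed: int = 0,
    amplicon_length: int = 80,
    sex_locus_id: str | None = "SRY",
) -> list[MicrohapLocus]:
    """Amplicon catalog matching the panel's allele labels.

    Each locus gets a random template sequence and evenly spread SNP
    offsets; allele haplotype strings are taken from the frequency set
    so genotype labels agree across the whole pipeline.  When
    ``sex_locus_id`` is set, a male-specific single-allele amplicon is
    appended.
    """
    rng = np.random.default_rng(seed)
    catalog = []
    for locus in freqs:
        n_snps = len(locus.alleles[0])
        span = amplicon_length - 20
        offsets = [10 + round(k * span / max(1, n_snps - 1)) for k in range(n_snps)] if n_snps > 1 else [amplicon_length // 2]
        seq = "".join(rng.choice(list(BASES), size=amplicon_length))
        seq = list(seq)
        for off, base in zip(offsets, locus.alleles[0]):
            seq[off] = base
        catalog.append(
            MicrohapLocus(
                locus_id=locus.locus_id,
                snp_offsets=offsets,
                alleles=list(locus.alleles),
                amplicon_length=amplicon_length,
                sequence="".join(seq),
            )
        )
    if sex_locus_id is not None:
        seq = "".join(rng.choice(list(BASES), size=amplicon_length))
        catalog.append(
            MicrohapLocus(
                locus_id=sex_locus_id,
                snp_offsets=[amplicon_length // 2],
                alleles=[seq[amplicon_length // 2]],
                amplicon_length=amplicon_length,
                sequence=seq,
            )
        )
    return catalog


PHRED_OFFSET = 33


def _mutate(seq: str, n_errors: int, rng: np.random.Generator) -> str:
    chars = list(seq)
    sites = rng.choice(len(chars), size=n_errors, replace=False)
    for s in sites:
        chars[s] = BASES[(BASES.index(chars[s]) + rng.integers(1, 4)) % 4]
    return "".join(chars)


def simulate_reads(
    matrix: GenotypeMatrix,
    catalog: list[MicrohapLocus],
    outdir,
    sex: dict[str, str] | None = None,
    depth_mean: int = 200,
    depth_dispersion: float | None = 8.0,
    base_quality: int = 37,
    seq_error_rate: float | None = None,
    sry_fraction: float = 5e-4,
    sry_locus_id: str = "SRY",
    seed: int = 0,
) -> pd.DataFrame:
    """Write one SAM file per sample and return the per-locus read-count table.

    Depth per sample x locus is negative binomial around ``depth_mean``
    (constant when ``depth_dispersion`` is None); heterozygote reads
    pick either allele with probability 1/2; substitution errors are
    injected at the phred-implied rate of ``base_quality`` unless
    ``seq_error_rate`` overrides it.  Male samples additionally receive
    SRY-amplicon reads at roughly ``sry_fraction`` of their total;
    females receive none.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    by_id = {loc.locus_id: loc for loc in catalog}
    for locus_id in matrix.locus_ids:
        if locus_id not in by_id:
            raise KeyError(f"locus {locus_id} missing from catalog")
    if sex is not None and any(s == "M" for s in sex.values()) and sry_locus_id not in by_id:
        raise KeyError(f"sex locus {sry_locus_id} missing from catalog")

    rng = np.random.default_rng(seed)
    err = 10 ** (-base_quality / 10) if seq_error_rate is None else seq_error_rate
    qual_char = chr(base_quality + PHRED_OFFSET)

    header_lines = ["@HD\tVN:1.6\tSO:unsorted"]
    for loc in catalog:
        header_lines.append(f"@SQ\tSN:{loc.locus_id}\tLN:{loc.amplicon_length}")
    header = "\n".join(header_lines)

    counts = []
    for i, sample in enumerate(matrix.sample_ids):
        lines = [header, f"@RG\tID:{sample}\tSM:{sample}"]
        total = 0
        for j, locus_id in enumerate(matrix.locus_ids):
            loc = by_id[locus_id]
            a1, a2 = matrix.a1[i, j], matrix.a2[i, j]
            if a1 == MISSING:
                counts.append((sample, locus_id, 0))
                continue
            if depth_dispersion is None:
                n = int(depth_mean)
            else:
                k = depth_dispersion
                n = int(rng.negative_binomial(k, k / (k + depth_mean)))
            hap1 = loc.haplotype_sequence(loc.alleles[a1])
            hap2 = hap1 if a2 == a1 else loc.haplotype_sequence(loc.alleles[a2])
            pick = rng.integers(0, 2, size=n) if a2 != a1 else np.zeros(n, dtype=int)
            n_err = rng.binomial(loc.amplicon_length, err, size=n) if err > 0 else np.zeros(n, dtype=int)
            qual = qual_char * loc.amplicon_length
            for r in range(n):
                seq = hap2 if pick[r] else hap1
                if n_err[r]:
                    seq = _mutate(seq, int(n_err[r]), rng)
                lines.append(
                    f"{sample}:{locus_id}:{r}\t0\t{locus_id}\t1\t60\t"
                    f"{loc.amplicon_length}M\t*\t0\t0\t{seq}\t{qual}\tRG:Z:{sample}"
                )
            counts.append((sample, locus_id, n))
            total += n
        if sex is not None:
            n_sry = 0
            if sex.get(sample) == "M":
                n_sry = int(rng.poisson(sry_fraction * total))
                loc = by_id[sry_locus_id]
                seq0 = loc.sequence
                qual = qual_char * loc.amplicon_length
                n_err = rng.binomial(loc.amplicon_length, err, size=n_sry) if err > 0 else np.zeros(n_sry, dtype=int)
                for r in range(n_sry):
                    seq = _mutate(seq0, int(n_err[r]), rng) if n_err[r] else seq0
                    lines.append(
                        f"{sample}:{sry_locus_id}:{r}\t0\t{sry_locus_id}\t1\t60\t"
                        f"{loc.amplicon_length}M\t*\t0\t0\t{seq}\t{qual}\tRG:Z:{sample}"
                    )
            counts.append((sample, sry_locus_id, n_sry))
        with open(outdir / f"{sample}.sam", "w") as fh:
            fh.write("\n".join(lines) + "\n")
    return pd.DataFrame(counts, columns=["sample_id", "locus_id", "n_reads"])


def read_count_totals(counts: pd.DataFrame, sry_locus_id: str = "SRY") -> pd.DataFrame:
    """Collapse a per-locus read-count table to total and SRY counts per sample."""
    total = counts.groupby("sample_id")["n_reads"].sum()
    sry = (
        counts[counts["locus_id"] == sry_locus_id]
        .groupby("sample_id")["n_reads"]
        .sum()
        .reindex(total.index, fill_value=0)
    )
    return pd.DataFrame(
        {"sample_id": total.index, "total_reads": total.values, "sry_reads": sry.values}
    ).reset_index(drop=True)


# ---------------------------------------------------------------------------
# bundled validation scenario
# ---------------------------------------------------------------------------

@dataclass
class ValidationScenario:
    """A complete synthetic study: reads, catalog, truth, and expected outputs."""

    sam_dir: Path
    catalog: list[MicrohapLocus]
    catalog_path: Path
    freqs: AlleleFrequencySet
    truth: TruthTable
    matrix_true: GenotypeMatrix
    matrix_observed: GenotypeMatrix
    read_counts: pd.DataFrame
    sample_sex: dict[str, str]
    sry_locus_id: str
    n_individuals: int
    n_samples: int

    @property
    def sam_paths(self) -> dict[str, Path]:
        return {s: self.sam_dir / f"{s}.sam" for s in self.matrix_observed.sample_ids}


def _resident_pedigree() -> PedigreeSpec:
    """A matriarch-centred multigenerational family plus an unrelated cohort.

    36 individuals (24 F / 12 M) sampled 82 times: the matriarch has
    three litters by different sires, one daughter has her own litter,
    a second unrelated family breeds once, and 17 harvest-like
    singletons are unrelated to everyone.
    """
    singles = [f"H{i:02d}" for i in range(1, 18)]
    founders = ["MAT", "SIRE1", "SIRE2", "SIRE3", "SIRE4", "DAM2", "SIRE5", *singles]
    matings = [
        ("MAT", "SIRE1", ["C1A", "C1B", "C1C"]),
        ("MAT", "SIRE2", ["C2A", "C2B"]),
        ("MAT", "SIRE3", ["C3A", "C3B"]),
        ("C1A", "SIRE4", ["G1A", "G1B"]),
        ("DAM2", "SIRE5", ["K1", "K2", "K3"]),
    ]
    males = {"SIRE1", "SIRE2", "SIRE3", "SIRE4", "SIRE5", "C1B", "C3A", "G1B",
             "H01", "H02", "H03", "H04"}
    sex = {}
    recaptures = {
        "MAT": 7, "C1A": 6, "C1B": 5, "C2A": 5, "C3A": 5,
        "SIRE1": 4, "C1C": 4, "C2B": 4, "C3B": 4, "G1A": 4,
        "G1B": 3, "SIRE2": 3, "DAM2": 3, "K1": 2, "K2": 2,
    }
    groups = {}
    all_inds = founders + [c for _, _, off in matings for c in off]
    for ind in all_inds:
        sex[ind] = "M" if ind in males else "F"
        groups[ind] = "HARVEST" if ind.startswith("H") else "RESIDENT"
    return PedigreeSpec(
        founders=founders,
        matings=matings,
        sex_assignment=sex,
        recapture_counts=recaptures,
        group_assignment=groups,
    )


def make_validation_scenario(
    outdir,
    seed: int = 0,
    depth_mean: int = 200,
    epsilon: float = 0.005,
    panel_spec: PanelSpec | None = None,
) -> ValidationScenario:
    """Generate the full desk-scale validation study under one seed."""
    outdir = Path(outdir)
    ss = np.random.SeedSequence(seed)
    s_panel, s_geno, s_err, s_reads, s_cat = (
        int(c.generate_state(1)[0] % (2**31)) for c in ss.spawn(5)
    )
    if panel_spec is None:
        panel_spec = PanelSpec(seed=s_panel)
    freqs = simulate_allele_frequencies(panel_spec)
    catalog = build_catalog(freqs, seed=s_cat)
    ped = _resident_pedigree()
    matrix_true, truth = simulate_pedigree_genotypes(freqs, ped, seed=s_geno)
    matrix_obs = apply_genotyping_error(matrix_true, freqs, epsilon, seed=s_err)
    sample_sex = {s: truth.sample_sex(s) for s in matrix_obs.sample_ids}
    sam_dir = outdir / "sam"
    read_counts = simulate_reads(
        matrix_obs,
        catalog,
        sam_dir,
        sex=sample_sex,
        depth_mean=depth_mean,
        seed=s_reads,
    )
    catalog_path = outdir / "catalog.tsv"
    write_catalog(catalog, catalog_path)
    return ValidationScenario(
        sam_dir=sam_dir,
        catalog=catalog,
        catalog_path=catalog_path,
        freqs=freqs,
        truth=truth,
        matrix_true=matrix_true,
        matrix_observed=matrix_obs,
        read_counts=read_counts,
        sample_sex=sample_sex,
        sry_locus_id="SRY",
        n_individuals=len(truth.individuals),
        n_samples=matrix_obs.n_samples,
    )
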