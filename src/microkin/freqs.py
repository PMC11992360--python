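"""Per-locus allele frequencies — the basis of all likelihoods and simulations."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import MISSING, GenotypeMatrix


@dataclass
class LocusFrequencies:
    """Allele labels and frequencies for one locus (positive, sum to 1)."""

    locus_id: str
    alleles: list[str]
    freqs: np.ndarray

    def __post_init__(self) -> None:
        self.freqs = np.asarray(self.freqs, dtype=float)
        if len(self.alleles) != self.freqs.size:
            raise ValueError("allele labels and frequencies differ in length")
        if np.any(self.freqs <= 0):
            raise ValueError(f"{self.locus_id}: frequencies must be positive")
        if abs(self.freqs.sum() - 1.0) > 1e-9:
            raise ValueError(f"{self.locus_id}: frequencies must sum to 1")

    @property
    def n_alleles(self) -> int:
        return self.freqs.size

    def expected_heterozygosity(self) -> float:
        """Hardy-Weinberg expected heterozygosity, 1 - sum(p^2)."""
        return float(1.0 - np.sum(self.freqs**2))


class AlleleFrequencySet:
    """Ordered collection of :class:`LocusFrequencies`, indexable by position or id."""

    def __init__(self, loci: list[LocusFrequencies]):
        self.loci = list(loci)
        self._by_id = {l.locus_id: l for l in self.loci}
        if len(self._by_id) != len(self.loci):
            raise ValueError("duplicate locus ids")

    def __len__(self) -> int:
        return len(self.loci)

    def __iter__(self):
        return iter(self.loci)

    def __getitem__(self, key) -> LocusFrequencies:
        if isinstance(key, str):
            return self._by_id[key]
        return self.loci[key]

    def __contains__(self, locus_id: str) -> bool:
        return locus_id in self._by_id

    @property
    def locus_ids(self) -> list[str]:
        return [l.locus_id for l in self.loci]

    def subset(self, locus_ids: list[str]) -> "AlleleFrequencySet":
        return AlleleFrequencySet([self._by_id[l] for l in locus_ids])

    def mean_expected_heterozygosity(self) -> float:
        return float(np.mean([l.expected_heterozygosity() for l in self.loci]))

    # -- serialization ---------------------------------------------------
    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"locus_id": l.locus_id, "allele": a, "frequency": f}
            for l in self.loci
            for a, f in zip(l.alleles, l.freqs)
        ]
        return pd.DataFrame(rows)

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "AlleleFrequencySet":
        df = pd.read_csv(path, sep="\t", dtype={"locus_id": str, "allele": str})
        loci = []
        for locus_id, sub in df.groupby("locus_id", sort=False):
            loci.append(
                LocusFrequencies(
                    locus_id=locus_id,
                    alleles=list(sub["allele"]),
                    freqs=sub["frequency"].to_numpy(),
                )
            )
        return cls(loci)

    @classmethod
    def from_genotype_matrix(
        cls,
        matrix: GenotypeMatrix,
        samples: list[str] | None = None,
        pseudocount: float = 0.5,
    ) -> "AlleleFrequencySet":
        """Empirical allele frequencies from called genotypes.

        A per-allele pseudocount (default 0.5) keeps every catalog allele
        at a positive frequency even when unobserved in the reference
        cohort, so downstream likelihoods stay finite.
        """
        sub = matrix if samples is None else matrix.subset(samples=samples)
        if sub.allele_labels is None:
            raise ValueError("matrix has no allele labels; cannot derive frequencies")
        loci = []
        for j, locus_id in enumerate(sub.locus_ids):
            k = len(sub.allele_labels[j])
            counts = np.full(k, pseudocount, dtype=float)
            for arr in (sub.a1[:, j], sub.a2[:, j]):
                called = arr[arr != MISSING]
                counts += np.bincount(called, minlength=k)
            loci.append(
                LocusFrequencies(
                    locus_id=locus_id,
                    alleles=list(sub.allele_labels[j]),
                    freqs=counts / counts.sum(),
                )
            )
        return cls(loci)
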