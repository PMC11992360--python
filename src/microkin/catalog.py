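"""Amplicon locus catalog: SNP offsets and haplotype alleles per GT-seq locus.

The catalog TSV schema is shared between the panel-design output, the
synthetic read simulator, and the genotype caller::

    locus_id  scaffold  amplicon_start  snp_offsets  alleles  [sequence]

``snp_offsets`` are comma-separated 0-based positions within the
amplicon; ``alleles`` are comma-separated haplotype strings (one base
per SNP).  The optional ``sequence`` column carries the consensus
amplicon sequence when known.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd


@dataclass
class MicrohapLocus:
    """An amplicon with ordered SNP offsets and a catalog of haplotype alleles."""

    locus_id: str
    snp_offsets: list[int]
    alleles: list[str]
    amplicon_length: int
    scaffold: str = "synthetic"
    amplicon_start: int = 1
    sequence: str | None = None

    def __post_init__(self) -> None:
        self.snp_offsets = [int(o) for o in self.snp_offsets]
        if sorted(set(self.snp_offsets)) != self.snp_offsets:
            raise ValueError(f"{self.locus_id}: offsets must be strictly increasing")
        if any(o < 0 or o >= self.amplicon_length for o in self.snp_offsets):
            raise ValueError(f"{self.locus_id}: offsets outside amplicon")
        n = len(self.snp_offsets)
        if any(len(a) != n for a in self.alleles):
            raise ValueError(f"{self.locus_id}: allele length != number of SNPs")
        if len(set(self.alleles)) != len(self.alleles):
            raise ValueError(f"{self.locus_id}: duplicate alleles")
        if self.sequence is not None and len(self.sequence) != self.amplicon_length:
            raise ValueError(f"{self.locus_id}: sequence length != amplicon_length")

    @property
    def n_alleles(self) -> int:
        return len(self.alleles)

    def haplotype_sequence(self, allele: str) -> str:
        """Amplicon sequence with the given haplotype substituted at SNP sites."""
        if self.sequence is None:
            raise ValueError(f"{self.locus_id}: no template sequence available")
        seq = list(self.sequence)
        for off, base in zip(self.snp_offsets, allele):
            seq[off] = base
        return "".join(seq)


def write_catalog(catalog: list[MicrohapLocus], path) -> None:
    rows = []
    for loc in catalog:
        row = {
            "locus_id": loc.locus_id,
            "scaffold": loc.scaffold,
            "amplicon_start": loc.amplicon_start,
            "snp_offsets": ",".join(str(o) for o in loc.snp_offsets),
            "alleles": ",".join(loc.alleles),
        }
        if loc.sequence is not None:
            row["sequence"] = loc.sequence
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_catalog(path) -> list[MicrohapLocus]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    catalog = []
    for rec in df.itertuples(index=False):
        offsets = [int(x) for x in str(rec.snp_offsets).split(",")]
        alleles = str(rec.alleles).split(",")
        sequence = getattr(rec, "sequence", None)
        if isinstance(sequence, float):  # NaN from missing column entries
            sequence = None
        length = (
            len(sequence)
            if sequence is not None
            else max(offsets) + 1
        )
        catalog.append(
            MicrohapLocus(
                locus_id=str(rec.locus_id),
                scaffold=str(rec.scaffold),
                amplicon_start=int(rec.amplicon_start),
                snp_offsets=offsets,
                alleles=alleles,
                amplicon_length=length,
                sequence=sequence,
            )
        )
    return catalog
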