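import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))

from microkin.freqs import AlleleFrequencySet, LocusFrequencies
from microkin.synthetic import PanelSpec, simulate_allele_frequencies


def make_freqs(vectors, prefix="L"):
    """AlleleFrequencySet from raw frequency vectors (labels A, B, C, ...)."""
    loci = []
    for i, p in enumerate(vectors):
        p = np.asarray(p, dtype=float)
        labels = [chr(ord("A") + k) for k in range(p.size)]
        loci.append(LocusFrequencies(f"{prefix}{i + 1:03d}", labels, p))
    return AlleleFrequencySet(loci)


def random_freq_vector(rng, n_alleles, floor=0.02):
    p = rng.dirichlet(np.full(n_alleles, 0.8))
    p = np.clip(p, floor, None)
    return p / p.sum()


@pytest.fixture(scope="session")
def panel170():
    """The default 170-locus synthetic panel (He calibrated to 0.46)."""
    return simulate_allele_frequencies(PanelSpec(seed=1))


@pytest.fixture
def biallelic_even():
    return make_freqs([[0.5, 0.5]])


# ---------------------------------------------------------------------------
# small VCF / FASTA writers for panel-design tests
# ---------------------------------------------------------------------------

def write_vcf(path, samples, records):
    """records: (chrom, pos, vid, ref, alt, genotypes) with genotypes like 0/1."""
    lines = [
        "##fileformat=VCFv4.2",
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
    ]
    chroms = sorted({r[0] for r in records})
    for c in chroms:
        lines.append(f"##contig=<ID={c}>")
    lines.append(
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(samples)
    )
    for chrom, pos, vid, ref, alt, genos in records:
        lines.append(
            f"{chrom}\t{pos}\t{vid}\t{ref}\t{alt}\t.\tPASS\t.\tGT\t" + "\t".join(genos)
        )
    Path(path).write_text("\n".join(lines) + "\n")
    return path


def write_fasta(path, sequences):
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 60):
                fh.write(seq[i : i + 60] + "\n")
    return path
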