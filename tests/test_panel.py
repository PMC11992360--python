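"""Heterozygosity screening, MAF tables, locus selection, consensus extraction."""

import numpy as np
import pandas as pd
import pytest

from microkin.containers import MISSING, GenotypeMatrix
from microkin.panel import (
    CandidateLocus,
    ConsistencyError,
    HetScreenConfig,
    PanelCriteria,
    compute_maf_table,
    design_panel,
    extract_amplicon_consensus,
    screen_heterozygosity,
    select_panel_loci,
    snp_pass_table,
)

from conftest import write_fasta, write_vcf


def het_matrix(h_values, n_loci=50):
    """Matrix whose per-sample heterozygosity equals the given fractions."""
    a1 = np.zeros((len(h_values), n_loci), dtype=int)
    a2 = np.zeros_like(a1)
    for i, h in enumerate(h_values):
        a2[i, : int(round(h * n_loci))] = 1
    return GenotypeMatrix(
        [f"s{i}" for i in range(len(h_values))],
        [f"L{j}" for j in range(n_loci)],
        a1,
        a2,
    )


class TestHetScreen:
    def test_outlier_flagged(self):
        m = het_matrix([0.30] * 9 + [0.36])
        res = screen_heterozygosity(m, HetScreenConfig())
        assert res.flagged == ["s9"]
        assert res.mean == pytest.approx(0.306, abs=1e-9)
        assert res.sd == pytest.approx(0.018, abs=1e-9)

    def test_identical_values_none_flagged(self):
        res = screen_heterozygosity(het_matrix([0.3] * 8))
        assert res.flagged == []

    def test_unbounded_multiplier_none_flagged(self):
        m = het_matrix([0.1, 0.2, 0.3, 0.9])
        res = screen_heterozygosity(m, HetScreenConfig(sd_multiplier=np.inf))
        assert res.flagged == []

    def test_two_sided_flags_low_outlier(self):
        m = het_matrix([0.30] * 9 + [0.06])
        assert screen_heterozygosity(m, HetScreenConfig()).flagged == []
        res = screen_heterozygosity(m, HetScreenConfig(side="two_sided"))
        assert res.flagged == ["s9"]

    def test_all_missing_sample_uncomputable(self):
        m = het_matrix([0.3] * 5)
        m.a1[0, :] = MISSING
        m.a2[0, :] = MISSING
        res = screen_heterozygosity(m)
        assert res.uncomputable == ["s0"]
        assert "s0" not in res.flagged


class TestMafTable:
    def make_vcf(self, tmp_path, records, samples=None):
        samples = samples or [f"s{i}" for i in range(10)]
        path = write_vcf(tmp_path / "v.vcf", samples, records)
        groups = {s: ("g1" if i < 5 else "g2") for i, s in enumerate(samples)}
        return path, groups

    def test_all_heterozygous(self, tmp_path):
        path, groups = self.make_vcf(
            tmp_path, [("sc1", 100, "1:50", "A", "G", ["0/1"] * 10)]
        )
        df = compute_maf_table(path, groups)
        assert df.loc[0, "global_maf"] == pytest.approx(0.5)
        assert df.loc[0, "call_rate"] == pytest.approx(1.0)
        assert df.loc[0, "read_offset"] == 50

    def test_allele_counting_with_missing(self, tmp_path):
        genos = ["0/0"] * 6 + ["0/1"] * 2 + ["./."] * 2
        path, groups = self.make_vcf(tmp_path, [("sc1", 100, ".", "A", "G", genos)])
        df = compute_maf_table(path, groups)
        assert df.loc[0, "global_maf"] == pytest.approx(2 / 16)
        assert df.loc[0, "call_rate"] == pytest.approx(0.8)
        assert np.isnan(df.loc[0, "read_offset"])

    def test_group_maf_zero_for_monomorphic_group(self, tmp_path):
        genos = ["0/0"] * 5 + ["0/1"] * 5
        path, groups = self.make_vcf(tmp_path, [("sc1", 100, ".", "A", "G", genos)])
        df = compute_maf_table(path, groups)
        assert df.loc[0, "maf_g1"] == 0.0
        assert df.loc[0, "maf_g2"] == pytest.approx(0.5)

    def test_unlabeled_sample_raises(self, tmp_path):
        path, groups = self.make_vcf(
            tmp_path, [("sc1", 100, ".", "A", "G", ["0/1"] * 10)]
        )
        del groups["s0"]
        with pytest.raises(ValueError, match="missing from group map"):
            compute_maf_table(path, groups)

    def test_multiallelic_and_indel_records_skipped(self, tmp_path):
        records = [
            ("sc1", 100, ".", "A", "G,T", ["0/1"] * 10),
            ("sc1", 200, ".", "AT", "A", ["0/1"] * 10),
            ("sc1", 300, ".", "A", "G", ["0/1"] * 10),
        ]
        path, groups = self.make_vcf(tmp_path, records)
        df = compute_maf_table(path, groups)
        assert list(df["pos"]) == [300]


def maf_row(scaffold, pos, gmaf=0.45, g1=0.4, g2=0.4, call=1.0, offset=70.0,
            ref="A", alt="G", alt_freq=0.45, vid=None):
    return {
        "scaffold": scaffold, "pos": pos, "id": vid, "ref": ref, "alt": alt,
        "alt_freq": alt_freq, "global_maf": gmaf, "call_rate": call,
        "read_offset": offset, "maf_g1": g1, "maf_g2": g2,
    }


class TestSelection:
    def test_frequency_and_call_rate_predicates(self):
        table = pd.DataFrame([
            maf_row("sc1", 1000, gmaf=0.30),                 # global MAF too low
            maf_row("sc1", 50000, gmaf=0.40, g2=0.20),       # one group too low
            maf_row("sc1", 100000, call=0.90),               # call rate too low
            maf_row("sc1", 150000, offset=5.0),              # too close to read end
            maf_row("sc1", 200000),                          # passes everything
        ])
        loci = select_panel_loci(table, PanelCriteria())
        assert [l.snp_positions for l in loci] == [[200000]]
        flags = snp_pass_table(table, PanelCriteria())
        assert list(flags["pass_all"]) == [False, False, False, False, True]

    def test_clustering_within_window(self):
        table = pd.DataFrame([
            maf_row("sc1", 1000),
            maf_row("sc1", 1015),
            maf_row("sc1", 1040),   # > 20 bp from the first cluster SNP
        ])
        crit = PanelCriteria(min_locus_spacing=10)  # don't let spacing interfere
        loci = select_panel_loci(table, crit)
        assert [l.snp_positions for l in loci] == [[1000, 1015], [1040]]
        for l in loci:
            assert l.snp_positions[-1] - l.snp_positions[0] <= crit.snp_cluster_window

    def test_spacing_keeps_best_group_maf(self):
        table = pd.DataFrame([
            maf_row("sc1", 10000, g1=0.30, g2=0.30),
            maf_row("sc1", 20000, g1=0.45, g2=0.45),  # 10 kb apart: conflict
            maf_row("sc2", 10000),                     # other scaffold unaffected
        ])
        loci = select_panel_loci(table, PanelCriteria())
        kept = [(l.scaffold, l.snp_positions[0]) for l in loci]
        assert kept == [("sc1", 20000), ("sc2", 10000)]

    def test_spacing_tie_keeps_leftmost(self):
        table = pd.DataFrame([
            maf_row("sc1", 10000),
            maf_row("sc1", 20000),
        ])
        loci = select_panel_loci(table, PanelCriteria())
        assert [l.snp_positions[0] for l in loci] == [10000]

    def test_selected_loci_respect_pairwise_spacing(self):
        rng = np.random.default_rng(4)
        rows = [
            maf_row("sc1", int(pos), g1=float(rng.uniform(0.26, 0.5)))
            for pos in np.sort(rng.choice(10**6, size=60, replace=False))
        ]
        crit = PanelCriteria()
        loci = select_panel_loci(pd.DataFrame(rows), crit)
        positions = [l.snp_positions[0] for l in loci]
        assert all(
            b - a >= crit.min_locus_spacing
            for a, b in zip(positions, positions[1:])
        )

    def test_tightening_thresholds_never_adds_loci(self):
        rng = np.random.default_rng(8)
        rows = [
            maf_row(
                "sc1",
                int(pos),
                gmaf=float(rng.uniform(0.2, 0.5)),
                g1=float(rng.uniform(0.2, 0.5)),
                g2=float(rng.uniform(0.2, 0.5)),
                call=float(rng.uniform(0.9, 1.0)),
                offset=float(rng.integers(0, 140)),
            )
            for pos in np.sort(rng.choice(10**6, size=80, replace=False))
        ]
        table = pd.DataFrame(rows)
        # spacing conflicts are resolved greedily, so monotonicity is stated
        # on the retained SNP set with spacing not binding
        base = PanelCriteria(min_locus_spacing=1)
        tighter = [
            dict(maf_global_min=0.40),
            dict(maf_group_min=0.30),
            dict(call_rate_min=0.98),
            dict(end_avoid_margin=20),
        ]

        def snp_set(crit):
            return {
                (l.scaffold, p)
                for l in select_panel_loci(table, crit)
                for p in l.snp_positions
            }

        baseline_pass = set(
            snp_pass_table(table, base).query("pass_all")["pos"]
        )
        baseline_snps = snp_set(base)
        for kw in tighter:
            crit = PanelCriteria(min_locus_spacing=1, **kw)
            assert set(snp_pass_table(table, crit).query("pass_all")["pos"]) <= baseline_pass
            assert snp_set(crit) <= baseline_snps

    def test_empty_result_is_empty_list(self):
        table = pd.DataFrame([maf_row("sc1", 1000, gmaf=0.05)])
        assert select_panel_loci(table, PanelCriteria()) == []


def candidate(scaffold="sc1", positions=(1000,), refs=None, majors=None):
    refs = list(refs or ["A"] * len(positions))
    majors = list(majors or ["G"] * len(positions))
    return CandidateLocus(
        scaffold=scaffold,
        snp_positions=list(positions),
        snp_refs=refs,
        snp_alts=["G"] * len(positions),
        snp_major=majors,
        global_mafs=[0.45] * len(positions),
        group_mafs={"g1": [0.4] * len(positions)},
    )


class TestConsensus:
    @pytest.fixture
    def reference(self, tmp_path):
        rng = np.random.default_rng(12)
        seq = "".join(rng.choice(list("ACGT"), size=2000))
        seq = seq[:999] + "A" + seq[1000:1014] + "A" + seq[1015:]
        return write_fasta(tmp_path / "ref.fa", {"sc1": seq}), seq

    def test_single_snp_coordinates(self, reference):
        path, seq = reference
        out = extract_amplicon_consensus(path, candidate(positions=[1000]))
        assert len(out.consensus_sequence) == 101
        assert out.snp_offsets == [50]
        assert out.amplicon_start == 950
        assert out.consensus_sequence[50] == "G"  # major allele substituted

    def test_two_snp_coordinates(self, reference):
        path, seq = reference
        out = extract_amplicon_consensus(path, candidate(positions=[1000, 1015]))
        assert len(out.consensus_sequence) == 116
        assert out.snp_offsets == [50, 65]

    def test_flank_truncated_at_scaffold_edge(self, reference):
        path, seq = reference
        loc = candidate(positions=[20], refs=[seq[19]])
        out = extract_amplicon_consensus(path, loc)
        assert out.truncated
        assert out.amplicon_start == 1
        assert out.snp_offsets == [19]

    def test_reference_mismatch_raises(self, reference):
        path, seq = reference
        wrong_ref = "C" if seq[999] != "C" else "T"
        with pytest.raises(ConsistencyError):
            extract_amplicon_consensus(path, candidate(refs=[wrong_ref]))


def test_design_panel_end_to_end(tmp_path):
    """VCF -> catalog round trip with one passing 2-SNP locus."""
    rng = np.random.default_rng(30)
    seq = "".join(rng.choice(list("ACGT"), size=3000))
    seq = seq[:499] + "A" + seq[500:509] + "C" + seq[510:]
    write_fasta(tmp_path / "ref.fa", {"sc1": seq})
    # 10 samples, 2 tightly linked high-MAF SNPs + 1 low-MAF SNP
    het = ["0/1"] * 10
    low = ["0/0"] * 9 + ["0/1"]
    write_vcf(
        tmp_path / "v.vcf",
        [f"s{i}" for i in range(10)],
        [
            ("sc1", 500, "7:60", "A", "T", het),
            ("sc1", 510, "7:70", "C", "G", het),
            ("sc1", 2500, "8:60", seq[2499], "A" if seq[2499] != "A" else "T", low),
        ],
    )
    groups = {f"s{i}": ("g1" if i < 5 else "g2") for i in range(10)}
    catalog, report = design_panel(
        tmp_path / "v.vcf", tmp_path / "ref.fa", groups
    )
    assert len(catalog) == 1
    loc = catalog[0]
    assert loc.snp_offsets == [50, 60]
    assert sorted(loc.alleles) == sorted(["AC", "AG", "TC", "TG"])
    assert len(loc.sequence) == 111
    assert report["pass_all"].sum() == 2
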