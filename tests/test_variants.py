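"""Variant summarisation: somatic subtraction, tallies, coverage, overlap."""

import logging

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import pdcrx
from pdcrx import io as pio
from pdcrx.config import CHROMOSOMES, SUBSTITUTION_TYPES

KEY = ["chrom", "pos", "ref", "alt"]


def keyset(df):
    return set(map(tuple, df[KEY].itertuples(index=False, name=None)))


class TestReadVariants:
    def test_vcf_roundtrip_single_snv(self, tmp_path, make_variants):
        v = make_variants([("s1", "chr1", 100, "C", "T", "TP53")])
        pio.write_vcf(v, tmp_path / "one.vcf")
        back = pio.read_variants(tmp_path / "one.vcf", sample_id="s1")
        assert len(back) == 1
        assert back.loc[0, ["chrom", "pos", "ref", "alt", "gene"]].tolist() == [
            "chr1", 100, "C", "T", "TP53",
        ]
        assert back.attrs["build"] == "hg38"

    def test_multiallelic_split_into_one_row_per_alt(self, tmp_path):
        vcf = tmp_path / "multi.vcf"
        vcf.write_text(
            "##fileformat=VCFv4.2\n"
            "##contig=<ID=chr2,length=242193529>\n"
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n"
            "chr2\t500\t.\tA\tG,T\t.\t.\t.\n"
        )
        back = pio.read_variants(vcf, sample_id="s1")
        assert len(back) == 2
        assert back["alt"].tolist() == ["G", "T"]
        assert back["chrom"].nunique() == 1 and back["pos"].nunique() == 1

    def test_non_snv_records_dropped_and_logged(self, tmp_path, caplog):
        lines = [
            "##fileformat=VCFv4.2",
            "##contig=<ID=chr1,length=248956422>",
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO",
        ]
        for i in range(20):
            lines.append(f"chr1\t{100 + i}\t.\tC\tT\t.\t.\t.")
        for i in range(5):
            lines.append(f"chr1\t{1000 + i}\t.\tCA\tC\t.\t.\t.")  # deletions
        vcf = tmp_path / "mix.vcf"
        vcf.write_text("\n".join(lines) + "\n")
        with caplog.at_level(logging.INFO, logger="pdcrx.io"):
            back = pio.read_variants(vcf)
        assert len(back) == 20
        assert any("5 non-SNV" in m for m in caplog.messages)

    def test_annovar_style_table(self, tmp_path):
        tsv = tmp_path / "ann.tsv"
        tsv.write_text(
            "Chr\tStart\tRef\tAlt\tGene.refGene\n"
            "7\t1000\tG\tA\tEGFR\n"
            "chr17\t2000\tC\tT\tTP53\n"
            "7\t3000\tGT\tG\tBRAF\n"  # indel: dropped
        )
        back = pio.read_variants(tsv, sample_id="p1")
        assert len(back) == 2
        assert back["chrom"].tolist() == ["chr7", "chr17"]
        assert back["gene"].tolist() == ["EGFR", "TP53"]


class TestSomaticFilter:
    def test_tumor_equals_germline_gives_empty(self, make_variants):
        t = make_variants([("s", "chr1", 1, "A", "G"), ("s", "chr2", 2, "C", "T")])
        assert pdcrx.somatic_filter(t, t.copy()).empty

    def test_empty_germline_returns_tumor(self, make_variants):
        t = make_variants([("s", "chr1", 1, "A", "G")])
        g = t.iloc[0:0]
        out = pdcrx.somatic_filter(t, g)
        pd.testing.assert_frame_equal(out, t)

    def test_planted_somatic_set_recovered(self, small_cfg):
        tumor, germ, somatic = pdcrx.generate_paired_vcfs(small_cfg, 50, 300)
        out = pdcrx.somatic_filter(tumor, germ)
        assert keyset(out) == keyset(somatic)
        assert keyset(out) & keyset(germ) == set()

    def test_idempotent(self, small_cfg):
        tumor, germ, _ = pdcrx.generate_paired_vcfs(small_cfg, 20, 100)
        once = pdcrx.somatic_filter(tumor, germ)
        twice = pdcrx.somatic_filter(once, germ)
        pd.testing.assert_frame_equal(once, twice)

    def test_build_mismatch_raises(self, make_variants):
        t = make_variants([("s", "chr1", 1, "A", "G")])
        g = make_variants([("s", "chr1", 5, "C", "T")])
        t.attrs["build"] = "hg38"
        g.attrs["build"] = "hg19"
        with pytest.raises(ValueError, match="build"):
            pdcrx.somatic_filter(t, g)


class TestTallies:
    def test_empty_table_all_zero(self, make_variants):
        counts = pdcrx.chrom_distribution(make_variants([]))
        assert list(counts.columns) == list(CHROMOSOMES)
        assert counts.to_numpy().sum() == 0

    def test_explicit_counts(self, make_variants):
        v = make_variants(
            [("s", "chr1", p, "A", "G") for p in (1, 2, 3)]
            + [("s", "chrX", p, "C", "T") for p in (10, 20)]
        )
        counts = pdcrx.chrom_distribution(v)
        assert counts.loc["s", "chr1"] == 3
        assert counts.loc["s", "chrX"] == 2
        assert counts.loc["s"].sum() == 5

    def test_unknown_chromosome_listed(self, make_variants):
        v = make_variants([("s", "chrUn_KI270302v1", 1, "A", "G")])
        with pytest.raises(ValueError, match="chrUn_KI270302v1"):
            pdcrx.chrom_distribution(v)

    def test_single_substitution(self, make_variants):
        spec = pdcrx.substitution_spectrum(make_variants([("s", "chr1", 1, "C", "T")]))
        assert spec.loc["s", "C>T"] == 1
        assert spec.loc["s"].sum() == 1

    def test_dominant_types_are_largest(self):
        probs = {t: 0.4 / 10 for t in SUBSTITUTION_TYPES}
        probs["C>T"] = 0.3
        probs["G>A"] = 0.3
        cfg = pdcrx.SimConfig(
            spectrum_probs=tuple(probs[t] for t in SUBSTITUTION_TYPES), seed=4
        )
        _, germ, _ = pdcrx.generate_paired_vcfs(cfg, 0, 2000)
        totals = pdcrx.substitution_spectrum(germ).sum(axis=0)
        assert set(totals.nlargest(2).index) == {"C>T", "G>A"}

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(st.data())
    def test_conservation_of_record_counts(self, data):
        n = data.draw(st.integers(1, 40))
        rng = np.random.default_rng(data.draw(st.integers(0, 2**31 - 1)))
        subs = [SUBSTITUTION_TYPES[i] for i in rng.integers(0, 12, n)]
        v = pd.DataFrame(
            {
                "sample_id": [f"s{i % 3}" for i in range(n)],
                "chrom": [CHROMOSOMES[i] for i in rng.integers(0, 24, n)],
                "pos": np.arange(1, n + 1),
                "ref": [s[0] for s in subs],
                "alt": [s[2] for s in subs],
                "gene": "",
            }
        )
        per_sample = v.groupby("sample_id").size()
        chrom = pdcrx.chrom_distribution(v).sum(axis=1)
        spec = pdcrx.substitution_spectrum(v).sum(axis=1)
        assert (chrom.reindex(per_sample.index) == per_sample).all()
        assert (spec.reindex(per_sample.index) == per_sample).all()


class TestPerGeneCoverage:
    def _track(self, rows):
        return pd.DataFrame(rows, columns=["chrom", "start", "end", "depth"])

    def _genes(self, rows):
        return pd.DataFrame(rows, columns=["chrom", "start", "end", "gene"])

    def test_constant_depth(self):
        cov = pdcrx.per_gene_coverage(
            self._track([("chr1", 0, 1000, 42.0)]),
            self._genes([("chr1", 100, 200, "A")]),
        )
        assert cov.loc[0, "mean_depth"] == 42.0
        assert cov.loc[0, "interval_bp"] == 100

    def test_uncovered_bases_count_as_zero(self):
        cov = pdcrx.per_gene_coverage(
            self._track([("chr1", 0, 50, 10.0)]),
            self._genes([("chr1", 0, 100, "A")]),
        )
        assert cov.loc[0, "mean_depth"] == 5.0

    def test_length_weighted_mean(self):
        cov = pdcrx.per_gene_coverage(
            self._track([("chr1", 0, 100, 10.0), ("chr1", 1000, 1300, 20.0)]),
            self._genes([("chr1", 0, 100, "A"), ("chr1", 1000, 1300, "A")]),
        )
        assert cov.loc[0, "mean_depth"] == pytest.approx(17.5)

    def test_matches_per_base_bruteforce(self, rng):
        # independent oracle: expand to individual bases and average
        genes, track, pos = [], [], 0
        for i in range(6):
            w = int(rng.integers(20, 80))
            track.append(("chr1", pos, pos + w, float(rng.integers(0, 50))))
            pos += w + int(rng.integers(0, 30))
        for g in range(3):
            s = int(rng.integers(0, pos - 60))
            genes.append(("chr1", s, s + int(rng.integers(30, 60)), f"g{g}"))
        depth_at = {}
        for _, s, e, d in track:
            for b in range(s, e):
                depth_at[b] = d
        expected = {
            name: np.mean([depth_at.get(b, 0.0) for b in range(s, e)])
            for _, s, e, name in genes
        }
        cov = pdcrx.per_gene_coverage(self._track(track), self._genes(genes))
        for _, row in cov.iterrows():
            assert row["mean_depth"] == pytest.approx(expected[row["gene"]])

    @pytest.mark.parametrize("c", [0.5, 2.0, 10.0])
    def test_linear_under_depth_scaling(self, c):
        track = self._track([("chr1", 0, 100, 10.0), ("chr1", 150, 300, 25.0)])
        genes = self._genes([("chr1", 0, 250, "A")])
        base = pdcrx.per_gene_coverage(track, genes).loc[0, "mean_depth"]
        scaled = track.assign(depth=track["depth"] * c)
        assert pdcrx.per_gene_coverage(scaled, genes).loc[0, "mean_depth"] == pytest.approx(c * base)

    def test_bad_coordinates_flagged(self):
        with pytest.raises(ValueError, match="half-open"):
            pdcrx.per_gene_coverage(
                self._track([("chr1", 100, 100, 5.0)]),
                self._genes([("chr1", 0, 100, "A")]),
            )


class TestMutationMatrix:
    def test_binarized_not_counted(self, make_variants):
        v = make_variants([("s1", "chr17", p, "C", "T", "TP53") for p in (1, 2, 3)])
        mat = pdcrx.mutation_matrix(v, ["TP53", "EGFR"])
        assert mat.loc["s1", "TP53"] == 1
        assert mat.loc["s1", "EGFR"] == 0

    def test_all_zero_row_retained(self, make_variants):
        v = make_variants([("s1", "chr1", 1, "A", "G", "OFFPANEL")])
        mat = pdcrx.mutation_matrix(v, ["TP53"])
        assert list(mat.index) == ["s1"]
        assert mat.loc["s1"].sum() == 0

    def test_planted_matrix_recovered_from_vcfs(self, small_cfg, tmp_path):
        panel = [f"G{i + 1:03d}" for i in range(10)]
        tumor, germ, somatic = pdcrx.generate_paired_vcfs(
            small_cfg, 80, 200, sample_id="p1", gene_pool=panel, genic_frac=1.0
        )
        som = pdcrx.somatic_filter(tumor, germ)
        mat = pdcrx.mutation_matrix(som, panel)
        expected = {g: int((somatic["gene"] == g).any()) for g in panel}
        assert {g: int(mat.loc["p1", g]) for g in panel} == expected

    def test_empty_panel_rejected(self, make_variants):
        with pytest.raises(ValueError, match="panel"):
            pdcrx.mutation_matrix(make_variants([]), [])


class TestTopkOverlap:
    def test_identical_tables_full_overlap(self, rng):
        genes = [f"g{i}" for i in range(40)]
        scores = pd.Series(rng.random(40), index=genes)
        assert len(pdcrx.topk_overlap(scores, scores.copy(), 30)) == 30

    def test_disjoint_topk_empty(self):
        a = pd.Series({"a": 10, "b": 9, "c": 1, "d": 1})
        b = pd.Series({"a": 1, "b": 1, "c": 10, "d": 9})
        assert pdcrx.topk_overlap(a, b, 2) == []

    def test_matches_bruteforce_oracle(self, rng):
        for _ in range(20):
            genes = [f"g{i}" for i in range(15)]
            a = pd.Series(rng.integers(0, 8, 15).astype(float), index=genes)
            b = pd.Series(rng.integers(0, 8, 15).astype(float), index=genes)
            k = 5

            def brute_top(s):
                ranked = sorted(s.items(), key=lambda kv: (-kv[1], kv[0]))
                return {g for g, _ in ranked[:k]}

            assert set(pdcrx.topk_overlap(a, b, k)) == brute_top(a) & brute_top(b)

    def test_tie_at_rank_k_broken_lexicographically(self):
        a = pd.Series({"zeta": 5.0, "alpha": 3.0, "beta": 3.0})
        b = pd.Series({"zeta": 5.0, "alpha": 1.0, "beta": 3.0})
        # rank-2 tie in a between alpha/beta -> alpha wins lexicographically
        assert pdcrx.topk_overlap(a, b, 2) == ["zeta"]
        assert pdcrx.topk_overlap(a, a.copy(), 2) == ["alpha", "zeta"]

    def test_duplicate_gene_rejected(self):
        dup = pd.Series([1.0, 2.0], index=["g1", "g1"])
        with pytest.raises(ValueError, match="duplicate"):
            pdcrx.topk_overlap(dup, dup, 1)

    def test_k_larger_than_table_rejected(self):
        s = pd.Series({"a": 1.0})
        with pytest.raises(ValueError, match="exceeds"):
            pdcrx.topk_overlap(s, s, 2)
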