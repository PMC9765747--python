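"""Read ingestion, pseudo-RPKM and the site-level matrix views."""

import numpy as np
import pandas as pd
import pytest

from metasecretome.biogeography import (
    SiteFunctionMatrix,
    average_by_site,
    ec_read_counts,
    filter_prevalent_ecs,
    load_assignments,
    mean_orf_length_per_ec,
    mucosa_lumen_ratio,
    normalize_by_row_max,
    pseudo_rpkm,
    reads_per_phylum_secreted,
    rpkm_matrix,
    zscore_by_row,
)
from metasecretome.model import SampleMeta
from metasecretome.simulate import SamplingConfig, generate_reads, write_sam


class TestLoadAssignments:
    def test_tsv_and_uniqueness_filter(self, tmp_path):
        p = tmp_path / "a.tsv"
        p.write_text(
            "read_id\torf_id\tsample_id\n"
            "r1\to1\ts1\n"
            "r2\to1\ts1\nr2\to2\ts1\n"  # multi-mapped: dropped entirely
            "r1\to3\ts2\n"  # same read id in another sample is fine
        )
        df = load_assignments(p)
        assert sorted(map(tuple, df[["read_id", "sample_id"]].to_numpy())) == [
            ("r1", "s1"), ("r1", "s2")
        ]

    def test_malformed_tsv_errors(self, tmp_path):
        p = tmp_path / "a.tsv"
        p.write_text("read_id\torf_id\tsample_id\nr1\to1\n")
        with pytest.raises(ValueError):
            load_assignments(p)

    def test_sam_primary_semantics(self, tmp_path):
        sam = tmp_path / "s1.sam"
        sam.write_text(
            "@HD\tVN:1.6\n@SQ\tSN:o1\tLN:300\n@SQ\tSN:o2\tLN:300\n"
            "r1\t0\to1\t1\t42\t50M\t*\t0\t0\t" + "A" * 50 + "\t*\n"
            "r1\t256\to2\t1\t42\t50M\t*\t0\t0\t*\t*\n"  # secondary: ignored
            "r2\t0\to1\t1\t5\t50M\t*\t0\t0\t" + "A" * 50 + "\t*\n"  # low MAPQ
            "r3\t4\t*\t0\t0\t*\t*\t0\t0\t*\t*\n"  # unmapped
        )
        df = load_assignments(sam, sample_id="s1", min_mapq=10)
        assert df["read_id"].tolist() == ["r1"]

    def test_sam_requires_sample_id(self, tmp_path):
        sam = tmp_path / "x.sam"
        sam.write_text("@HD\tVN:1.6\n")
        with pytest.raises(ValueError):
            load_assignments(sam)

    def test_sam_roundtrip_matches_generator_ledger(self, tiny_community, tmp_path):
        reads = generate_reads(
            tiny_community,
            SamplingConfig(reads_per_sample=300, replicates_per_site=1),
            seed=4,
        )
        sample = reads.sample_meta[0].sample_id
        sam_path = tmp_path / f"{sample}.sam"
        write_sam(tiny_community, reads.assignments, sample, sam_path, seed=4)
        loaded = load_assignments(sam_path, sample_id=sample)
        expected = reads.assignments[reads.assignments["sample_id"] == sample]
        assert sorted(map(tuple, loaded[["read_id", "orf_id"]].to_numpy())) == sorted(
            map(tuple, expected[["read_id", "orf_id"]].to_numpy())
        )


class TestPhylumCounts:
    def test_counts_restricted_to_secreted(self):
        assign = pd.DataFrame(
            {"read_id": [f"r{i}" for i in range(12)],
             "orf_id": ["a"] * 10 + ["b"] * 2,
             "sample_id": ["s1"] * 12}
        )
        labels = {"a": True, "b": False}
        table = reads_per_phylum_secreted(
            assign, labels, {"a": "m1", "b": "m2"}, {"m1": "Bacteroidetes", "m2": "Firmicutes"}
        )
        assert table.loc["s1", "Bacteroidetes"] == 10
        assert "Firmicutes" not in table.columns or table.loc["s1", "Firmicutes"] == 0

    def test_all_nonsecreted_gives_zero(self):
        assign = pd.DataFrame(
            {"read_id": ["r1"], "orf_id": ["a"], "sample_id": ["s1"]}
        )
        table = reads_per_phylum_secreted(assign, {"a": False}, {"a": "m"}, {"m": "P"})
        assert table.to_numpy().sum() == 0

    def test_unknown_orf_errors(self):
        assign = pd.DataFrame({"read_id": ["r"], "orf_id": ["ghost"], "sample_id": ["s"]})
        with pytest.raises(ValueError):
            reads_per_phylum_secreted(assign, {}, {}, {})


class TestPseudoRpkm:
    def test_hand_computed_fixture(self):
        assert pseudo_rpkm(10, 1000.0, 10**6) == pytest.approx(10.0)
        assert pseudo_rpkm(0, 1000.0, 10**6) == 0.0

    def test_scaling_identities(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            reads = float(rng.integers(1, 10**4))
            length = float(rng.uniform(100, 5000))
            total = int(rng.integers(10**4, 10**7))
            base = pseudo_rpkm(reads, length, total)
            assert pseudo_rpkm(2 * reads, length, total) == pytest.approx(2 * base)
            assert pseudo_rpkm(reads, 2 * length, total) == pytest.approx(base / 2)
            assert pseudo_rpkm(reads, length, 2 * total) == pytest.approx(base / 2)

    def test_degenerate_inputs_error(self):
        with pytest.raises(ValueError):
            pseudo_rpkm(1, 0.0, 100)
        with pytest.raises(ValueError):
            pseudo_rpkm(1, 100.0, 0)

    def test_mean_length_is_per_ec_over_secreted_orfs(self):
        lengths = {"a": 900, "b": 1100, "c": 5000, "d": 700}
        ecs = {"a": ["3.2.1.23"], "b": ["3.2.1.23", "3.1.3.5"], "c": ["3.2.1.23"], "d": []}
        labels = {"a": True, "b": True, "c": False, "d": True}  # c excluded
        means = mean_orf_length_per_ec(lengths, ecs, labels)
        assert means["3.2.1.23"] == pytest.approx(1000.0)
        assert means["3.1.3.5"] == pytest.approx(1100.0)

    def test_multi_ec_reads_counted_once_per_ec(self):
        assign = pd.DataFrame(
            {"read_id": ["r1", "r2"], "orf_id": ["a", "a"], "sample_id": ["s1", "s1"]}
        )
        counts = ec_read_counts(assign, {"a": ["3.2.1.23", "3.1.3.5"]}, {"a": True})
        assert counts.loc["s1", "3.2.1.23"] == 2
        assert counts.loc["s1", "3.1.3.5"] == 2


def _meta(pairs):
    return [SampleMeta(s, site, comp, n) for s, site, comp, n in pairs]


class TestSiteAveraging:
    def test_same_site_mean(self):
        values = pd.DataFrame({"EC1": [4.0, 6.0]}, index=["s1", "s2"])
        meta = _meta([("s1", "duodenum", "lumen", 10), ("s2", "duodenum", "lumen", 10)])
        out = average_by_site(values, meta)
        assert out.loc["EC1", ("duodenum", "lumen")] == pytest.approx(5.0)

    def test_single_sample_identity_and_order_invariance(self):
        values = pd.DataFrame({"EC1": [7.0, 1.0, 3.0]}, index=["a", "b", "c"])
        meta = _meta([("a", "colon", "mucosa", 5), ("b", "colon", "lumen", 5),
                      ("c", "colon", "lumen", 5)])
        out1 = average_by_site(values, meta)
        out2 = average_by_site(values.iloc[::-1], meta)
        assert out1.loc["EC1", ("colon", "mucosa")] == 7.0
        pd.testing.assert_frame_equal(out1, out2)


def _site_matrix(rows, sites=(("colon", "lumen"), ("colon", "mucosa"), ("stool", "stool"))):
    cols = pd.MultiIndex.from_tuples(sites, names=["site", "compartment"])
    return pd.DataFrame(rows, columns=cols)


class TestMatrixViews:
    def test_prevalence_filter_is_strict(self):
        m = _site_matrix([[50.1, 1, 1], [50.0, 1, 1], [0, 0, 0]])
        kept = filter_prevalent_ecs(m, 50.0)
        assert list(kept.index) == [0]

    def test_row_max_normalization(self):
        m = _site_matrix([[10.0, 50.0, 25.0]])
        norm = normalize_by_row_max(m)
        assert norm.iloc[0].tolist() == pytest.approx([0.2, 1.0, 0.5])
        const = _site_matrix([[3.0, 3.0, 3.0]])
        assert normalize_by_row_max(const).iloc[0].tolist() == [1.0, 1.0, 1.0]

    def test_every_row_attains_one(self):
        rng = np.random.default_rng(1)
        m = _site_matrix(rng.uniform(1, 100, size=(20, 3)))
        norm = normalize_by_row_max(m)
        assert np.allclose(norm.max(axis=1), 1.0)

    def test_ratio_views(self):
        m = _site_matrix([[10.0, 20.0, 5.0], [7.0, 7.0, 1.0], [0.0, 3.0, 1.0]])
        ratio = mucosa_lumen_ratio(m)
        assert ratio.loc[0, "colon"] == pytest.approx(2.0)
        assert ratio.loc[1, "colon"] == pytest.approx(1.0)
        assert np.isnan(ratio.loc[2, "colon"])
        stabilized = mucosa_lumen_ratio(m, epsilon=1.0)
        assert stabilized.loc[2, "colon"] == pytest.approx(4.0)  # (3+1)/(0+1)

    def test_zscore_view(self):
        m = _site_matrix([[1.0, 2.0, 3.0]])
        z = zscore_by_row(m)
        assert z.iloc[0].mean() == pytest.approx(0.0, abs=1e-12)
        assert z.iloc[0].std(ddof=0) == pytest.approx(1.0)

    def test_site_function_matrix_facade(self):
        m = _site_matrix([[60.0, 30.0, 10.0], [4.0, 2.0, 1.0]])
        sfm = SiteFunctionMatrix(m, min_rpkm=50.0)
        assert list(sfm.filtered.index) == [0]
        assert sfm.normalized.loc[0, ("colon", "lumen")] == 1.0
        assert sfm.ratio.loc[0, "colon"] == pytest.approx(0.5)


class TestRpkmMatrix:
    def test_qc_vs_mapped_denominator(self):
        counts = pd.DataFrame({"EC1": [10]}, index=["s1"])
        lengths = pd.Series({"EC1": 1000.0})
        meta = _meta([("s1", "colon", "lumen", 10**6)])
        qc = rpkm_matrix(counts, lengths, meta, "qc")
        assert qc.loc["s1", "EC1"] == pytest.approx(10.0)
        mapped = rpkm_matrix(counts, lengths, meta, "mapped")
        assert mapped.loc["s1", "EC1"] == pytest.approx(10 / (1.0 * 10 / 1e6))

    def test_missing_sample_metadata_errors(self):
        counts = pd.DataFrame({"EC1": [1]}, index=["ghost"])
        with pytest.raises(ValueError):
            rpkm_matrix(counts, pd.Series({"EC1": 100.0}), [])


def test_planted_enrichment_lands_at_colon_lumen(default_community_nosequences):
    """With a 4x colon-lumen multiplier on beta-galactosidase, the
    max-normalized row peaks there and the colon mucosa/lumen ratio < 1."""
    com = default_community_nosequences
    reads = generate_reads(com, SamplingConfig(reads_per_sample=30_000), seed=9)
    labels = com.secretion_truth()
    counts = ec_read_counts(reads.assignments, com.orf_ecs(), labels)
    mean_len = mean_orf_length_per_ec(com.orf_lengths_nt(), com.orf_ecs(), labels)
    rpkm = rpkm_matrix(counts, mean_len, reads.sample_meta)
    site = average_by_site(rpkm, reads.sample_meta)
    sfm = SiteFunctionMatrix(site, min_rpkm=50.0)
    target = "3.2.1.23"
    assert target in sfm.filtered.index
    norm_row = sfm.normalized.loc[target]
    assert norm_row.idxmax() == ("colon", "lumen")
    assert sfm.ratio.loc[target, "colon"] < 1.0
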