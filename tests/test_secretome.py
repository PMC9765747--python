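"""Signal-peptide / transmembrane parsing and secretion calling."""

import math
import random

import numpy as np
import pytest

from metasecretome.model import Mag, Orf, OrfCluster, SpClass
from metasecretome.secretome import (
    annotate_secretion,
    classify_secretion,
    cost_per_residue,
    length_summary,
    load_cost_table,
    parse_signalp5,
    parse_tmhmm,
    percent_secreted_per_mag,
    percent_secreted_per_phylum,
    propagate_labels,
    read_secretion_table,
    write_secretion_table,
)


class TestSignalpParser:
    def test_class_mapping(self, tmp_path):
        p = tmp_path / "sp.txt"
        p.write_text(
            "# SignalP-5.0\n# ID\tPrediction\n"
            "orf1\tSP(Sec/SPI)\t0.98\norf2\tLIPO(Sec/SPII)\t0.91\n"
            "orf3\tOTHER\t0.99\norf4\tTAT(Tat/SPI)\t0.88\n"
        )
        assert parse_signalp5(p) == {
            "orf1": SpClass.SEC_SPI,
            "orf2": SpClass.LIPO,
            "orf3": SpClass.OTHER,
            "orf4": SpClass.TAT,
        }

    def test_unknown_class_errors(self, tmp_path):
        p = tmp_path / "sp.txt"
        p.write_text("orf1\tSP(Sec/SPIII)\t0.9\n")
        with pytest.raises(ValueError):
            parse_signalp5(p)

    def test_duplicate_id_errors(self, tmp_path):
        p = tmp_path / "sp.txt"
        p.write_text("orf1\tOTHER\t0.9\norf1\tOTHER\t0.9\n")
        with pytest.raises(ValueError):
            parse_signalp5(p)


class TestTmhmmParser:
    def test_helix_counts(self, tmp_path):
        p = tmp_path / "tm.txt"
        p.write_text(
            "orf1\tlen=210\tExpAA=0.00\tFirst60=0.00\tPredHel=0\tTopology=i\n"
            "orf2\tlen=300\tExpAA=66.1\tFirst60=21.9\tPredHel=3\tTopology=i7-29o44-66i80-102o\n"
        )
        assert parse_tmhmm(p) == {"orf1": 0, "orf2": 3}

    def test_missing_predhel_errors(self, tmp_path):
        p = tmp_path / "tm.txt"
        p.write_text("orf1\tlen=210\tExpAA=0.00\n")
        with pytest.raises(ValueError):
            parse_tmhmm(p)

    def test_duplicate_id_errors(self, tmp_path):
        p = tmp_path / "tm.txt"
        p.write_text("orf1\tlen=1\tPredHel=0\norf1\tlen=1\tPredHel=1\n")
        with pytest.raises(ValueError):
            parse_tmhmm(p)


class TestClassifySecretion:
    @pytest.mark.parametrize(
        "sp, tm, expected",
        [
            (SpClass.SEC_SPI, 0, True),
            (SpClass.TAT, 0, True),
            (SpClass.LIPO, 0, False),
            (SpClass.OTHER, 0, False),
            (SpClass.SEC_SPI, 2, False),
            (SpClass.TAT, 1, False),
            (SpClass.LIPO, 3, False),
            (SpClass.OTHER, 5, False),
        ],
    )
    def test_truth_table(self, sp, tm, expected):
        assert classify_secretion(sp, tm) is expected

    def test_missing_predictions_default_to_other(self):
        anns = annotate_secretion(["x"], {}, {})
        assert anns["x"].sp_class is SpClass.OTHER and not anns["x"].secreted

    def test_nterm_helix_discount_flag(self):
        spans = {"x": [(7, 29)], "y": [(120, 142)]}
        sp = {"x": SpClass.SEC_SPI, "y": SpClass.SEC_SPI}
        tm = {"x": 1, "y": 1}
        strict = annotate_secretion(["x", "y"], sp, tm)
        assert not strict["x"].secreted and not strict["y"].secreted
        relaxed = annotate_secretion(
            ["x", "y"], sp, tm, tm_spans=spans, ignore_nterm_helices=True
        )
        assert relaxed["x"].secreted  # helix inside the signal-peptide window
        assert not relaxed["y"].secreted


class TestPropagation:
    def test_members_inherit_centroid_label(self):
        clusters = [OrfCluster("c", ("c", "m1", "m2"))]
        labels = propagate_labels(clusters, {"c": True})
        assert labels == {"c": True, "m1": True, "m2": True}

    def test_singleton_unchanged(self):
        assert propagate_labels([OrfCluster("s", ("s",))], {"s": False}) == {"s": False}

    def test_label_multiset_matches_centroid_replication(self):
        rng = random.Random(0)
        clusters, centroid_labels, expected = [], {}, []
        for i in range(37):
            size = rng.randint(1, 9)
            ids = tuple(f"c{i}_m{j}" for j in range(size))
            clusters.append(OrfCluster(ids[0], ids))
            label = rng.random() < 0.5
            centroid_labels[ids[0]] = label
            expected += [label] * size
        labels = propagate_labels(clusters, centroid_labels)
        assert sorted(labels.values()) == sorted(expected)
        assert len(labels) == sum(c.size for c in clusters)

    def test_unlabeled_centroid_errors(self):
        with pytest.raises(ValueError):
            propagate_labels([OrfCluster("c", ("c",))], {})


def _mag_with_orfs(mag_id, phylum, n, aa_len=100):
    orfs = [
        Orf(f"{mag_id}_{i}", mag_id, "c1", 1, 3 * (aa_len + 1), "+", "", "A" * aa_len)
        for i in range(n)
    ]
    return Mag(mag_id, mag_id, phylum, "fam", orfs=orfs)


class TestSecretionSummaries:
    def test_percent_secreted_arithmetic(self):
        mag = _mag_with_orfs("m", "P", 10)
        labels = {o.orf_id: i < 3 for i, o in enumerate(mag.orfs)}
        assert percent_secreted_per_mag(labels, [mag])["m"] == 30.0
        labels = {o.orf_id: False for o in mag.orfs}
        assert percent_secreted_per_mag(labels, [mag])["m"] == 0.0

    def test_empty_mag_errors(self):
        with pytest.raises(ValueError):
            percent_secreted_per_mag({}, [Mag("m", "o", "P", "F")])

    def test_planted_fraction_recovered(self):
        rng = np.random.default_rng(0)
        mag = _mag_with_orfs("m", "P", 4000)
        labels = {o.orf_id: bool(rng.random() < 0.25) for o in mag.orfs}
        assert percent_secreted_per_mag(labels, [mag])["m"] == pytest.approx(25.0, abs=1.5)

    def test_per_phylum_means_and_floor(self):
        mags = [_mag_with_orfs(f"a{i}", "A", 10) for i in range(5)]
        mags += [_mag_with_orfs(f"b{i}", "B", 10) for i in range(2)]
        labels = {o.orf_id: o.mag_id.startswith("a") for m in mags for o in m.orfs}
        per_mag = percent_secreted_per_mag(labels, mags)
        by_phylum = percent_secreted_per_phylum(per_mag, mags, min_mags=5)
        assert list(by_phylum.index) == ["A"] and by_phylum["A"] == 100.0


class TestLengthSummary:
    def test_means(self):
        orfs = [
            Orf("s1", "m", "c", 1, 303, "+", "", "A" * 100),
            Orf("s2", "m", "c", 1, 303, "+", "", "A" * 100),
            Orf("n1", "m", "c", 1, 153, "+", "", "A" * 50),
            Orf("n2", "m", "c", 1, 153, "+", "", "A" * 50),
        ]
        labels = {"s1": True, "s2": True, "n1": False, "n2": False}
        res = length_summary(labels, orfs)
        assert (res.mean_len_secreted, res.mean_len_nonsecreted) == (100.0, 50.0)

    def test_no_shift_gives_large_p(self):
        orfs = [
            Orf(f"{g}{i}", "m", "c", 1, 3 * (ln + 1), "+", "", "A" * ln)
            for g, flag in (("s", True), ("n", False))
            for i, ln in enumerate([10, 20])
        ]
        labels = {o.orf_id: o.orf_id.startswith("s") for o in orfs}
        assert length_summary(labels, orfs).test.p_value > 0.6

    def test_planted_length_difference_recovered(self):
        rng = np.random.default_rng(1)
        sigma = 0.35
        orfs, labels = [], {}
        for group, mean, flag in (("s", 480.0, True), ("n", 330.0, False)):
            mu = math.log(mean) - sigma**2 / 2
            for i, ln in enumerate(rng.lognormal(mu, sigma, 5000)):
                ln = max(int(round(ln)), 10)
                oid = f"{group}{i}"
                orfs.append(Orf(oid, "m", "c", 1, 3 * (ln + 1), "+", "", "A" * ln))
                labels[oid] = flag
        res = length_summary(labels, orfs)
        assert res.mean_len_secreted == pytest.approx(480, abs=10)
        assert res.mean_len_nonsecreted == pytest.approx(330, abs=10)
        assert res.test.p_value < 1e-3

    def test_empty_group_errors(self):
        orf = Orf("a", "m", "c", 1, 6, "+", "", "M")
        with pytest.raises(ValueError):
            length_summary({"a": True}, [orf])


class TestBiosyntheticCost:
    def test_uniform_and_mixed_sequences(self):
        table = load_cost_table()
        assert cost_per_residue("GG", table) == pytest.approx(table["G"])
        assert cost_per_residue("GW", table) == pytest.approx((table["G"] + table["W"]) / 2)

    def test_matches_direct_summation(self):
        table = load_cost_table()
        rng = random.Random(2)
        for _ in range(50):
            seq = "".join(rng.choice(list(table)) for _ in range(rng.randint(1, 300)))
            expected = sum(table[c] for c in seq) / len(seq)
            assert cost_per_residue(seq, table) == pytest.approx(expected, abs=1e-12)

    def test_cost_table_covers_standard_residues(self):
        table = load_cost_table()
        assert set("ACDEFGHIKLMNPQRSTVWY") <= set(table)
        assert all(v > 0 for v in table.values())

    def test_unknown_residue_handling(self):
        table = load_cost_table()
        assert cost_per_residue("GXG", table) == pytest.approx(table["G"])
        with pytest.raises(ValueError):
            cost_per_residue("GXG", table, on_unknown="error")
        with pytest.raises(ValueError):
            cost_per_residue("", table)


def test_secretion_table_roundtrip(tmp_path):
    anns = annotate_secretion(
        ["a", "b"], {"a": SpClass.SEC_SPI, "b": SpClass.LIPO}, {"a": 0, "b": 0}
    )
    path = tmp_path / "secretion.tsv"
    write_secretion_table(anns, path, meta={"source": "test"})
    assert read_secretion_table(path) == anns
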