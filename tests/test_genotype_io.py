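"""PLINK/Oxford I/O, QC semantics and panel merging."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import make_genotypes
from oracles import decode_bed_byte
from rohsweep import genotype_io as gio
from rohsweep.types import MISSING, GenotypeMatrix, HaplotypePanel, MarkerMap


@pytest.fixture
def ped_fixture(tmp_path):
    """Hand-written 2-individual, 3-marker text fileset.

    Alleles chosen so the lexicographic allele_a/allele_b rule gives
    dosages [[0,1,2],[2,missing,0]].
    """
    (tmp_path / "toy.map").write_text(
        "1 m1 0 1000\n1 m2 0 2000\n1 m3 0 3000\n"
    )
    (tmp_path / "toy.ped").write_text(
        "F1 i1 0 0 0 -9 A A A G G G\n"
        "F1 i2 0 0 0 -9 G G 0 0 A A\n"
    )
    return tmp_path / "toy"


def test_ped_fixture_decodes_to_expected_dosages(ped_fixture):
    g = gio.read_plink(ped_fixture, format="text")
    assert g.calls.tolist() == [[0, 1, 2], [2, MISSING, 0]]
    assert list(g.map.table["allele_a"]) == ["A", "A", "A"]
    assert list(g.samples["individual_id"]) == ["i1", "i2"]


def test_text_binary_text_round_trip_is_identity(ped_fixture, tmp_path):
    g = gio.read_plink(ped_fixture, format="text")
    gio.write_plink(g, tmp_path / "bin", format="binary")
    g2 = gio.read_plink(tmp_path / "bin", format="binary")
    gio.write_plink(g2, tmp_path / "txt", format="text")
    g3 = gio.read_plink(tmp_path / "txt", format="text")
    np.testing.assert_array_equal(g.calls, g3.calls)
    pd.testing.assert_frame_equal(g.map.table, g3.map.table)
    pd.testing.assert_frame_equal(g.samples, g3.samples)


def test_bed_byte_decoding_matches_bitwise_oracle(tmp_path):
    """One marker, 4 individuals packed in the byte 0b11011000."""
    byte = 0b11011000
    (tmp_path / "b.bim").write_text("1\tm1\t0\t100\tA\tG\n")
    (tmp_path / "b.fam").write_text(
        "".join(f"F ind{k} 0 0 0 -9\n" for k in range(4))
    )
    (tmp_path / "b.bed").write_bytes(bytes([0x6C, 0x1B, 0x01, byte]))
    g = gio.read_plink(tmp_path / "b", format="binary")
    assert g.calls[:, 0].tolist() == decode_bed_byte(byte, 4)


def test_bed_magic_byte_mismatch_raises(tmp_path):
    (tmp_path / "b.bim").write_text("1\tm1\t0\t100\tA\tG\n")
    (tmp_path / "b.fam").write_text("F i 0 0 0 -9\n")
    (tmp_path / "b.bed").write_bytes(bytes([0x00, 0x1B, 0x01, 0x00]))
    with pytest.raises(ValueError, match="magic"):
        gio.read_plink(tmp_path / "b", format="binary")


def _allele_pairs(g):
    """Genotypes as unordered allele-label pairs (coding-invariant view)."""
    a = g.map.table["allele_a"].to_numpy(dtype=object)
    b = g.map.table["allele_b"].to_numpy(dtype=object)
    out = np.empty(g.calls.shape, dtype=object)
    for j in range(g.n_markers):
        lut = {0: (a[j], a[j]), 1: tuple(sorted((a[j], b[j]))), 2: (b[j], b[j]),
               MISSING: ("0", "0")}
        out[:, j] = [lut[int(d)] for d in g.calls[:, j]]
    return out


@settings(max_examples=20, deadline=None, derandomize=True)
@given(st.integers(0, 2**31 - 1), st.integers(1, 9), st.integers(1, 30))
def test_random_matrix_round_trips_both_formats(tmp_path_factory, seed, n, m):
    """Binary round trips are bit-exact; text round trips preserve the
    allele-level genotypes (a .map file carries no allele labels, so the
    dosage coding of a marker whose second allele is never observed is not
    recoverable from text — exactly PLINK's own .ped semantics)."""
    rng = np.random.default_rng(seed)
    calls = rng.choice([0, 1, 2, MISSING], size=(n, m)).astype(np.int8)
    g = make_genotypes(calls)
    tmp = tmp_path_factory.mktemp("rt")
    gio.write_plink(g, tmp / "bin", format="binary")
    g2 = gio.read_plink(tmp / "bin", format="binary")
    np.testing.assert_array_equal(g.calls, g2.calls)
    gio.write_plink(g, tmp / "txt", format="text")
    g3 = gio.read_plink(tmp / "txt", format="text")
    np.testing.assert_array_equal(_allele_pairs(g), _allele_pairs(g3))
    np.testing.assert_array_equal(g.map.positions, g3.map.positions)


def test_single_missing_call_survives_round_trip(tmp_path):
    g = make_genotypes([[MISSING]])
    gio.write_plink(g, tmp_path / "one", format="binary")
    g2 = gio.read_plink(tmp_path / "one", format="binary")
    assert g2.calls[0, 0] == MISSING


def test_write_zero_marker_panel_produces_valid_files(tmp_path):
    g = GenotypeMatrix(
        pd.DataFrame({"individual_id": ["i1"], "population": ["P"]}),
        np.empty((1, 0), dtype=np.int8),
        MarkerMap(
            pd.DataFrame(
                columns=["chromosome", "position", "marker_id", "allele_a", "allele_b"]
            )
        ),
    )
    gio.write_plink(g, tmp_path / "empty", format="binary")
    assert (tmp_path / "empty.bed").read_bytes()[:3] == bytes([0x6C, 0x1B, 0x01])
    assert (tmp_path / "empty.bim").read_text() == ""


class TestQC:
    def test_individual_threshold_is_inclusive_on_keep_side(self):
        # ind0: 15% missing -> removed; ind1: exactly 10% -> retained
        m = 20
        calls = np.ones((3, m), dtype=np.int8)
        calls[0, :3] = MISSING  # 15%
        calls[1, :2] = MISSING  # 10%
        g = make_genotypes(calls)
        g2, rep = gio.apply_qc(g, max_snp_missing=1.0)
        assert list(g2.samples["individual_id"]) == ["ind1", "ind2"]
        assert rep.n_individuals_removed == 1

    def test_snp_missingness_computed_on_retained_individuals(self):
        # After dropping the bad individual, the SNP is complete and kept.
        calls = np.ones((10, 10), dtype=np.int8)
        calls[0, :] = MISSING  # individual removed first
        g = make_genotypes(calls)
        g2, _ = gio.apply_qc(g)
        assert g2.n_markers == 10
        assert g2.n_individuals == 9

    def test_snp_above_five_percent_missing_removed(self):
        calls = np.ones((50, 4), dtype=np.int8)
        calls[:3, 0] = MISSING  # 6% missing
        calls[:2, 1] = MISSING  # 4% missing
        g = make_genotypes(calls)
        g2, rep = gio.apply_qc(g, max_ind_missing=1.0)
        assert g2.n_markers == 3
        assert rep.n_markers_removed == 1

    def test_complete_matrix_unchanged_and_idempotent(self):
        calls = np.ones((4, 6), dtype=np.int8)
        g = make_genotypes(calls)
        g1, rep = gio.apply_qc(g)
        g2, rep2 = gio.apply_qc(g1)
        assert rep.n_individuals_removed == rep.n_markers_removed == 0
        np.testing.assert_array_equal(g1.calls, g2.calls)

    def test_non_autosomal_markers_dropped(self):
        calls = np.ones((2, 4), dtype=np.int8)
        g = make_genotypes(calls)
        g.map.table.loc[3, "chromosome"] = 30  # beyond the cattle autosomes
        g2, rep = gio.apply_qc(g)
        assert g2.n_markers == 3
        assert rep.n_non_autosomal_removed == 1

    def test_all_individuals_removed_is_an_error(self):
        calls = np.full((2, 4), MISSING, dtype=np.int8)
        with pytest.raises(ValueError, match="individuals"):
            gio.apply_qc(make_genotypes(calls))


class TestMerge:
    @staticmethod
    def _panel(marker_ids, n_ind=2, seed=0, positions=None):
        rng = np.random.default_rng(seed)
        calls = rng.integers(0, 3, size=(n_ind, len(marker_ids))).astype(np.int8)
        g = make_genotypes(calls, positions=positions)
        g.map.table["marker_id"] = marker_ids
        return GenotypeMatrix(g.samples, g.calls, MarkerMap(g.map.table))

    def test_merge_intersects_markers_and_concatenates_samples(self):
        # shared ids B and C sit at identical coordinates in both panels
        a = self._panel(["A", "B", "C"], seed=1, positions=[10_000, 20_000, 30_000])
        b = self._panel(["B", "C", "D"], seed=2, positions=[20_000, 30_000, 40_000])
        merged = gio.merge_panels([a, b])
        assert set(merged.map.marker_ids) == {"B", "C"}
        assert merged.n_individuals == 4

    def test_allele_conflict_names_the_marker(self):
        a = self._panel(["A", "B", "C"], seed=1)
        b = self._panel(["A", "B", "C"], seed=2)
        b.map.table.loc[1, ["allele_a", "allele_b"]] = ["T", "C"]
        b = GenotypeMatrix(b.samples, b.calls, MarkerMap(b.map.table))
        with pytest.raises(ValueError, match="'B'"):
            gio.merge_panels([a, b])

    def test_self_merge_doubles_samples_keeps_markers(self):
        a = self._panel(["A", "B", "C"])
        merged = gio.merge_panels([a, a])
        assert merged.n_individuals == 4
        assert merged.n_markers == 3
        np.testing.assert_array_equal(merged.calls[:2], merged.calls[2:])


class TestHaps:
    @pytest.fixture
    def haps_fixture(self, tmp_path):
        (tmp_path / "h.haps").write_text(
            "1 m1 1000 A G 0 1 1 0\n1 m2 2000 A C 1 1 0 0\n"
        )
        (tmp_path / "h.sample").write_text(
            "ID_1 ID_2 missing\n0 0 0\nP i1 0\nP i2 0\n"
        )
        return tmp_path / "h"

    def test_fixture_parses_to_hand_checked_matrix(self, haps_fixture):
        h = gio.read_haps(haps_fixture)
        assert h.haplotypes.tolist() == [[0, 1], [1, 1], [1, 0], [0, 0]]
        assert h.n_individuals == 2

    def test_round_trip_identity(self, haps_fixture, tmp_path):
        h = gio.read_haps(haps_fixture)
        gio.write_haps(h, tmp_path / "h2")
        h2 = gio.read_haps(tmp_path / "h2")
        np.testing.assert_array_equal(h.haplotypes, h2.haplotypes)
        pd.testing.assert_frame_equal(h.map.table, h2.map.table)

    def test_sample_count_mismatch_raises(self, haps_fixture, tmp_path):
        (tmp_path / "h.sample").write_text("ID_1 ID_2 missing\n0 0 0\nP i1 0\n")
        with pytest.raises(ValueError, match="haplotype"):
            gio.read_haps(haps_fixture)

    def test_non_binary_symbol_raises(self, tmp_path):
        (tmp_path / "h.haps").write_text("1 m1 1000 A G 0 2\n")
        (tmp_path / "h.sample").write_text("ID_1 ID_2 missing\n0 0 0\nP i1 0\n")
        with pytest.raises(ValueError, match="non-binary"):
            gio.read_haps(tmp_path / "h")


class TestAttachAncestral:
    @staticmethod
    def _panel(column, alleles=("A", "G")):
        hap = np.array(column, dtype=np.uint8).reshape(-1, 1)
        mm = MarkerMap(
            pd.DataFrame(
                {
                    "chromosome": [1],
                    "position": [1000],
                    "marker_id": ["m1"],
                    "allele_a": [alleles[0]],
                    "allele_b": [alleles[1]],
                }
            )
        )
        samples = pd.DataFrame(
            {
                "individual_id": [f"i{k}" for k in range(len(column) // 2)],
                "population": "P",
            }
        )
        return HaplotypePanel(hap, mm, samples)

    def test_user_table_flips_column_when_ancestral_is_allele_b(self):
        h = self._panel([0, 1, 1, 0])
        h2 = gio.attach_ancestral(h, {"m1": "G"}, fallback="none")
        assert h2.haplotypes[:, 0].tolist() == [1, 0, 0, 1]
        assert h2.map.table.loc[0, "allele_a"] == "G"
        assert h2.ancestral_source[0] == "user"

    def test_major_fallback_flips_derived_frequency_below_half(self):
        h = self._panel([1, 1, 1, 0, 1, 0, 1, 1, 1, 0])  # derived freq 0.7
        h2 = gio.attach_ancestral(h, fallback="major")
        assert h2.derived_frequencies()[0] == pytest.approx(0.3)
        assert h2.ancestral_source[0] == "major"

    def test_fallback_none_drops_unassigned_markers(self):
        h = self._panel([0, 1, 1, 0])
        h2 = gio.attach_ancestral(h, {}, fallback="none")
        assert h2.n_markers == 0

    def test_foreign_ancestral_allele_raises(self):
        h = self._panel([0, 1, 1, 0])
        with pytest.raises(ValueError, match="ancestral"):
            gio.attach_ancestral(h, {"m1": "C"})

    def test_major_fallback_caps_derived_frequency(self, rng):
        hap = (rng.random((40, 30)) < rng.uniform(0.1, 0.9, 30)).astype(np.uint8)
        mm = MarkerMap(
            pd.DataFrame(
                {
                    "chromosome": 1,
                    "position": (np.arange(30) + 1) * 1000,
                    "marker_id": [f"m{i}" for i in range(30)],
                    "allele_a": "A",
                    "allele_b": "G",
                }
            )
        )
        samples = pd.DataFrame(
            {"individual_id": [f"i{k}" for k in range(20)], "population": "P"}
        )
        h2 = gio.attach_ancestral(
            HaplotypePanel(hap, mm, samples), fallback="major"
        )
        assert (h2.derived_frequencies() <= 0.5).all()
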