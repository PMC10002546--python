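import numpy as np
import pandas as pd
import pytest

from crossortho.crosspecies import (
    OrthologMap,
    anchor_groups,
    average_profiles,
    correlate_profiles,
    harmonize_orthologs,
    merge_on_orthologs,
)
from crossortho.errors import PipelineError
from crossortho.io_tenx import OrthologTable
from crossortho.qc_normalize import NormalizedMatrix
from _oracles import harmonize_reference, pearson_closed_form


def _table(a, b, pairs):
    return OrthologTable(species_a=a, species_b=b, pairs=pairs)


def _layer(dense, gene_ids, species="s"):
    dense = np.asarray(dense, dtype=float)
    return NormalizedMatrix(
        values=dense,
        layer="lognorm",
        species=species,
        gene_ids=list(gene_ids),
        gene_symbols=list(gene_ids),
        cell_barcodes=[f"B{i}" for i in range(dense.shape[1])],
    )


class TestHarmonize:
    def test_minimal_two_table_map(self):
        omap = harmonize_orthologs(
            [_table("h", "b", [("h1", "b1")]), _table("h", "r", [("h1", "r1")])],
            "h",
        )
        assert omap.reference_ids == ["h1"]
        assert omap.rows.loc["h1", "b"] == "b1"
        assert omap.rows.loc["h1", "r"] == "r1"

    def test_one_to_many_gene_dropped_entirely(self):
        omap = harmonize_orthologs(
            [
                _table("h", "b", [("h1", "b1"), ("h1", "b2"), ("h2", "b3")]),
                _table("h", "r", [("h1", "r1"), ("h2", "r2")]),
            ],
            "h",
        )
        assert omap.reference_ids == ["h2"]

    def test_gene_absent_from_one_table_excluded(self):
        omap = harmonize_orthologs(
            [
                _table("h", "b", [("h1", "b1"), ("h2", "b2")]),
                _table("h", "r", [("h2", "r2")]),
            ],
            "h",
        )
        assert omap.reference_ids == ["h2"]

    def test_reference_orientation_is_irrelevant(self):
        omap = harmonize_orthologs(
            [_table("b", "h", [("b1", "h1")]), _table("h", "r", [("h1", "r1")])],
            "h",
        )
        assert omap.rows.loc["h1", "b"] == "b1"

    def test_empty_result_reports_survival_counts(self):
        with pytest.raises(PipelineError, match="1-1"):
            harmonize_orthologs(
                [
                    _table("h", "b", [("h1", "b1"), ("h1", "b2")]),
                    _table("h", "r", [("h1", "r1")]),
                ],
                "h",
            )

    def test_matches_bruteforce_on_random_toy_tables(self, rng):
        for _ in range(50):
            tables, raw = _random_tables(rng)
            ref = harmonize_reference(raw, "h")
            if not ref:
                with pytest.raises(PipelineError):
                    harmonize_orthologs(tables, "h")
                continue
            omap = harmonize_orthologs(tables, "h")
            assert set(omap.reference_ids) == set(ref)
            for r, per_sp in ref.items():
                for s, g in per_sp.items():
                    assert omap.rows.loc[r, s] == g


def _random_tables(rng, n_genes=40):
    species = ["b", "r"]
    tables, raw = [], []
    for s in species:
        n = int(rng.integers(5, n_genes))
        pairs = [(f"h{i}", f"{s}{i}") for i in rng.integers(0, n_genes, n)]
        # inject many-to-many rows
        for _ in range(int(rng.integers(0, 8))):
            pairs.append(
                (f"h{rng.integers(0, n_genes)}", f"{s}{rng.integers(0, n_genes)}")
            )
        pairs = list(dict.fromkeys(pairs))
        tables.append(_table("h", s, pairs))
        raw.append(("h", s, pairs))
    return tables, raw


class TestMergeOnOrthologs:
    def _omap(self):
        rows = pd.DataFrame(
            {"h": ["h1", "h2", "h3"], "b": ["b1", "b2", "b3"]},
            index=["h1", "h2", "h3"],
        )
        return OrthologMap(reference_species="h", rows=rows)

    def test_output_has_map_rows_in_reference_order(self):
        nm = _layer([[1, 2], [3, 4]], ["b2", "b1"], species="b")
        merged = merge_on_orthologs([nm], self._omap())
        out = merged["b"]
        assert out.gene_ids == ["h1", "h2", "h3"]
        np.testing.assert_array_equal(out.values[0], [3, 4])  # b1 row
        np.testing.assert_array_equal(out.values[1], [1, 2])  # b2 row

    def test_missing_gene_becomes_zero_row(self, caplog):
        nm = _layer([[1, 2]], ["b1"], species="b")
        merged = merge_on_orthologs([nm], self._omap())
        np.testing.assert_array_equal(merged["b"].values[1], [0, 0])
        np.testing.assert_array_equal(merged["b"].values[2], [0, 0])

    def test_present_values_carried_bit_identically(self, rng):
        dense = rng.normal(size=(3, 5))
        perm = [2, 0, 1]
        nm = _layer(dense, [f"b{i+1}" for i in perm], species="b")
        merged = merge_on_orthologs([nm], self._omap())
        for out_row, src in enumerate(np.argsort(perm)):
            np.testing.assert_array_equal(
                merged["b"].values[out_row], dense[src]
            )


class TestProfilesAndCorrelation:
    def test_single_group_profile_is_row_means(self, rng):
        dense = rng.normal(size=(4, 6)) ** 2
        nm = _layer(dense, ["g1", "g2", "g3", "g4"])
        prof = average_profiles(nm, np.zeros(6, int))
        np.testing.assert_allclose(prof.loc[0], dense.mean(axis=1))

    def test_two_cell_mean(self):
        nm = _layer([[0, 2]], ["g"])
        prof = average_profiles(nm, np.array([0, 0]))
        assert prof.loc[0, "g"] == 1.0

    def test_profiles_invariant_to_cell_permutation(self, rng):
        dense = rng.normal(size=(5, 8))
        groups = np.array([0, 1, 0, 1, 1, 0, 1, 0])
        nm = _layer(dense, [f"g{i}" for i in range(5)])
        perm = rng.permutation(8)
        nm_p = _layer(dense[:, perm], [f"g{i}" for i in range(5)])
        a = average_profiles(nm, groups)
        b = average_profiles(nm_p, groups[perm])
        pd.testing.assert_frame_equal(a, b)

    def test_identical_profiles_have_unit_diagonal(self, rng):
        prof = pd.DataFrame(
            rng.normal(size=(4, 30)), columns=[f"g{i}" for i in range(30)]
        )
        cm = correlate_profiles(prof, prof)
        np.testing.assert_allclose(np.diag(cm.to_numpy()), 1.0, atol=1e-12)

    def test_anti_correlated_profiles(self):
        pa = pd.DataFrame([[1.0, 2.0, 3.0]], columns=list("xyz"))
        pb = pd.DataFrame([[3.0, 2.0, 1.0]], columns=list("xyz"))
        assert correlate_profiles(pa, pb).iloc[0, 0] == pytest.approx(-1.0)

    def test_three_point_closed_form(self):
        pa = pd.DataFrame([[1.0, 2.0, 3.0]], columns=list("xyz"))
        pb = pd.DataFrame([[1.0, 2.0, 4.0]], columns=list("xyz"))
        expected = pearson_closed_form([1, 2, 3], [1, 2, 4])
        got = correlate_profiles(pa, pb).iloc[0, 0]
        assert got == pytest.approx(expected, abs=1e-12)
        assert got == pytest.approx(0.981980506, abs=1e-9)

    def test_zero_variance_profile_correlates_zero(self):
        pa = pd.DataFrame([[1.0, 1.0, 1.0]], columns=list("xyz"))
        pb = pd.DataFrame([[1.0, 2.0, 4.0]], columns=list("xyz"))
        assert correlate_profiles(pa, pb).iloc[0, 0] == 0.0

    def test_gene_order_mismatch_rejected(self):
        pa = pd.DataFrame([[1.0, 2.0]], columns=["a", "b"])
        pb = pd.DataFrame([[1.0, 2.0]], columns=["b", "a"])
        with pytest.raises(PipelineError):
            correlate_profiles(pa, pb)


class TestAnchoring:
    def test_diagonal_argmax(self):
        cm = pd.DataFrame([[0.9, 0.2], [0.1, 0.8]], index=[0, 1], columns=[0, 1])
        anchors = anchor_groups(cm).assignments
        assert anchors.loc[0, "best"] == 0 and anchors.loc[1, "best"] == 1
        assert anchors.loc[0, "margin"] == pytest.approx(0.7)
        assert not anchors["tie"].any()

    def test_tie_flag_and_lower_index_preference(self):
        cm = pd.DataFrame([[0.5, 0.5]], index=["a"], columns=["b0", "b1"])
        anchors = anchor_groups(cm, tie_epsilon=1e-6).assignments
        assert anchors.loc["a", "best"] == "b0"
        assert bool(anchors.loc["a", "tie"])
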