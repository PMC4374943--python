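"""Matrix data model, validation and file round trips."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from hollownet import (
    AbundanceMatrix,
    DegenerateNetworkError,
    IncidenceMatrix,
    MatrixInputError,
    export_edges,
    read_edges,
    read_guilds,
    read_matrix,
    write_matrix,
)

from conftest import labeled


class TestValidation:
    def test_all_ones_counts(self, tmp_path):
        p = tmp_path / "m.csv"
        p.write_text("sp,h1,h2,h3\na,1,1,1\nb,1,1,1\nc,1,1,1\n")
        m = read_matrix(p)
        assert m.links == 9 and m.individuals == 9

    def test_negative_cell_names_offender(self, tmp_path):
        p = tmp_path / "m.csv"
        p.write_text("sp,h1,h2\na,0,3\nb,-1,2\n")
        with pytest.raises(MatrixInputError, match=r"'b'.*'h1'"):
            read_matrix(p)

    def test_non_integer_cell_rejected(self, tmp_path):
        p = tmp_path / "m.csv"
        p.write_text("sp,h1,h2\na,0,3\nb,1.5,2\n")
        with pytest.raises(MatrixInputError, match=r"1\.5"):
            read_matrix(p)

    def test_duplicate_labels_rejected(self, tmp_path):
        p = tmp_path / "m.csv"
        p.write_text("sp,h1,h1\na,0,3\nb,1,2\n")
        with pytest.raises(MatrixInputError, match="duplicate"):
            read_matrix(p)

    def test_labels_whitespace_trimmed(self):
        m = AbundanceMatrix([[1]], (" a ",), ("h 1",))
        assert m.row_labels == ("a",) and m.col_labels == ("h 1",)

    def test_incidence_rejects_counts(self):
        with pytest.raises(MatrixInputError):
            IncidenceMatrix([[2]], ("a",), ("h",))

    def test_paper_scale_dimensions(self, tmp_path):
        rng = np.random.default_rng(0)
        vals = (rng.random((137, 30)) < 0.15).astype(int)
        p = tmp_path / "big.csv"
        write_matrix(labeled(vals), p)
        m = read_matrix(p)
        assert m.shape == (137, 30)


class TestTransforms:
    def test_binarize(self):
        m = labeled([[3, 0], [1, 2]])
        assert (m.binarize().values == [[1, 0], [1, 1]]).all()

    def test_binarize_all_zero(self):
        m = labeled([[0, 0], [0, 0]])
        assert m.binarize().values.sum() == 0

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=25, deadline=None)
    def test_binarize_idempotent_and_conserves_links(self, seed):
        rng = np.random.default_rng(seed)
        m = labeled((rng.random((5, 4)) < 0.5) * rng.integers(1, 9, (5, 4)))
        b = m.binarize()
        assert b.links == m.links
        assert (b.binarize().values == b.values).all()

    def test_drop_empty(self):
        m = labeled([[1, 0], [0, 0]])
        d = m.drop_empty()
        assert d.shape == (1, 1) and d.row_labels == ("sp0",)

    def test_drop_empty_noop(self):
        m = labeled([[1, 0], [0, 2]])
        assert m.drop_empty() is m

    def test_drop_empty_all_zero_degenerate(self):
        with pytest.raises(DegenerateNetworkError):
            labeled([[0, 0], [0, 0]]).drop_empty()


class TestEdgesAndGuilds:
    def test_edge_count_equals_links(self, tmp_path):
        m = labeled([[2, 0], [0, 1]])
        p = tmp_path / "e.csv"
        export_edges(m, p)
        lines = p.read_text().strip().splitlines()
        assert len(lines) - 1 == m.links == 2
        assert "sp0,h0,2" in lines and "sp1,h1,1" in lines

    def test_edge_list_round_trip(self, tmp_path):
        rng = np.random.default_rng(3)
        m = labeled((rng.random((6, 5)) < 0.6) * rng.integers(1, 9, (6, 5))).drop_empty()
        p = tmp_path / "e.csv"
        export_edges(m, p)
        back = read_edges(p)
        assert set(back.row_labels) <= set(m.row_labels)
        left = back.to_dataframe().loc[list(m.row_labels), list(m.col_labels)]
        assert (left.to_numpy() == m.values).all()

    def test_matrix_csv_round_trip(self, tmp_path):
        rng = np.random.default_rng(4)
        m = labeled((rng.random((7, 4)) < 0.5) * rng.integers(1, 50, (7, 4)))
        for name in ("m.csv", "m.tsv"):
            p = tmp_path / name
            write_matrix(m, p)
            back = read_matrix(p)
            assert back.row_labels == m.row_labels
            assert back.col_labels == m.col_labels
            assert (back.values == m.values).all()

    def test_graphml_node_attributes(self, tmp_path):
        import networkx as nx

        m = labeled([[2, 1], [0, 3]])
        p = tmp_path / "g.graphml"
        export_edges(m, p, fmt="graphml", guilds={"sp0": "SX"}, tiers={"h1": "core_a"})
        g = nx.read_graphml(p)
        assert g.nodes["sp0"]["guild"] == "SX"
        assert g.nodes["sp0"]["level"] == "species"
        assert g.nodes["h1"]["core_tier"] == "core_a"
        assert g.edges["sp1", "h1"]["weight"] == 3

    def test_guild_map(self, tmp_path):
        p = tmp_path / "g.csv"
        p.write_text("species,guild\na,SX\nb,P\n")
        assert read_guilds(p) == {"a": "SX", "b": "P"}
        p.write_text("species,guild\na,QQ\n")
        with pytest.raises(MatrixInputError, match="QQ"):
            read_guilds(p)
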