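"""Artifact writers, heat maps, clustering, and the pipeline."""

import numpy as np
import pytest

import ums
from ums.constants import AA_ALPHABET
from ums.reporting import (
    PipelineError,
    _color,
    read_attribute_file,
    read_descriptor_file,
    read_matrix,
    render_clustered_heatmap,
    render_standard_heatmap,
    write_descriptor_file,
    write_matrix,
    write_structure_coloring,
)


@pytest.fixture(scope="module")
def helix10_descriptors(helix10_matrix, helix10):
    return ums.build_descriptors(helix10_matrix, ums.residue_depth(helix10))


class TestMatrixFile:
    def test_line_count_and_header(self, helix10_matrix, tmp_path):
        p = tmp_path / "m.txt"
        write_matrix(helix10_matrix, p)
        lines = p.read_text().splitlines()
        assert len(lines) == 11  # header + 10 rows
        assert lines[0].split("\t")[1:] == list(AA_ALPHABET)

    def test_round_trip_at_printed_precision(self, helix10_matrix, tmp_path):
        p = tmp_path / "m.txt"
        write_matrix(helix10_matrix, p)
        back = read_matrix(p)
        assert back.row_keys == helix10_matrix.row_keys
        assert back.wt_aas == helix10_matrix.wt_aas
        np.testing.assert_allclose(back.values, helix10_matrix.values, atol=5e-4)

    def test_cell_matches_scan_record(self, helix10_matrix, helix10_records, tmp_path):
        p = tmp_path / "m.txt"
        write_matrix(helix10_matrix, p)
        back = read_matrix(p)
        rec = next(r for r in helix10_records if r.seq_number == 2 and r.mut_aa == "W")
        i = back.row_keys.index(rec.site_key)
        j = AA_ALPHABET.index("W")
        assert back.values[i, j] == pytest.approx(ums.propensity(rec.ddg), abs=5e-4)


class TestDescriptorFile:
    def test_columns_and_round_trip(self, helix10_descriptors, tmp_path):
        p = tmp_path / "d.txt"
        write_descriptor_file(helix10_descriptors, p)
        lines = p.read_text().splitlines()
        assert lines[0].split("\t") == [
            "sequence", "avg_propensity", "foldability", "entropy", "depth",
        ]
        assert all(len(ln.split("\t")) == 5 for ln in lines[1:])
        back = read_descriptor_file(p)
        assert len(back) == len(helix10_descriptors)
        for a, b in zip(back, helix10_descriptors):
            assert a.wt_aa == b.wt_aa and a.seq_number == b.seq_number
            assert a.avg_propensity == pytest.approx(b.avg_propensity, abs=5e-4)
            assert a.depth == pytest.approx(b.depth, abs=5e-4)

    def test_empty_is_error(self, tmp_path):
        with pytest.raises(ValueError):
            write_descriptor_file([], tmp_path / "d.txt")


class TestStandardHeatmap:
    def test_cells_and_colors(self, helix10_matrix, tmp_path):
        p = tmp_path / "s.html"
        render_standard_heatmap(helix10_matrix, p)
        html = p.read_text()
        assert html.count("<rect") == 200
        assert "<title>" in html  # hover labels

    def test_color_anchors(self):
        assert _color(0.0) == "#0000ff"
        assert _color(0.5) == "#ffffff"
        assert _color(1.0) == "#ff0000"

    def test_deterministic_bytes(self, helix10_matrix, tmp_path):
        a, b = tmp_path / "a.html", tmp_path / "b.html"
        render_standard_heatmap(helix10_matrix, a)
        render_standard_heatmap(helix10_matrix, b)
        assert a.read_bytes() == b.read_bytes()


def _leaf_order_naive(vals, method="average"):
    """Independent O(n^3) agglomerative clustering (euclidean), returning the
    dendrogram leaf order with scipy's cluster-merge ordering convention."""
    n = len(vals)
    members = {i: [i] for i in range(n)}
    active = list(range(n))
    dist = {
        (i, j): float(np.linalg.norm(vals[i] - vals[j]))
        for i in range(n)
        for j in range(i + 1, n)
    }

    def d(a, b):
        total = 0.0
        for x in members[a]:
            for y in members[b]:
                total += dist[(min(x, y), max(x, y))] if x != y else 0.0
        if method == "average":
            return total / (len(members[a]) * len(members[b]))
        return max(
            dist[(min(x, y), max(x, y))] for x in members[a] for y in members[b]
        )

    order = {i: [i] for i in range(n)}
    nxt = n
    while len(active) > 1:
        best = None
        for ai in range(len(active)):
            for bi in range(ai + 1, len(active)):
                a, b = active[ai], active[bi]
                dd = d(a, b)
                if best is None or dd < best[0] - 1e-12:
                    best = (dd, a, b)
        _, a, b = best
        members[nxt] = members[a] + members[b]
        order[nxt] = order[a] + order[b]
        active = [x for x in active if x not in (a, b)] + [nxt]
        nxt += 1
    return order[active[0]]


class TestClusteredHeatmap:
    def test_identical_rows_adjacent(self, tmp_path):
        rng = np.random.default_rng(0)
        vals = rng.uniform(0, 1, (6, 20))
        vals[4] = vals[1]  # two identical rows far apart in input order
        keys = [("A", i + 1, "") for i in range(6)]
        mat = ums.MutationMatrix(keys, list("ACDEFG"[:6]), vals)
        p = tmp_path / "c.html"
        render_clustered_heatmap(mat, p)
        html = p.read_text()
        # identical rows C2/F5 (wt aa C at 2, F at 5) must be adjacent leaves
        rows = [seg.split("<")[0] for seg in html.split("text-anchor=\"end\">")[1:]]
        i, j = rows.index("C2"), rows.index("F5")
        assert abs(i - j) == 1

    def test_cysteine_like_rows_form_one_subtree(self, tmp_path):
        """Rows sharing an extreme mutation pattern (as disulfide cysteines
        do) cluster into one contiguous block of leaves."""
        rng = np.random.default_rng(1)
        vals = rng.uniform(0.3, 0.6, (12, 20))
        cys_rows = [1, 4, 7, 10]
        for r in cys_rows:
            vals[r] = 0.02
            vals[r, 5] = 0.98  # shared extreme column pattern
        keys = [("A", i + 1, "") for i in range(12)]
        wts = ["C" if i in cys_rows else "A" for i in range(12)]
        mat = ums.MutationMatrix(keys, wts, vals)
        p = tmp_path / "c.html"
        render_clustered_heatmap(mat, p)
        html = p.read_text()
        rows = [seg.split("<")[0] for seg in html.split("text-anchor=\"end\">")[1:]]
        cys_positions = sorted(rows.index(f"C{r + 1}") for r in cys_rows)
        assert cys_positions == list(range(cys_positions[0], cys_positions[0] + 4))

    def test_leaf_order_matches_independent_oracle(self, tmp_path):
        rng = np.random.default_rng(7)
        vals = rng.uniform(0, 1, (7, 20))
        keys = [("A", i + 1, "") for i in range(7)]
        mat = ums.MutationMatrix(keys, ["A"] * 7, vals)
        p = tmp_path / "c.html"
        render_clustered_heatmap(mat, p)
        html = p.read_text()
        rows = [seg.split("<")[0] for seg in html.split("text-anchor=\"end\">")[1:]]
        got = [int(lbl[1:]) - 1 for lbl in rows]
        want = _leaf_order_naive(vals)
        assert got == want or got == want[::-1]

    def test_cell_multiset_preserved(self, helix10_matrix, tmp_path):
        ps, pc = tmp_path / "s.html", tmp_path / "c.html"
        render_standard_heatmap(helix10_matrix, ps)
        render_clustered_heatmap(helix10_matrix, pc)

        def values(path):
            out = []
            for seg in path.read_text().split("<title>")[1:]:
                if "&#8594;" not in seg:  # skip the page <title>
                    continue
                out.append(float(seg.split(": ")[1].split("<")[0]))
            return sorted(out)

        assert values(ps) == values(pc)

    def test_single_row_falls_back(self, tmp_path, caplog):
        mat = ums.MutationMatrix([("A", 1, "")], ["A"], np.full((1, 20), 0.5))
        p = tmp_path / "c.html"
        with caplog.at_level("WARNING", logger="ums"):
            render_clustered_heatmap(mat, p)
        assert p.exists()
        assert any("standard" in r.message for r in caplog.records)


class TestStructureColoring:
    def test_script_and_attr(self, helix3, tmp_path):
        mat = ums.MutationMatrix(
            [s.key for s in helix3.sites],
            list(helix3.sequence),
            np.array([[0.2] * 20, [0.95] * 20, [0.5] * 20]),
        )
        descs = ums.build_descriptors(mat, ums.residue_depth(helix3))
        script = tmp_path / "x_coloring.py"
        write_structure_coloring(helix3, descs, script)
        text = script.read_text()
        for s in helix3.sites:
            assert f":{s.seq_number}.{s.chain_id}" in text
        attr = tmp_path / "x_foldability.attr"
        values = read_attribute_file(attr)
        for d in descs:
            assert values[(d.chain_id, d.seq_number, d.insertion_code)] == pytest.approx(
                d.foldability, abs=5e-4
            )

    def test_zero_foldability_is_red_and_critical(self, helix3, tmp_path, caplog):
        mat = ums.MutationMatrix(
            [s.key for s in helix3.sites],
            list(helix3.sequence),
            np.array([[0.99] * 20, [0.0] * 20, [0.0] * 20]),
        )
        descs = ums.build_descriptors(mat, ums.residue_depth(helix3))
        assert descs[0].foldability == 0.0
        script = tmp_path / "y_coloring.py"
        with caplog.at_level("WARNING", logger="ums"):
            write_structure_coloring(helix3, descs, script)
        text = script.read_text()
        assert "#ff0000 :1.A" in text  # foldability 0 -> ramp extreme
        assert any("critical residue" in r.message for r in caplog.records)

    def test_descriptor_site_mismatch(self, helix3, tmp_path):
        bad = [ums.ResidueDescriptor("Z", 99, "", "A", 0.5, 1.0, 0.0, 1.0)]
        with pytest.raises(KeyError):
            write_structure_coloring(helix3, bad, tmp_path / "z_coloring.py")


class TestPipeline:
    def test_manifest_and_determinism(self, helix10, tmp_path):
        cfg = ums.RunConfig(model=helix10, out_dir=tmp_path / "run1", basename="h10")
        manifest = ums.run_pipeline(cfg)
        assert set(manifest) == {
            "h10_matrix.txt", "h10_descriptor.txt", "h10_standard.html",
            "h10_cluster.html", "h10_coloring.py", "h10_foldability.attr",
            "h10_control.txt",
        }
        mat = read_matrix(tmp_path / "run1" / "h10_matrix.txt")
        assert mat.values.shape == (10, 20)  # 200 mutations
        cfg2 = ums.RunConfig(model=helix10, out_dir=tmp_path / "run2", basename="h10")
        assert ums.run_pipeline(cfg2) == manifest

    def test_bad_input_names_stage_and_cleans_up(self, tmp_path):
        out = tmp_path / "out"
        cfg = ums.RunConfig(input=tmp_path / "missing.pdb", out_dir=out)
        with pytest.raises(PipelineError, match="stage 'parse'"):
            ums.run_pipeline(cfg)
        assert list(out.iterdir()) == []
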