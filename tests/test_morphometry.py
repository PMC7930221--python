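"""SWC parsing and the nine per-arbor morphometric features."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from neurobn import compute_features, extract_branches, read_swc, toy_swc, write_swc
from neurobn.morphometry import (
    Branch,
    NeuronReconstruction,
    SwcNode,
    SwcParseError,
    arbor_extent,
    mean_branch_length,
    mean_diameter,
    mean_path_distance,
    mean_remote_bifurcation_angle,
    mean_tortuosity,
    parse_swc,
    total_length,
)
from neurobn.synthetic import TOY_SWC_FEATURES


def _transformed(recon, scale=1.0, shift=(0.0, 0.0, 0.0)):
    nodes = [
        SwcNode(
            n.id, n.type_code,
            n.x * scale + shift[0], n.y * scale + shift[1], n.z * scale + shift[2],
            n.radius * scale, n.parent_id,
        )
        for n in recon.nodes
    ]
    return NeuronReconstruction(nodes)


class TestParsing:
    def test_round_trip(self, tmp_path):
        recon = toy_swc("symmetric_Y")
        path = tmp_path / "y.swc"
        write_swc(recon, path)
        assert read_swc(path).nodes == recon.nodes

    def test_dangling_parent_named_in_error(self):
        with pytest.raises(SwcParseError, match="parent 99"):
            parse_swc("1 1 0 0 0 1 -1\n2 3 0 1 0 0.2 99\n")

    def test_duplicate_id_rejected(self):
        with pytest.raises(SwcParseError, match="duplicate"):
            parse_swc("1 1 0 0 0 1 -1\n1 3 0 1 0 0.2 1\n")

    def test_wrong_column_count_names_line(self):
        with pytest.raises(SwcParseError, match="line 2"):
            parse_swc("1 1 0 0 0 1 -1\n2 3 0 1 0\n")

    def test_comments_and_blank_lines_ignored(self):
        recon = parse_swc("# header\n\n1 1 0 0 0 1 -1  # soma\n2 3 0 1 0 0.2 1\n")
        assert len(recon.nodes) == 2

    def test_two_arbor_cell_has_both_classes(self):
        recon = toy_swc("two_arbor_cell")
        assert recon.arbor_nodes("basal") and recon.arbor_nodes("apical")


class TestBranches:
    def test_straight_branch_single(self):
        assert len(extract_branches(toy_swc("straight_branch"), "basal")) == 1

    def test_symmetric_y_three_branches(self):
        assert len(extract_branches(toy_swc("symmetric_Y"), "basal")) == 3

    def test_missing_arbor_gives_empty_list(self):
        assert extract_branches(toy_swc("straight_branch"), "apical") == []

    def test_branches_partition_compartments(self):
        for case in ("straight_branch", "right_angle_bifurcation", "symmetric_Y", "two_arbor_cell"):
            recon = toy_swc(case)
            for cls in ("basal", "apical"):
                arbor = recon.arbor_nodes(cls)
                if not arbor:
                    continue
                code = arbor[0].type_code
                n_compartments = sum(
                    1 for n in arbor
                    if n.parent_id != -1 and recon.node(n.parent_id).type_code == code
                )
                branches = extract_branches(recon, cls)
                assert sum(len(b.nodes) - 1 for b in branches) == n_compartments


class TestFeatures:
    @pytest.mark.parametrize("case", sorted(TOY_SWC_FEATURES))
    def test_fixture_ground_truth(self, case):
        feats = compute_features(toy_swc(case), rel_depth=0.28)
        for key, expected in TOY_SWC_FEATURES[case].items():
            got = feats[key]
            if isinstance(expected, float) and math.isnan(expected):
                assert math.isnan(got), key
            else:
                assert got == pytest.approx(expected, abs=1e-12), key
        assert feats["rel_depth"] == 0.28

    def test_straight_branch_has_no_bifurcation_features(self):
        recon = toy_swc("straight_branch")
        assert math.isnan(mean_path_distance(recon, "basal"))
        assert math.isnan(mean_remote_bifurcation_angle(recon, "basal"))

    def test_l_branch_tortuosity_is_sqrt2(self):
        nodes = [
            SwcNode(1, 1, 0, 0, 0, 1.0, -1),
            SwcNode(2, 3, 0, 1, 0, 0.2, 1),
            SwcNode(3, 3, 0, 2, 0, 0.2, 2),
            SwcNode(4, 3, 1, 2, 0, 0.2, 3),
        ]
        branches = extract_branches(NeuronReconstruction(nodes), "basal")
        assert mean_tortuosity(branches) == pytest.approx(math.sqrt(2), abs=1e-12)

    def test_collinear_daughters_angle_pi(self):
        nodes = [
            SwcNode(1, 1, 0, 0, 0, 1.0, -1),
            SwcNode(2, 3, 0, 1, 0, 0.2, 1),
            SwcNode(3, 3, 1, 1, 0, 0.2, 2),
            SwcNode(4, 3, -1, 1, 0, 0.2, 2),
        ]
        recon = NeuronReconstruction(nodes)
        assert mean_remote_bifurcation_angle(recon, "basal") == pytest.approx(math.pi, abs=1e-12)

    def test_mixed_radius_length_weighted_diameter(self):
        # two compartments: length 1 with radii (0.1, 0.3), length 2 with (0.3, 0.5)
        nodes = [
            SwcNode(1, 1, 0, 0, 0, 1.0, -1),
            SwcNode(2, 3, 0, 1, 0, 0.1, 1),
            SwcNode(3, 3, 0, 2, 0, 0.3, 2),
            SwcNode(4, 3, 0, 4, 0, 0.5, 3),
        ]
        branches = extract_branches(NeuronReconstruction(nodes), "basal")
        expected = (1 * (0.1 + 0.3) + 2 * (0.3 + 0.5)) / 3
        assert mean_diameter(branches) == pytest.approx(expected, abs=1e-12)

    def test_basal_only_cell_has_nan_apical_features(self):
        feats = compute_features(toy_swc("symmetric_Y"), 0.1)
        assert math.isnan(feats["a.total_length"]) and math.isnan(feats["a.height"])

    def test_zero_chord_branch_rejected(self):
        b = Branch((
            SwcNode(1, 3, 0, 0, 0, 0.2, -1),
            SwcNode(2, 3, 1, 0, 0, 0.2, 1),
            SwcNode(3, 3, 0, 0, 0, 0.2, 2),
        ))
        with pytest.raises(ValueError, match="coincident"):
            _ = b.tortuosity


class TestInvariances:
    CASES = ("right_angle_bifurcation", "symmetric_Y", "two_arbor_cell")

    @settings(max_examples=20, derandomize=True, deadline=None)
    @given(
        scale=st.floats(0.5, 20.0),
        shift=st.tuples(st.floats(-50, 50), st.floats(-50, 50), st.floats(-50, 50)),
        case=st.sampled_from(CASES),
    )
    def test_scaling_and_translation(self, scale, shift, case):
        base = compute_features(toy_swc(case), 0.3).to_dict()
        scaled = compute_features(_transformed(toy_swc(case), scale=scale), 0.3).to_dict()
        moved = compute_features(_transformed(toy_swc(case), shift=shift), 0.3).to_dict()
        for key, v in base.items():
            if key == "rel_depth" or math.isnan(v):
                continue
            stem = key.removeprefix("a.")
            if stem in ("tortuosity", "angle"):
                assert scaled[key] == pytest.approx(v, rel=1e-9), key
            else:
                assert scaled[key] == pytest.approx(v * scale, rel=1e-9), key
            assert moved[key] == pytest.approx(v, rel=1e-9, abs=1e-9), key

    def test_total_length_equals_sum_of_compartments(self):
        recon = toy_swc("two_arbor_cell")
        for cls in ("basal", "apical"):
            branches = extract_branches(recon, cls)
            comp_sum = sum(
                np.linalg.norm(b.nodes[k + 1].xyz - b.nodes[k].xyz)
                for b in branches
                for k in range(len(b.nodes) - 1)
            )
            assert total_length(branches) == pytest.approx(comp_sum, abs=1e-12)


def test_extent_axis_convention():
    h, w, d = arbor_extent(toy_swc("right_angle_bifurcation"), "basal")
    assert (h, w, d) == (2.0, 1.0, 0.0)  # Y, X, Z


def test_features_table_builder(tmp_path):
    import pandas as pd

    from neurobn.morphometry import features_table

    meta = pd.DataFrame(
        {"cell_id": ["c1", "c2"], "species": ["human", "mouse"], "rel_depth": [0.2, 0.6]}
    )
    paths = {}
    for cid in meta["cell_id"]:
        p = tmp_path / f"{cid}.swc"
        write_swc(toy_swc("two_arbor_cell"), p)
        paths[cid] = p
    table = features_table(paths, meta)
    assert list(table.index) == ["c1", "c2"]
    assert table.loc["c1", "total_length"] == pytest.approx(4.0)
    assert table.loc["c2", "rel_depth"] == 0.6
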