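"""Graph assembly: adjacency, 26-slot features, normalization, datasets."""

from dataclasses import replace

import numpy as np
import pandas as pd
import pytest

from conftest import random_rotation
from pkagraph.graph_builder import (
    DATASET_SCHEMA_VERSION,
    FeatureSchema,
    N_FEATURES,
    ResidueGraph,
    build_adjacency,
    build_dataset,
    featurize_nodes,
    load_dataset,
    normalize_dataset,
    apply_normalization,
    save_dataset,
)
from pkagraph.microenvironment import ResidueEnvironment, crop_environment
from pkagraph.residue_templates import RESIDUE_TEMPLATES
from pkagraph.structure_io import (
    AtomRecord,
    ProteinStructure,
    ResidueKey,
    attach_dipoles,
)
from pkagraph.synthetic_fixtures import (
    FixtureSpec,
    make_toy_protein,
    reference_label_table,
)


class TestBuildAdjacency:
    def test_single_atom_graph(self):
        atom = AtomRecord(1, "CA", "C", "ASP", 1, "A", np.zeros(3))
        env = ResidueEnvironment(
            key=ResidueKey("A", 1, "ASP"), radius=9.0,
            self_atoms=[atom], context_atoms=[],
        )
        A = build_adjacency(env)
        assert A.shape == (1, 1) and A[0, 0] == 1

    @pytest.mark.parametrize("rtype", ["ASP", "GLU", "HIS", "LYS"])
    def test_template_bond_pattern(self, toy_structure, rtype):
        seq = {"ASP": 1, "GLU": 3, "HIS": 5, "LYS": 7}[rtype]
        key = ResidueKey("A", seq, rtype)
        env = crop_environment(toy_structure, key, 9.0)
        A = build_adjacency(env, toy_structure.bonds)
        tmpl = RESIDUE_TEMPLATES[rtype]
        names = [a.atom_name for a in env.self_atoms]
        expected = np.eye(len(names))
        for a, b in tmpl.bonds:
            i, j = names.index(a), names.index(b)
            expected[i, j] = expected[j, i] = 1
        np.testing.assert_array_equal(A, expected)

    def test_trace_equals_node_count(self, toy_graphs):
        for g in toy_graphs:
            assert np.trace(g.adjacency) == g.n_nodes

    def test_distance_fallback_matches_template(self, toy_structure):
        key = ResidueKey("A", 1, "ASP")
        env = crop_environment(toy_structure, key, 9.0)
        # strip atom names so neither explicit bonds nor template apply
        anon = replace(env, self_atoms=[
            replace(a, atom_name=f"X{i}") for i, a in enumerate(env.self_atoms)
        ])
        anon.key = key
        A_template = build_adjacency(env, toy_structure.bonds)
        A_fallback = build_adjacency(anon, None)
        np.testing.assert_array_equal(A_template, A_fallback)


class TestFeaturizeNodes:
    def _featurize(self, structure, key, radius=9.0):
        from pkagraph.local_frame import build_local_frame
        from pkagraph.microenvironment import compute_sasa, detect_hydrogen_bonds

        env = crop_environment(structure, key, radius)
        by_name = {a.atom_name: a for a in env.self_atoms}
        frame = build_local_frame(
            by_name["CA"].position, by_name["C"].position,
            by_name["O"].position,
        )
        return env, featurize_nodes(
            env, frame, detect_hydrogen_bonds(structure),
            compute_sasa(structure),
        )

    def test_calpha_row(self, toy_structure):
        key = ResidueKey("A", 1, "ASP")
        env, X = self._featurize(toy_structure, key)
        ca_row = X[[a.atom_name for a in env.self_atoms].index("CA")]
        np.testing.assert_allclose(ca_row[FeatureSchema.COORDS], 0.0,
                                   atol=1e-10)
        assert ca_row[FeatureSchema.atom_type_index("C", True)] == 1

    def test_onehot_blocks_sum_to_one(self, toy_graphs):
        for g in toy_graphs:
            X = g.node_features
            np.testing.assert_array_equal(
                X[:, FeatureSchema.RESIDUE_ONEHOT].sum(axis=1), 1.0
            )
            np.testing.assert_array_equal(
                X[:, FeatureSchema.ATOM_TYPE_ONEHOT].sum(axis=1), 1.0
            )

    def test_isolated_residue_zero_env_features(self):
        from pkagraph.synthetic_fixtures import make_ideal_residue

        s = ProteinStructure(atoms=make_ideal_residue("ASP"))
        env, X = self._featurize(s, ResidueKey("A", 1, "ASP"))
        # no dipoles, no context, no H-bond partners: slots 8-16 all zero
        assert np.all(X[:, 7:16] == 0)

    def test_rotated_structure_identical_features(self, toy_structure):
        labels = reference_label_table(toy_structure)
        base, _ = build_dataset(toy_structure, labels, radius=9.0)
        rng = np.random.default_rng(42)
        R = random_rotation(rng)
        t = rng.normal(scale=25, size=3)
        moved = ProteinStructure(
            atoms=[
                replace(a, position=R @ a.position + t,
                        dipole=None if a.dipole is None else R @ a.dipole)
                for a in toy_structure.atoms
            ],
            bonds=toy_structure.bonds,
            source_id=toy_structure.source_id,
        )
        rotated, _ = build_dataset(moved, labels, radius=9.0)
        for g1, g2 in zip(base, rotated):
            np.testing.assert_allclose(
                g1.node_features, g2.node_features, atol=1e-8
            )


class TestNormalization:
    def _graph_with_counts(self, values, rtype="ASP"):
        n = len(values)
        X = np.zeros((n, N_FEATURES))
        X[:, FeatureSchema.RESIDUE_ONEHOT.start] = 1
        X[:, 17] = 1
        X[:, 10] = values
        return ResidueGraph(
            key=ResidueKey("A", 1, rtype), node_features=X,
            adjacency=np.eye(n), label=4.0, radius=9.0,
        )

    def test_two_point_minmax(self):
        g = self._graph_with_counts([0.0, 4.0])
        out, consts = normalize_dataset([g])
        np.testing.assert_allclose(
            sorted(out[0].node_features[:, 10]), [0.0, 1.0]
        )

    def test_constant_slot_maps_to_zero(self):
        g = self._graph_with_counts([3.0, 3.0])
        out, _ = normalize_dataset([g])
        np.testing.assert_array_equal(out[0].node_features[:, 10], 0.0)

    def test_stored_constants_reproduce(self, toy_graphs):
        normalized, consts = normalize_dataset(toy_graphs)
        again = apply_normalization(toy_graphs, consts)
        for a, b in zip(normalized, again):
            np.testing.assert_array_equal(a.node_features, b.node_features)

    def test_only_slots_11_16_touched(self, toy_graphs):
        normalized, _ = normalize_dataset(toy_graphs)
        for before, after in zip(toy_graphs, normalized):
            np.testing.assert_array_equal(
                before.node_features[:, :10], after.node_features[:, :10]
            )
            np.testing.assert_array_equal(
                before.node_features[:, 16:], after.node_features[:, 16:]
            )

    def test_empty_dataset_errors(self):
        with pytest.raises(ValueError):
            normalize_dataset([])


class TestBuildDataset:
    def test_graph_per_label(self, toy_structure):
        labels = reference_label_table(toy_structure)
        graphs, skipped = build_dataset(toy_structure, labels, radius=9.0)
        assert len(graphs) == len(labels)
        assert not skipped
        for g in graphs:
            assert g.node_features.shape == (g.n_nodes, 26)

    def test_unsupported_type_skipped_with_reason(self, toy_structure):
        labels = reference_label_table(toy_structure)
        labels = pd.concat(
            [labels, pd.DataFrame([{
                "pdb_id": toy_structure.source_id, "chain": "A",
                "resnum": 2, "restype": "CYS", "pka_exp": 8.3,
            }])],
            ignore_index=True,
        )
        graphs, skipped = build_dataset(toy_structure, labels, radius=9.0)
        assert len(graphs) == len(labels) - 1
        assert len(skipped) == 1
        assert "unsupported residue type" in skipped[0]["reason"]

    def test_zero_graphs_errors(self, toy_structure):
        labels = pd.DataFrame([{
            "pdb_id": toy_structure.source_id, "chain": "A", "resnum": 2,
            "restype": "CYS", "pka_exp": 8.3,
        }])
        with pytest.raises(ValueError, match="no graphs"):
            build_dataset(toy_structure, labels)


class TestSerialization:
    def test_roundtrip_exact(self, toy_graphs, tmp_path):
        p = tmp_path / "ds.json"
        normalized, consts = normalize_dataset(toy_graphs)
        save_dataset(normalized, p, normalization=consts)
        back, norm = load_dataset(p)
        assert len(back) == len(normalized)
        for a, b in zip(normalized, back):
            assert a.key == b.key
            assert a.label == b.label
            assert a.radius == b.radius
            np.testing.assert_array_equal(a.node_features, b.node_features)
            np.testing.assert_array_equal(a.adjacency, b.adjacency)
        np.testing.assert_array_equal(norm["min"], consts["min"])

    def test_empty_save_errors(self, tmp_path):
        with pytest.raises(ValueError):
            save_dataset([], tmp_path / "x.json")

    def test_version_mismatch_errors(self, toy_graphs, tmp_path):
        import json

        p = tmp_path / "ds.json"
        save_dataset(toy_graphs, p)
        payload = json.loads(p.read_text())
        payload["schema"] = "pkagraph-v0"
        p.write_text(json.dumps(payload))
        with pytest.raises(ValueError, match="schema"):
            load_dataset(p)


class TestResidueGraphInvariants:
    def test_asymmetric_adjacency_rejected(self):
        X = np.zeros((2, N_FEATURES))
        A = np.array([[1.0, 1.0], [0.0, 1.0]])
        with pytest.raises(ValueError, match="symmetric"):
            ResidueGraph(ResidueKey("A", 1, "ASP"), X, A, 4.0, 9.0)

    def test_missing_self_loops_rejected(self):
        X = np.zeros((2, N_FEATURES))
        A = np.array([[1.0, 1.0], [1.0, 0.0]])
        with pytest.raises(ValueError, match="diagonal"):
            ResidueGraph(ResidueKey("A", 1, "ASP"), X, A, 4.0, 9.0)
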