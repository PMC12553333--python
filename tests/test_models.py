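"""Model zoo: construction, forward contracts, invariances, configs."""

import json
from pathlib import Path

import numpy as np
import pytest

from protbench import TaskSpec
from protbench.errors import (
    EmptyGraph,
    IncompatibleArchitecture,
    ShapeMismatch,
)
from protbench.graph_features import MolecularGraph, sequence_to_peptide_graph
from protbench.synthetic import GeneratorSpec, generate
from protbench.zoo import (
    ARCHITECTURES,
    GRAPH_ARCHITECTURES,
    SEQUENCE_ARCHITECTURES,
    build_model,
    default_config,
    default_config_table,
    forward_graph,
    forward_sequence,
    load_model,
    save_model,
)
from protbench.zoo.embedding import hashed_random_provider, kmer_provider
from protbench.zoo.graph_models import GCNLayer
from protbench.zoo.batches import ModelBatch, batch_graphs

DATA = Path(__file__).parent / "data"


def _records(task, n=6, seed=0, lengths=(8, 14)):
    motifs = ("WKW", "CHC") if task.is_classification else ("WKW",)
    if task.objective == "multiclass":
        motifs = ("WKW", "CHC", "FYF")
    return generate(GeneratorSpec(task_spec=task, n_samples=n,
                                  length_range=lengths, motifs=motifs,
                                  seed=seed))


class TestBuildAndShapes:
    @pytest.mark.parametrize("arch", ARCHITECTURES)
    def test_single_regression_output_is_batch_vector(self, arch,
                                                      regression_task):
        model = build_model(arch, regression_task, seed=0)
        recs = _records(regression_task)
        out = model(model.prepare(recs[:4]))
        assert out.shape == (4,)
        assert np.isfinite(out.data).all()

    @pytest.mark.parametrize("arch", ARCHITECTURES)
    def test_pair_binary_single_logit(self, arch, pair_binary_task):
        model = build_model(arch, pair_binary_task, seed=0)
        recs = _records(pair_binary_task)
        out = model(model.prepare(recs[:3]))
        assert out.shape == (3,)

    def test_single_binary_two_logits(self, binary_task):
        model = build_model("cnn", binary_task, seed=0)
        out = model(model.prepare(_records(binary_task, n=4)))
        assert out.shape == (4, 2)

    def test_multiclass_logits(self, multiclass_task):
        model = build_model("transformer", multiclass_task, seed=0)
        out = model(model.prepare(_records(multiclass_task, n=6)[:5]))
        assert out.shape == (5, 3)

    @pytest.mark.parametrize("arch", SEQUENCE_ARCHITECTURES)
    def test_residue_logits(self, arch, residue_task):
        model = build_model(arch, residue_task, seed=0)
        recs = generate(GeneratorSpec(task_spec=residue_task, n_samples=2,
                                      length_range=(7, 7), motifs=("WWW",),
                                      seed=0))
        out = model(model.prepare(recs[:1]))
        assert out.shape == (1, 7, 2)

    @pytest.mark.parametrize("arch", GRAPH_ARCHITECTURES + ("fixed_embedding",))
    def test_residue_level_refused(self, arch, residue_task):
        with pytest.raises(IncompatibleArchitecture):
            build_model(arch, residue_task, seed=0)

    def test_forward_sequence_rejects_graph_model(self, regression_task):
        model = build_model("gcn", regression_task, seed=0)
        with pytest.raises(ShapeMismatch):
            forward_sequence(model, None)

    def test_forward_graph_rejects_empty(self, regression_task):
        model = build_model("gcn", regression_task, seed=0)
        with pytest.raises(EmptyGraph):
            forward_graph(model, [])


class TestArchitectureStructure:
    def test_cnn_conv_stages(self, regression_task):
        model = build_model("cnn", regression_task, seed=0)
        convs = model.stack.convs
        assert [c.weight.shape for c in convs] == [
            (4, 21, 32), (8, 32, 64), (12, 64, 96)]
        assert model.head.fc1.weight.shape == (96, 256)

    def test_cnn_gru_two_bidirectional_layers(self, regression_task):
        model = build_model("cnn_gru", regression_task, seed=0)
        assert len(model.grus) == 2
        assert model.grus[0].fwd.hidden == 64
        # bidirectional: layer 2 consumes 2 x 64
        assert model.grus[1].fwd.w.shape[0] == 128

    def test_transformer_two_layers_four_heads_dim64(self, regression_task):
        model = build_model("transformer", regression_task, seed=0)
        assert len(model.blocks) == 2
        assert model.blocks[0].attn.n_heads == 4
        assert model.embed.weight.shape == (22, 64)

    def test_duplicated_batch_rows_identical_eval_outputs(self, binary_task):
        model = build_model("cnn", binary_task, seed=0)
        recs = _records(binary_task, n=4)
        batch = model.prepare([recs[0], recs[1], recs[0]])
        out = model(batch).data
        np.testing.assert_array_equal(out[0], out[2])

    @pytest.mark.parametrize("arch", SEQUENCE_ARCHITECTURES)
    def test_padding_never_influences_real_positions(self, arch,
                                                     regression_task):
        model = build_model(arch, regression_task, seed=0)
        recs = _records(regression_task, n=4, lengths=(6, 6))
        long = _records(regression_task, n=4, seed=5, lengths=(20, 20))
        alone = model(model.prepare([recs[0]])).data
        padded = model(model.prepare([recs[0], long[0]])).data
        np.testing.assert_allclose(alone[0], padded[0], atol=2e-5)


def _permuted(g: MolecularGraph, rng) -> MolecularGraph:
    perm = rng.permutation(g.n_atoms)
    inv = np.argsort(perm)  # old index -> new index is perm[old]
    new_edges, new_orders = [], []
    for (u, v), o in zip(g.edges, g.bond_orders):
        a, b = int(perm[u]), int(perm[v])
        new_edges.append((min(a, b), max(a, b)))
        new_orders.append(o)
    elements = [None] * g.n_atoms
    for old, new in enumerate(perm):
        elements[new] = g.atom_elements[old]
    out = MolecularGraph(atom_elements=elements, edges=new_edges,
                         bond_orders=new_orders)
    out.node_features = g.node_features[inv]
    ef = np.zeros_like(g.edge_features)
    ef[:] = g.edge_features
    out.edge_features = ef
    return out


class TestGraphModels:
    @pytest.mark.parametrize("arch", GRAPH_ARCHITECTURES)
    def test_node_permutation_invariance(self, arch, regression_task):
        model = build_model(arch, regression_task, seed=0)
        rng = np.random.default_rng(4)
        g = sequence_to_peptide_graph("WKAG")
        out1 = forward_graph(model, [g]).data
        out2 = forward_graph(model, [_permuted(g, rng)]).data
        np.testing.assert_allclose(out1, out2, atol=1e-6)

    def test_gcn_layer_matches_dense_closed_form(self):
        # 3-node path graph, hand-set weights, identity-like activation
        g = MolecularGraph(atom_elements=["C", "C", "C"],
                           edges=[(0, 1), (1, 2)],
                           bond_orders=["single", "single"])
        H = np.array([[1.0, 0.5], [0.2, 0.3], [0.7, 0.9]])
        g.node_features = H
        g.edge_features = np.tile([1.0, 0, 0], (2, 1))
        rng = np.random.default_rng(0)
        layer = GCNLayer(2, 2, rng)
        W = np.array([[0.4, -0.2], [0.1, 0.8]])
        layer.weight.data[...] = W
        layer.bias.data[...] = 0.0
        gb = batch_graphs([g])
        from protbench.nn.tensor import Tensor
        out = layer(Tensor(H), gb).data
        # dense oracle: D~^-1/2 (A + I) D~^-1/2 H W
        A = np.array([[0, 1, 0], [1, 0, 1], [0, 1, 0]], dtype=float)
        At = A + np.eye(3)
        Dt = np.diag(At.sum(1) ** -0.5)
        expected = Dt @ At @ Dt @ H @ W
        np.testing.assert_allclose(out, expected, atol=1e-6)

    def test_single_node_graph_degenerates_to_self_loop(self, regression_task):
        g = MolecularGraph(atom_elements=["C"], edges=[], bond_orders=[])
        g.node_features = np.array([[1.0, 0.0, 0.0, 0.0, 0.0]])
        g.edge_features = np.zeros((0, 3))
        model = build_model("gcn", regression_task, seed=0)
        out = forward_graph(model, [g])
        assert out.shape == (1,) and np.isfinite(out.data).all()

    @pytest.mark.parametrize("arch", GRAPH_ARCHITECTURES)
    def test_outputs_finite_at_default_config(self, arch, regression_task):
        model = build_model(arch, regression_task, seed=1)
        graphs = [sequence_to_peptide_graph(s) for s in ("GAW", "KKC", "PYF")]
        out = forward_graph(model, graphs)
        assert np.isfinite(out.data).all()


class TestFixedEmbedding:
    def test_regression_shape_with_mock_provider(self, regression_task):
        provider = hashed_random_provider(dimension=16)
        model = build_model("fixed_embedding", regression_task, seed=0,
                            provider=provider)
        out = model(model.prepare(_records(regression_task, n=5)))
        assert out.shape == (5,)

    def test_provider_vectors_fixed_per_sequence(self):
        provider = hashed_random_provider(dimension=8)
        v1 = provider.lookup("ACDW")
        v2 = provider.lookup("ACDW")
        np.testing.assert_array_equal(v1, v2)

    def test_provider_frozen_during_training(self, regression_task):
        from protbench import TrainConfig, make_split
        from protbench.training import train
        provider = kmer_provider(dimension=32, seed=0)
        recs = _records(regression_task, n=30)
        before = {r.sequence: provider.lookup(r.sequence).copy() for r in recs}
        model = build_model("fixed_embedding", regression_task, seed=0,
                            provider=provider)
        split = make_split(recs, seed=0)
        train(model, split, regression_task,
              TrainConfig(learning_rate=1e-3, max_epochs=2, seed=0))
        for seq, v in before.items():
            np.testing.assert_array_equal(v, provider.lookup(seq))

    def test_pair_head_consumes_interaction_features(self,
                                                     pair_regression_task):
        provider = hashed_random_provider(dimension=8)
        model = build_model("fixed_embedding", pair_regression_task, seed=0,
                            provider=provider)
        # u, v, |u - v|, u * v blocks of 8 each
        assert model.head.fc1.weight.shape[0] == 32

    def test_exact_kmer_provider_counts(self):
        provider = kmer_provider()  # exact 1..2-mer composition
        assert provider.dimension == 420
        v = provider.lookup("WKW")
        assert v.sum() == 3 + 2  # three 1-mers + two 2-mers



class TestConfigs:
    def test_default_table_matches_golden_file(self):
        golden = json.loads((DATA / "default_configs.json").read_text())
        assert default_config_table() == golden

    def test_overrides(self):
        cfg = default_config("cnn", max_epochs=5)
        assert cfg.max_epochs == 5 and cfg.hidden_dim == 256

    def test_unknown_architecture(self):
        with pytest.raises(ValueError):
            default_config("resnet")


def test_save_load_round_trip(tmp_path, binary_task):
    model = build_model("cnn", binary_task, seed=3)
    recs = _records(binary_task, n=3)
    batch = model.prepare(recs)
    out1 = model(batch).data
    path = tmp_path / "model.npz"
    save_model(model, str(path))
    loaded = load_model(str(path))
    out2 = loaded(loaded.prepare(recs)).data
    np.testing.assert_array_equal(out1, out2)
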