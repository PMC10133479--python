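"""Bernoulli-mixture EM, MRF smoothing, partition naming, query mapping."""

import itertools
import math

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from conftest import mixture_means
from srbmine.pangenome import (
    EPS,
    assign_partitions,
    fit_bmm,
    load_matrix,
    log_likelihood,
    map_query_genes,
    smooth_mrf,
)
from srbmine.synthetic import SimulationConfig, generate_pangenome

from _oracles import bmm_grid_oracle, potts_energy, potts_exhaustive


def dm(rows, families=None, genomes=None):
    rows = np.asarray(rows)
    return pd.DataFrame(
        rows,
        index=families or [f"f{i}" for i in range(rows.shape[0])],
        columns=genomes or [f"g{j}" for j in range(rows.shape[1])],
    )


class TestLoadMatrix:
    def test_non_binary_rejected(self):
        with pytest.raises(ValueError, match="0 or 1"):
            load_matrix(dm([[1, 2], [0, 1]]))

    def test_empty_families_rejected(self):
        with pytest.raises(ValueError, match="zero genomes"):
            load_matrix(dm([[0, 0], [1, 1]]))

    def test_duplicate_ids_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            load_matrix(dm([[1, 0], [0, 1]], families=["f", "f"]))


class TestLogLikelihood:
    def test_half_probability_closed_form(self):
        m = dm(np.ones((3, 4), dtype=int))
        from srbmine.pangenome import MixtureModel

        model = MixtureModel(
            pi=np.array([1.0]),
            theta=np.full((1, 4), 0.5),
            genomes=list(m.columns),
        )
        assert log_likelihood(m, model) == pytest.approx(3 * 4 * math.log(0.5))

    def test_duplicated_row_adds_its_contribution(self):
        m = dm([[1, 0, 1], [1, 1, 0]])
        model, _ = fit_bmm(m, K=1, seed=0)
        base = log_likelihood(m, model)
        m2 = dm([[1, 0, 1], [1, 1, 0], [1, 1, 0]])
        row = dm([[1, 1, 0]])
        assert log_likelihood(m2, model) == pytest.approx(
            base + log_likelihood(row, model)
        )

    def test_dimension_mismatch_rejected(self):
        m = dm([[1, 0], [0, 1]])
        model, _ = fit_bmm(m, K=1, seed=0)
        with pytest.raises(ValueError, match="genomes"):
            log_likelihood(dm([[1, 0, 1]]), model)


class TestFitBmm:
    def test_all_ones_k1_degenerate(self):
        model, resp = fit_bmm(dm(np.ones((5, 3), dtype=int)), K=1, seed=0)
        assert np.allclose(model.theta, 1 - EPS)
        assert model.pi == pytest.approx([1.0])
        assert np.allclose(resp.to_numpy(), 1.0)

    def test_k1_theta_equals_column_means(self):
        rows = [[1, 0, 1], [1, 1, 1], [0, 1, 1], [1, 0, 1]]
        model, _ = fit_bmm(dm(rows), K=1, seed=3)
        means = np.clip(np.asarray(rows, dtype=float).mean(axis=0), EPS, 1 - EPS)
        assert np.allclose(model.theta[0], means, atol=1e-9)

    def test_k1_mle_is_a_maximum(self):
        rows = [[1, 0, 1], [1, 1, 1], [0, 1, 1]]
        m = dm(rows)
        model, _ = fit_bmm(m, K=1, seed=0)
        best = log_likelihood(m, model)
        for delta in (0.05, -0.05):
            pert = model
            pert = type(model)(
                pi=model.pi,
                theta=np.clip(model.theta + delta, EPS, 1 - EPS),
                genomes=model.genomes,
            )
            assert log_likelihood(m, pert) <= best + 1e-12

    def test_k_larger_than_families_rejected(self):
        with pytest.raises(ValueError, match="exceeds"):
            fit_bmm(dm([[1, 0], [0, 1]]), K=3)

    def test_matches_exhaustive_grid_search(self):
        # 4 x 2 instance with 3 distinct patterns; theta on a 0.01 grid
        X = np.array([[1, 1], [1, 0], [0, 1], [1, 1]], dtype=np.int8)
        oracle = bmm_grid_oracle(X)
        m = dm(X)
        best_em = max(
            log_likelihood(m, fit_bmm(m, K=2, seed=s, tol=1e-12, max_iter=5000)[0])
            for s in range(3)
        )
        assert best_em == pytest.approx(oracle, abs=1e-3)

    def test_responsibilities_sum_to_one(self, planted_pangenome):
        _, matrix, _, _ = planted_pangenome
        _, resp = fit_bmm(matrix, K=3, seed=1)
        assert np.allclose(resp.sum(axis=1), 1.0, atol=1e-9)

    def test_genome_permutation_equivariance(self):
        cfg = SimulationConfig(seed=31, n_families=120, n_genomes=12)
        matrix, _, _ = generate_pangenome(cfg)
        model, _ = fit_bmm(matrix, K=3, seed=5, tol=1e-12, max_iter=3000)
        perm = list(reversed(matrix.columns))
        model_p, _ = fit_bmm(matrix[perm], K=3, seed=5, tol=1e-12, max_iter=3000)
        # init jitter is not permuted, but on well-separated data both runs
        # converge to the same fixed point, whose theta columns permute
        assert np.allclose(model.theta[:, ::-1], model_p.theta, atol=1e-5)
        assert np.allclose(model.pi, model_p.pi, atol=1e-5)

    @pytest.mark.parametrize("seed", [7, 8, 9])
    def test_planted_recovery(self, seed):
        # three replicates: >= 95% label accuracy, component mean presence
        # probability recovered within 0.05
        cfg = SimulationConfig(seed=seed)
        matrix, graph, truth = generate_pangenome(cfg)
        model, resp = fit_bmm(matrix, K=3, seed=seed)
        labels = smooth_mrf(resp, graph, beta=2.5)
        result = assign_partitions(model, resp, matrix, labels)
        true_lab = pd.Series(truth.family_labels)
        acc = (result.table["partition"].loc[true_lab.index] == true_lab).mean()
        assert acc >= 0.95
        names = model.partition_names()
        fitted = {names[k]: model.theta[k].mean() for k in range(model.K)}
        for label, planted in mixture_means(cfg).items():
            assert abs(fitted[label] - planted) <= 0.05


class TestSmoothMrf:
    def _resp(self, r):
        r = np.asarray(r, dtype=float)
        return pd.DataFrame(r, index=[f"f{i}" for i in range(len(r))], columns=range(r.shape[1]))

    def test_beta_zero_is_argmax(self):
        resp = self._resp([[0.6, 0.3, 0.1], [0.1, 0.8, 0.1], [0.2, 0.2, 0.6]])
        g = nx.path_graph([f"f{i}" for i in range(3)])
        out = smooth_mrf(resp, g, beta=0.0)
        assert list(out) == [0, 1, 2]

    def test_edgeless_graph_unchanged_for_any_beta(self):
        resp = self._resp([[0.6, 0.4], [0.3, 0.7]])
        g = nx.Graph()
        g.add_nodes_from(resp.index)
        for beta in (0.0, 1.0, 10.0):
            assert list(smooth_mrf(resp, g, beta=beta)) == [0, 1]

    def test_weak_middle_flips_to_strong_neighbors(self):
        # 3-node path; middle weakly prefers A(0), both ends strongly B(1)
        resp = self._resp([[0.01, 0.99], [0.55, 0.45], [0.01, 0.99]])
        g = nx.path_graph([f"f{i}" for i in range(3)])
        out = smooth_mrf(resp, g, beta=3.0)
        assert list(out) == [1, 1, 1]
        # matches exhaustive minimization over all 2^3 labelings
        logr = np.log(resp.to_numpy())
        edges = [(0, 1, 3.0), (1, 2, 3.0)]
        assert tuple(out) == potts_exhaustive(logr, edges, 2)

    @pytest.mark.parametrize("trial", range(60))
    def test_matches_exhaustive_on_tiny_instances(self, trial):
        # all <=3-node / 3-component instances reachable by the seeded draw
        rng = np.random.default_rng(1000 + trial)
        n = int(rng.integers(1, 4))
        beta = float(rng.choice([0.0, 0.5, 1.0, 2.5, 5.0]))
        r = rng.dirichlet(np.ones(3), size=n)
        resp = self._resp(r)
        g = nx.Graph()
        g.add_nodes_from(resp.index)
        pairs = list(itertools.combinations(range(n), 2))
        edges = []
        for i, j in pairs:
            if rng.random() < 0.7:
                g.add_edge(f"f{i}", f"f{j}")
                edges.append((i, j, beta))
        out = tuple(smooth_mrf(resp, g, beta=beta))
        logr = np.log(r)
        best = potts_exhaustive(logr, edges, 3)
        assert potts_energy(logr, edges, out) == pytest.approx(
            potts_energy(logr, edges, best), abs=1e-12
        )

    def test_negative_beta_rejected(self):
        resp = self._resp([[0.5, 0.5]])
        with pytest.raises(ValueError):
            smooth_mrf(resp, nx.Graph(), beta=-1.0)


class TestAssignPartitions:
    def test_extreme_rows_get_extreme_partitions(self):
        rows = np.zeros((30, 10), dtype=int)
        rows[:10] = 1                      # persistent block
        rows[10:20, :5] = 1                # intermediate block
        rows[20:, 0] = 1                   # rare block
        m = dm(rows)
        model, resp = fit_bmm(m, K=3, seed=2)
        result = assign_partitions(model, resp, m)
        t = result.table
        assert (t.loc[[f"f{i}" for i in range(10)], "partition"] == "persistent").all()
        assert (t.loc[[f"f{i}" for i in range(20, 30)], "partition"] == "cloud").all()

    def test_extra_components_become_numbered_shells(self):
        cfg = SimulationConfig(seed=12, n_families=200)
        matrix, _, _ = generate_pangenome(cfg)
        model, resp = fit_bmm(matrix, K=4, seed=0)
        names = model.partition_names()
        assert sorted(names) == ["cloud", "persistent", "shell_1", "shell_2"]

    def test_every_family_labelled_once(self, planted_pangenome):
        _, matrix, _, _ = planted_pangenome
        model, resp = fit_bmm(matrix, K=3, seed=4)
        result = assign_partitions(model, resp, matrix)
        assert len(result.table) == len(matrix)
        assert result.table["partition"].isin(["persistent", "shell", "cloud"]).all()


class TestMapQueryGenes:
    def _result(self):
        m = dm([[1, 1, 1], [1, 0, 0]], families=["famA", "famB"])
        model, resp = fit_bmm(m, K=2, seed=0)
        return assign_partitions(model, resp, m)

    def test_empty_query_table(self):
        q = pd.DataFrame(columns=["gene", "family", "pident", "evalue", "bitscore"])
        matched, unmatched = map_query_genes(q, self._result())
        assert matched.empty and unmatched.empty

    def test_join_carries_partition_and_quality_columns(self):
        result = self._result()
        q = pd.DataFrame(
            {"gene": ["dde_0001"], "family": ["famA"], "pident": [98.7],
             "evalue": [1e-50], "bitscore": [321.0]}
        )
        matched, unmatched = map_query_genes(q, result)
        assert unmatched.empty
        assert matched.loc[0, "partition"] == result.table.loc["famA", "partition"]
        assert matched.loc[0, "pident"] == 98.7

    def test_unmatched_reported_separately(self):
        q = pd.DataFrame({"gene": ["g1"], "family": ["nope"]})
        matched, unmatched = map_query_genes(q, self._result())
        assert matched.empty and list(unmatched["gene"]) == ["g1"]
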