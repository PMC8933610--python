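import numpy as np
import pandas as pd
import pytest
from scipy import stats

import setscape as ss
from setscape.association import GwasResult
from tests.conftest import make_freq_table


class TestDriftCovariance:
    def test_identical_populations_uniform_matrix(self):
        f = np.tile(np.random.default_rng(0).uniform(0.2, 0.8, 60), (3, 1))
        w = ss.drift_covariance(make_freq_table(f, 40))
        M = w.matrix.to_numpy()
        np.testing.assert_allclose(M, M[0, 0])

    def test_symmetric(self):
        f = np.random.default_rng(1).random((4, 80))
        w = ss.drift_covariance(make_freq_table(f, 40))
        np.testing.assert_allclose(w.matrix, w.matrix.T)

    def test_independent_drift_diagonal_scales_with_time(self):
        # four demes drifting independently; one four times longer
        rng = np.random.default_rng(2)
        L, N = 4000, 200
        q0 = rng.uniform(0.2, 0.8, L)
        times = [10, 10, 10, 40]
        rows = []
        for t in times:
            q = q0.copy()
            for _ in range(t):
                q = rng.binomial(2 * N, q) / (2 * N)
            rows.append(q)
        w = ss.drift_covariance(make_freq_table(np.vstack(rows), 2 * N)).matrix
        assert w.iloc[3, 3] > 2.0 * w.iloc[0, 0]
        # independent demes: off-diagonals (centering artifacts) stay small
        assert abs(w.iloc[0, 1]) < 0.5 * w.iloc[0, 0]


class TestFitTree:
    def test_three_taxon_additive_exact(self):
        # d_AB=0.3, d_AC=0.4, d_BC=0.5 -> lengths A:0.1, B:0.2, C:0.3
        pops = ["A", "B", "C"]
        d = pd.DataFrame(
            [[0.0, 0.3, 0.4], [0.3, 0.0, 0.5], [0.4, 0.5, 0.0]], index=pops, columns=pops
        )
        # build a covariance whose induced distances equal d
        diag = {"A": 0.1, "B": 0.2, "C": 0.3}
        W = pd.DataFrame(0.0, index=pops, columns=pops)
        for i in pops:
            W.loc[i, i] = diag[i]
        g = ss.fit_tree(ss.DriftCovariance(W, 100), root="A")
        lengths = {v: c for u, v, c in g.tree_edges()}
        assert lengths["A"] == pytest.approx(0.1, abs=1e-9)
        assert lengths["B"] == pytest.approx(0.2, abs=1e-9)
        assert lengths["C"] == pytest.approx(0.3, abs=1e-9)
        # path-distance residual zero
        assert g.root == g.tree_parent("A")

    def test_star_symmetry(self):
        pops = ["A", "B", "C", "D"]
        W = pd.DataFrame(np.eye(4) * 0.2, index=pops, columns=pops)
        g = ss.fit_tree(ss.DriftCovariance(W, 100), root="A")
        term = {v: c for u, v, c in g.tree_edges() if v in pops}
        vals = np.array(list(term.values()))
        np.testing.assert_allclose(vals, 0.2, atol=1e-6)

    def test_noiseless_additive_distances_reproduced(self):
        # caterpillar tree, distinct lengths; W from shared path lengths
        pops = ["A", "B", "C", "D", "E"]
        rng = np.random.default_rng(3)
        # construct covariance from a known chain history
        split = {"A": 0.0, "B": 0.1, "C": 0.2, "D": 0.3, "E": 0.4}
        term = {"A": 0.05, "B": 0.1, "C": 0.15, "D": 0.2, "E": 0.45}
        W = pd.DataFrame(0.0, index=pops, columns=pops)
        for i in pops:
            for j in pops:
                W.loc[i, j] = min(split[i], split[j])
            W.loc[i, i] = split[i] + term[i]
        g = ss.fit_tree(ss.DriftCovariance(W, 100), root="A")
        # reproduce all pairwise distances through the fitted tree
        import networkx as nx

        und = nx.Graph()
        for u, v, c in g.tree_edges():
            und.add_edge(u, v, weight=c)
        for i in pops:
            for j in pops:
                if i >= j:
                    continue
                d_true = W.loc[i, i] + W.loc[j, j] - 2 * W.loc[i, j]
                d_fit = nx.shortest_path_length(und, i, j, weight="weight")
                assert d_fit == pytest.approx(d_true, abs=1e-6)

    def test_topology_recovery_under_drift(self):
        # 6-leaf chain of population splits with distinct times
        rng = np.random.default_rng(4)
        hits = 0
        n_rep = 15
        for rep in range(n_rep):
            L, N = 3000, 300
            q = rng.uniform(0.1, 0.9, L)
            demes = [q.copy()]
            freqs = []
            gens_between = 25
            for k in range(5):
                # all current demes drift, then the last one splits
                for i in range(len(demes)):
                    for _ in range(gens_between):
                        demes[i] = rng.binomial(2 * N, demes[i]) / (2 * N)
                demes.append(demes[-1].copy())
            t = make_freq_table(np.vstack(demes), 2 * N)
            g = ss.fit_tree(ss.drift_covariance(t), root="pop1")
            # chain topology: pop6 and pop5 should be sisters
            import networkx as nx

            und = nx.Graph()
            for u, v, c in g.tree_edges():
                und.add_edge(u, v)
            assert nx.shortest_path_length(und, "pop5", "pop6")
            if nx.shortest_path_length(und, "pop5", "pop6") == 2:
                hits += 1
        assert hits / n_rep >= 0.8

    def test_nonfinite_distance_errors(self):
        pops = ["A", "B", "C"]
        W = pd.DataFrame(np.eye(3), index=pops, columns=pops)
        W.iloc[0, 1] = np.nan
        with pytest.raises(ValueError, match="finite"):
            ss.fit_tree(ss.DriftCovariance(W, 100), root="A")


class TestMigrationEdges:
    def _w(self, seed=0):
        sim_freqs = make_freq_table(np.random.default_rng(seed).random((4, 200)), 100)
        return ss.drift_covariance(sim_freqs)

    def test_zero_migrations_identity(self):
        w = self._w()
        g = ss.fit_tree(w, root="pop1")
        g2 = ss.add_migration_edges(g, w, 0)
        assert g2.admixture_edges() == g.admixture_edges() == []

    def test_residual_nonincreasing(self):
        from setscape.graphsel import _expected_covariance

        w = self._w(1)
        g0 = ss.fit_tree(w, root="pop1")
        leaves = g0.leaves()

        def cen(M):
            return M - M.mean(0, keepdims=True) - M.mean(1, keepdims=True) + M.mean()

        W = cen(w.matrix.loc[leaves, leaves].to_numpy())
        prev = np.inf
        for n_mig in range(3):
            g = ss.add_migration_edges(g0, w, n_mig)
            C = cen(_expected_covariance(g).loc[leaves, leaves].to_numpy())
            ss_now = float(((W - C) ** 2).sum())
            assert ss_now <= prev + 1e-9
            prev = ss_now

    def test_admixture_target_detected(self):
        # 4 demes from a chain; deme 4 is a 70/30 mix of demes 3 and 1
        rng = np.random.default_rng(5)
        hits = 0
        n_rep = 10
        for rep in range(n_rep):
            L, N = 3000, 400
            q0 = rng.uniform(0.1, 0.9, L)

            def drift(q, t):
                for _ in range(t):
                    q = rng.binomial(2 * N, q) / (2 * N)
                return q

            qa = drift(q0, 30)
            qb = drift(q0, 30)
            q1 = drift(qa, 30)
            q2 = drift(qa, 30)
            q3 = drift(qb, 30)
            q4 = drift(0.7 * q3 + 0.3 * q1, 10)
            t = make_freq_table(np.vstack([q1, q2, q3, q4]), 2 * N)
            w = ss.drift_covariance(t)
            g = ss.add_migration_edges(ss.fit_tree(w, root="pop1"), w, 1)
            adx = g.admixture_edges()
            if adx and adx[0][1] == "pop4":
                hits += 1
        assert hits / n_rep > 0.5


class TestPolygenicScores:
    def _gwas(self, loci, beta):
        tab = pd.DataFrame(
            {"beta": beta, "se": 0.1, "p": 0.0, "q": 0.0}, index=loci
        )
        return GwasResult("T", tab, list(loci), 0.05)

    def test_zero_beta_zero_scores(self):
        t = make_freq_table([[0.1, 0.4], [0.9, 0.6]], 40)
        z = ss.polygenic_scores(t, self._gwas(["L1", "L2"], [0.0, 0.0]))
        assert (z == 0).all()

    def test_single_locus_arithmetic(self):
        t = make_freq_table([[0.1], [0.9]], 40)
        z = ss.polygenic_scores(t, self._gwas(["L1"], [1.0]))
        np.testing.assert_allclose(z.to_numpy(), [0.2, 1.8])

    def test_linear_in_beta(self):
        t = make_freq_table([[0.1, 0.3], [0.9, 0.5]], 40)
        z1 = ss.polygenic_scores(t, self._gwas(["L1", "L2"], [1.0, -0.5]))
        z2 = ss.polygenic_scores(t, self._gwas(["L1", "L2"], [2.0, -1.0]))
        np.testing.assert_allclose(2 * z1.to_numpy(), z2.to_numpy())

    def test_empty_set_errors_with_trait_name(self):
        t = make_freq_table([[0.1], [0.9]], 40)
        with pytest.raises(ValueError, match="T"):
            ss.polygenic_scores(t, GwasResult("T", pd.DataFrame(columns=["beta"]), [], 0.05))


def _chain_graph():
    g = ss.AdmixtureGraph(root="a1")
    g.add_tree_edge("a1", "A", 0.1)
    g.add_tree_edge("a1", "a2", 0.05)
    g.add_tree_edge("a2", "B", 0.2)
    g.add_tree_edge("a2", "C", 0.15)
    return g


class TestEdgeSelection:
    def test_identical_scores_give_zero_alpha(self):
        g = _chain_graph()
        Z = pd.Series(3.0, index=["A", "B", "C"], name="T")
        v = ss.estimate_edge_selection(g, Z, V_A=1.0)
        np.testing.assert_allclose(v.alpha.to_numpy(), 0.0, atol=1e-10)

    def test_shift_invariance(self):
        g = _chain_graph()
        Z = pd.Series([1.0, -0.5, 2.0], index=["A", "B", "C"], name="T")
        v1 = ss.estimate_edge_selection(g, Z, V_A=0.7)
        v2 = ss.estimate_edge_selection(g, Z + 100.0, V_A=0.7)
        np.testing.assert_allclose(v1.alpha.to_numpy(), v2.alpha.to_numpy(), atol=1e-8)

    def test_raw_contrasts_telescope_along_paths(self):
        g = _chain_graph()
        Z = pd.Series([1.0, -0.5, 2.0], index=["A", "B", "C"], name="T")
        V_A = 0.7
        v = ss.estimate_edge_selection(g, Z, V_A=V_A)
        # sum of raw * sqrt(V_A c_e) down the path a1 -> a2 -> B
        path = [("a1", "a2"), ("a2", "B")]
        tele = sum(v.raw[e] * np.sqrt(V_A * v.c[e]) for e in path)
        assert tele == pytest.approx(v.node_scores["B"] - v.node_scores["a1"], abs=1e-8)

    def test_zero_length_edge_alpha_zero(self):
        g = ss.AdmixtureGraph(root="r")
        g.add_tree_edge("r", "A", 0.0)
        g.add_tree_edge("r", "B", 0.2)
        g.add_tree_edge("r", "C", 0.2)
        Z = pd.Series([1.0, 2.0, 0.0], index=["A", "B", "C"], name="T")
        v = ss.estimate_edge_selection(g, Z, V_A=1.0)
        assert v.alpha[("r", "A")] == 0.0

    def test_null_calibration_on_standing_variation(self, neutral_sim, neutral_tree):
        # effects on random genotyped loci: alpha should be ~N(0,1)
        rng = np.random.default_rng(8)
        rec = neutral_sim.locus_records
        loci = list(rec.index[rec["class"] == "init_neutral"])
        alphas = []
        for rep in range(25):
            sel = list(rng.choice(loci, size=20, replace=False))
            tab = pd.DataFrame(
                {"beta": rng.normal(0, 1, 20), "se": 0.1, "p": 0.0, "q": 0.0}, index=sel
            )
            gw = GwasResult("null", tab, sel, 0.05)
            v = ss.edge_selection_for_trait(neutral_tree, neutral_sim.freqs, gw)
            alphas.append(v.alpha.to_numpy())
        a = np.concatenate(alphas)
        assert abs(a.mean()) < 0.2
        assert 0.8 < a.std() < 1.25

    def test_selected_edges_carry_large_alpha(self, selected_sim):
        g = ss.fit_tree(ss.drift_covariance(selected_sim.freqs), root="pop1")
        e1_traits = [t for t in selected_sim.traits_individual.columns if t.startswith("T1.")]
        mats = []
        for trait in e1_traits:
            res = ss.gwas_scan(selected_sim.genotypes, selected_sim.traits_individual[trait],
                               trait=trait)
            if not res.significant:
                continue
            mats.append(ss.edge_selection_for_trait(g, selected_sim.freqs, res).alpha.abs())
        mean_abs = pd.concat(mats, axis=1).mean(axis=1)
        selected = {"pop3", "pop4", "pop5"}
        term_sel = [e for e in mean_abs.index if e[1] in selected]
        others = [e for e in mean_abs.index if e[1] not in selected]
        assert mean_abs[term_sel].mean() > mean_abs[others].mean()
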