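"""Paired permutation comparison, difference network, cross-time rho."""

import numpy as np
import pandas as pd
import pytest

from qolnet.cohort import CohortTable, ScaleDefinition
from qolnet.comparison import (
    difference_network,
    edge_weight_correlation,
    nct_paired,
)
from qolnet.estimator import NetworkEstimator
from qolnet.glasso import GGMNetwork
from qolnet.simulate import generate_cohort, make_precision_spec

EST = NetworkEstimator(n_lambda=30)


def make_net(W, names=None):
    W = np.asarray(W, dtype=float)
    names = names or [f"V{i}" for i in range(W.shape[0])]
    return GGMNetwork(
        node_names=names, weights=W, precision=np.eye(W.shape[0]),
        lambda_selected=0.1, gamma=0.5, n=100,
    )


def paired_table(X1, X2, names):
    rows, idx = [], []
    for i in range(X1.shape[0]):
        rows.append(X1[i]); idx.append((f"S{i:04d}", "M0"))
        rows.append(X2[i]); idx.append((f"S{i:04d}", "M12"))
    data = pd.DataFrame(
        np.asarray(rows),
        index=pd.MultiIndex.from_tuples(idx, names=["subject_id", "timepoint"]),
        columns=names,
    )
    defs = [ScaleDefinition(n, "continuous", (-1e9, 1e9)) for n in names]
    return CohortTable(data, defs, timepoint_order=["M0", "M12"])


class TestDifferenceNetwork:
    def test_identical_networks_give_zero(self):
        W = np.array([[0, 0.3], [0.3, 0]])
        d = difference_network(make_net(W), make_net(W))
        assert np.all(d.values == 0)

    def test_antisymmetric_under_swap(self):
        rng = np.random.default_rng(0)
        A = rng.uniform(-0.4, 0.4, (4, 4)); A = (A + A.T) / 2; np.fill_diagonal(A, 0)
        B = rng.uniform(-0.4, 0.4, (4, 4)); B = (B + B.T) / 2; np.fill_diagonal(B, 0)
        d1 = difference_network(make_net(A), make_net(B))
        d2 = difference_network(make_net(B), make_net(A))
        np.testing.assert_allclose(d1.values, -d2.values)

    def test_published_edge_difference(self):
        """|0.301| - |0.241| = 0.060 for the pf-fatigue edge."""
        names = ["physical_functioning", "fatigue"]
        d = difference_network(
            make_net([[0, 0.301], [0.301, 0]], names),
            make_net([[0, 0.241], [0.241, 0]], names),
        )
        assert d.values[0, 1] == pytest.approx(0.060, abs=1e-12)
        assert d.edge_list(threshold=0.04).iloc[0]["change"] == "decrease"

    def test_node_mismatch_raises(self):
        with pytest.raises(ValueError):
            difference_network(make_net(np.zeros((2, 2))),
                               make_net(np.zeros((2, 2)), names=["a", "b"]))

    def test_display_threshold_only_affects_export(self):
        W1 = np.array([[0, 0.30, 0.02], [0.30, 0, 0], [0.02, 0, 0]])
        d = difference_network(make_net(W1), make_net(np.zeros((3, 3))),
                               display_threshold=0.04)
        assert len(d.edge_list()) == 1          # 0.30 survives, 0.02 filtered
        assert len(d.edge_list(threshold=0.0)) == 2


class TestEdgeWeightCorrelation:
    def test_identical_networks_rho_one(self):
        rng = np.random.default_rng(1)
        W = rng.uniform(-0.4, 0.4, (5, 5)); W = (W + W.T) / 2; np.fill_diagonal(W, 0)
        rho, p = edge_weight_correlation(make_net(W), make_net(W))
        assert rho == pytest.approx(1.0)

    def test_rank_reversal_gives_minus_one(self):
        W = np.zeros((4, 4))
        iu = np.triu_indices(4, 1)
        W[iu] = np.linspace(0.1, 0.4, 6)
        W = W + W.T
        W2 = np.zeros((4, 4))
        W2[iu] = np.linspace(0.4, 0.1, 6)
        W2 = W2 + W2.T
        rho, _ = edge_weight_correlation(make_net(W), make_net(W2))
        assert rho == pytest.approx(-1.0)

    def test_constant_vector_raises(self):
        with pytest.raises(ValueError):
            edge_weight_correlation(make_net(np.zeros((3, 3))),
                                    make_net(np.zeros((3, 3))))

    def test_same_generator_networks_strongly_related(self, continuous_defs_15):
        spec = make_precision_spec(15, 0.15, seed=5)
        tab = generate_cohort(spec, continuous_defs_15, n=487,
                              subject_corr=0.5, seed=20)
        net0 = EST.fit(tab.scores("M0"))
        net1 = EST.fit(tab.scores("M12"))
        rho, _ = edge_weight_correlation(net0, net1)
        assert rho > 0.5


class TestNctPaired:
    def test_identical_timepoints_give_null_statistics(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(80, 5))
        tab = paired_table(X, X.copy(), [f"s{i}" for i in range(5)])
        res = nct_paired(tab, estimator=EST, iterations=100, seed=0)
        assert res.m_structure == 0.0
        assert res.global_strength_diff == 0.0
        assert res.p_structure == 1.0
        assert res.p_global_strength == 1.0
        assert (res.strength_p == 1.0).all()

    def test_observed_m_is_max_edge_difference(self):
        rng = np.random.default_rng(3)
        X1 = rng.normal(size=(100, 4))
        X2 = X1 + rng.normal(0, 0.5, size=(100, 4))
        tab = paired_table(X1, X2, [f"s{i}" for i in range(4)])
        res = nct_paired(tab, estimator=EST, iterations=100, seed=1)
        iu = np.triu_indices(4, 1)
        assert res.m_structure == pytest.approx(
            res.edge_diff.to_numpy()[iu].max()
        )

    def test_subject_at_single_timepoint_raises(self):
        rng = np.random.default_rng(4)
        X = rng.normal(size=(30, 3))
        tab = paired_table(X, X, ["a", "b", "c"])
        broken = CohortTable(
            tab.data.drop(index=("S0000", "M12")),
            list(tab.scale_defs.values()),
            timepoint_order=["M0", "M12"],
        )
        with pytest.raises(ValueError, match="one timepoint"):
            nct_paired(broken, estimator=EST, iterations=100)

    def test_low_iterations_warn(self):
        rng = np.random.default_rng(5)
        X = rng.normal(size=(40, 3))
        tab = paired_table(X, X, ["a", "b", "c"])
        with pytest.warns(UserWarning, match="iterations"):
            nct_paired(tab, estimator=EST, iterations=50, seed=0)

    def test_power_against_a_removed_edge(self, continuous_defs_15):
        """One strong edge zeroed at follow-up is detected (uncorrected)."""
        hits = 0
        reps = 5
        for rep in range(reps):
            spec1 = make_precision_spec(15, 0.1, seed=30 + rep,
                                        weight_range=(0.4, 0.45))
            iu = np.triu_indices(15, 1)
            strongest = np.unravel_index(
                np.argmax(np.abs(np.triu(spec1.true_pcor, 1))), (15, 15)
            )
            P2 = spec1.precision.copy()
            P2[strongest] = P2[strongest[::-1]] = 0.0
            from qolnet.simulate import PrecisionSpec
            spec2 = PrecisionSpec(spec1.node_names, P2)
            t1 = generate_cohort(spec1, continuous_defs_15, n=487, seed=40 + rep)
            t2 = generate_cohort(spec2, continuous_defs_15, n=487, seed=50 + rep)
            X1 = t1.scores("M0").to_numpy()
            X2 = t2.scores("M0").to_numpy()
            tab = paired_table(X1, X2, [d.name for d in continuous_defs_15])
            res = nct_paired(tab, estimator=EST, iterations=200, seed=60 + rep)
            i, j = strongest
            if res.edge_p.iloc[i, j] < 0.05:
                hits += 1
        assert hits >= 3

    def test_relabeling_invariance(self):
        """Swapping the timepoint labels leaves two-sided p-values unchanged."""
        rng = np.random.default_rng(6)
        X1 = rng.normal(size=(60, 4))
        X2 = X1 + rng.normal(0, 0.4, size=(60, 4))
        names = [f"s{i}" for i in range(4)]
        res_a = nct_paired(paired_table(X1, X2, names), estimator=EST,
                           iterations=150, seed=9)
        res_b = nct_paired(paired_table(X2, X1, names), estimator=EST,
                           iterations=150, seed=9)
        assert res_a.m_structure == pytest.approx(res_b.m_structure)
        assert res_a.global_strength_diff == pytest.approx(
            res_b.global_strength_diff
        )
        assert res_a.p_structure == pytest.approx(res_b.p_structure)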