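"""ΔK statistic, Q-replicate alignment, genotypic-cluster rules, parsers."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from palmdelim import (
    GroupingMap,
    LnPTable,
    QReplicateSet,
    align_q_replicates,
    evanno_delta_k,
    gsc_report,
    parse_structure_results,
    read_lnp_tsv,
    read_q_tsv,
)


class TestEvannoDeltaK:
    @pytest.mark.parametrize("pairing", ["by-replicate", "by-mean"])
    def test_worked_replicate_example(self, evanno_example, pairing):
        res = evanno_delta_k(evanno_example, pairing)
        assert res.delta_k[2] == pytest.approx(19.0)
        assert res.delta_k[3] == pytest.approx(1.0)
        assert res.best_k == 2
        assert np.isnan(res.delta_k[1]) and np.isnan(res.delta_k[4])

    def test_linear_means_give_zero_interior(self):
        table = LnPTable({k: [-100.0 * k + d for d in (-1, 0, 1)] for k in range(1, 6)})
        res = evanno_delta_k(table, "by-mean")
        for k in (2, 3, 4):
            assert res.delta_k[k] == pytest.approx(0.0)

    def test_single_replicates_all_undefined_error(self):
        table = LnPTable({1: [-100.0], 2: [-90.0], 3: [-85.0]})
        with pytest.raises(ValueError):
            evanno_delta_k(table)

    def test_zero_sd_flagged_not_fatal(self, evanno_example):
        vals = dict(evanno_example.values)
        vals[3] = [-790.0, -790.0, -790.0]  # sd = 0 at K=3 only
        res = evanno_delta_k(LnPTable(vals), "by-mean")
        assert np.isnan(res.delta_k[3])
        assert res.best_k == 2

    def test_needs_three_consecutive_k(self):
        with pytest.raises(ValueError):
            evanno_delta_k(LnPTable({1: [-10, -11], 2: [-9, -8]}))

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(
        a=st.floats(0.1, 50.0),
        b=st.floats(-1000.0, 1000.0),
    )
    def test_affine_invariance(self, a, b):
        """ΔK is unchanged by L -> aL + b with a > 0."""
        table = LnPTable(
            {
                1: [-1010, -1000, -990],
                2: [-810, -800, -790],
                3: [-795, -790, -785],
                4: [-790, -785, -780],
            }
        )
        base = evanno_delta_k(table)
        scaled = LnPTable(
            {k: [a * v + b for v in vs] for k, vs in table.values.items()}
        )
        res = evanno_delta_k(scaled)
        for k in (2, 3):
            assert res.delta_k[k] == pytest.approx(base.delta_k[k], rel=1e-9)
        assert res.best_k == base.best_k


BASE_Q = np.array(
    [
        [0.90, 0.05, 0.05],
        [0.10, 0.80, 0.10],
        [0.02, 0.08, 0.90],
        [0.85, 0.10, 0.05],
        [0.05, 0.95, 0.00],
    ]
)
INDS = [f"i{j}" for j in range(5)]


class TestAlignQReplicates:
    def test_identical_replicates_no_op(self):
        reps = QReplicateSet(INDS, [BASE_Q.copy(), BASE_Q.copy()])
        res = align_q_replicates(reps, permutations=5, seed=0)
        assert all(p == (0, 1, 2) for p in res.permutations)
        assert np.allclose(res.mean_q, BASE_Q)
        assert res.similarity == pytest.approx(1.0)

    def test_recovers_any_planted_permutation_exhaustively(self):
        """All K! label shuffles of a replicate are inverted exactly (K<=4)."""
        rng = np.random.default_rng(0)
        raw = rng.dirichlet(np.ones(4) * 0.5, size=8)
        for perm in itertools.permutations(range(4)):
            reps = QReplicateSet(list("abcdefgh"), [raw, raw[:, list(perm)]])
            res = align_q_replicates(reps, permutations=3, seed=1)
            assert np.allclose(res.mean_q, raw)
            assert res.similarity == pytest.approx(1.0)

    def test_noisy_permuted_replicates_average_close_to_truth(self):
        # alignment is defined up to one global relabelling, so compare the
        # mean to the truth in its best-matching label frame
        rng = np.random.default_rng(42)
        truth = np.array([[0.9, 0.05, 0.05], [0.05, 0.9, 0.05], [0.05, 0.05, 0.9]])
        truth = np.vstack([truth] * 4)
        reps = []
        for _ in range(8):
            noise = rng.uniform(-0.01, 0.01, size=truth.shape)
            noisy = np.clip(truth + noise, 0, None)
            noisy /= noisy.sum(axis=1, keepdims=True)
            perm = rng.permutation(3)
            reps.append(noisy[:, perm])
        res = align_q_replicates(
            QReplicateSet([f"x{j}" for j in range(12)], reps),
            permutations=20,
            seed=3,
        )
        err = min(
            np.max(np.abs(res.mean_q[:, list(p)] - truth))
            for p in itertools.permutations(range(3))
        )
        assert err <= 0.02

    def test_mean_rows_sum_to_one_and_realignment_is_noop(self):
        rng = np.random.default_rng(7)
        reps = QReplicateSet(
            INDS, [rng.dirichlet(np.ones(3), size=5) for _ in range(4)]
        )
        res = align_q_replicates(reps, permutations=10, seed=2)
        assert np.allclose(res.mean_q.sum(axis=1), 1.0)
        again = align_q_replicates(res.aligned, permutations=10, seed=2)
        assert all(p == (0, 1, 2) for p in again.permutations)
        assert np.allclose(again.mean_q, res.mean_q)

    def test_global_relabelling_invariance(self):
        """A common permutation of all replicates permutes the mean likewise."""
        rng = np.random.default_rng(8)
        reps = [rng.dirichlet(np.ones(3) * 0.7, size=5) for _ in range(3)]
        res = align_q_replicates(QReplicateSet(INDS, reps), permutations=5, seed=4)
        g = [2, 0, 1]
        res_g = align_q_replicates(
            QReplicateSet(INDS, [r[:, g] for r in reps]), permutations=5, seed=4
        )
        assert np.allclose(res_g.mean_q, res.mean_q[:, g])

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            QReplicateSet(INDS, [BASE_Q, BASE_Q[:, :2]])

    def test_bad_row_sums_rejected(self):
        bad = BASE_Q.copy()
        bad[0, 0] += 0.2
        with pytest.raises(ValueError):
            QReplicateSet(INDS, [bad])


class TestGSCReport:
    grouping = GroupingMap(
        {"a1": "pa", "a2": "pa", "b1": "pb", "b2": "pb"},
        {"pa": "spA", "pb": "spB"},
    )

    def test_crisp_species_necessary_and_exclusive(self):
        q = np.array([[1.0, 0.0], [1.0, 0.0], [0.0, 1.0], [0.0, 1.0]])
        recs = {
            r.species: r
            for r in gsc_report(q, ["a1", "a2", "b1", "b2"], self.grouping)
        }
        assert recs["spA"].necessary and recs["spA"].exclusive
        assert recs["spA"].satisfied
        assert recs["spA"].modal_cluster == 1
        assert recs["spB"].modal_cluster == 2

    def test_shared_cluster_necessary_but_not_exclusive(self):
        q = np.array([[0.9, 0.1], [0.9, 0.1], [0.9, 0.1], [0.9, 0.1]])
        recs = {
            r.species: r
            for r in gsc_report(q, ["a1", "a2", "b1", "b2"], self.grouping)
        }
        assert recs["spA"].necessary and recs["spB"].necessary
        assert not recs["spA"].exclusive and not recs["spB"].exclusive
        assert not recs["spA"].satisfied

    def test_render_matches_table_style(self):
        q = np.zeros((4, 12))
        q[:2, 11] = 0.91
        q[:2, 0] = 0.09
        q[2:, 0] = 1.0
        recs = gsc_report(q, ["a1", "a2", "b1", "b2"], self.grouping)
        rec = {r.species: r for r in recs}["spA"]
        assert rec.render() == "12; 0.91"
        assert rec.necessary

    def test_intermediate_count_and_thresholds(self):
        q = np.array([[0.7, 0.3], [0.45, 0.55], [0.85, 0.15], [0.0, 1.0]])
        recs = {
            r.species: r
            for r in gsc_report(q, ["a1", "a2", "b1", "b2"], self.grouping)
        }
        # a1 max 0.7 and b1 max 0.85... intermediates are (0.5, 0.8) strictly
        assert recs["spA"].n_intermediate == 2  # 0.7 and 0.55
        assert recs["spB"].n_intermediate == 0

    def test_unsampled_species_not_assessed(self):
        g = GroupingMap(
            {"a1": "pa", "a2": "pa"}, {"pa": "spA", "pz": "ghost"}
        )
        q = np.array([[1.0, 0.0], [1.0, 0.0]])
        recs = {r.species: r for r in gsc_report(q, ["a1", "a2"], g)}
        assert not recs["ghost"].assessed
        assert recs["ghost"].satisfied is None
        assert recs["ghost"].render() == "-"


STRUCTURE_TEXT = """
Estimated Ln Prob of Data   = -2802.0
Mean value of ln likelihood = -2700.1

Inferred ancestry of individuals:
        Label (%Miss) Pop:  Inferred clusters
  1 ind_a    (0)    1 :  0.912 0.088
  2 ind_b    (0)    1 :  0.100 0.900

Estimated Allele Frequencies in each cluster
"""


class TestParsers:
    def test_structure_results_block(self):
        inds, q, lnp = parse_structure_results(STRUCTURE_TEXT)
        assert inds == ["ind_a", "ind_b"]
        assert q.shape == (2, 2)
        assert q[0, 0] == pytest.approx(0.912)
        assert lnp == pytest.approx(-2802.0)

    def test_missing_block_raises(self):
        with pytest.raises(ValueError):
            parse_structure_results("no ancestry here")

    def test_lnp_and_q_tsv_round(self, tmp_path):
        lnp_path = tmp_path / "lnp.tsv"
        lnp_path.write_text(
            "K\treplicate\tlnp\n1\t1\t-10\n1\t2\t-11\n2\t1\t-8\n2\t2\t-7\n"
        )
        table = read_lnp_tsv(str(lnp_path))
        assert table.values[2] == [-8.0, -7.0]
        q_path = tmp_path / "q.tsv"
        q_path.write_text(
            "replicate\tindividual\tq1\tq2\n"
            "1\ta\t0.9\t0.1\n1\tb\t0.2\t0.8\n"
            "2\ta\t0.8\t0.2\n2\tb\t0.1\t0.9\n"
        )
        reps = read_q_tsv(str(q_path))
        assert reps.k == 2 and len(reps) == 2
        assert reps.individuals == ["a", "b"]
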