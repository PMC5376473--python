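"""Bipartition enumeration, TE tables and the three indices."""

from itertools import chain, combinations

import numpy as np
import pytest

from doaflow import (
    Bipartition,
    TETable,
    VARModel,
    enumerate_bipartitions,
    index_tmax,
    index_tmean,
    index_tmin,
    lagged_stationary_cov,
    n_bipartitions,
    te_table,
    te_table_from_cov,
)
from doaflow.var_sim import random_stable_var, simulate_var


def _brute_force_pairs(names, covering):
    """Independent enumeration over all subset pairs."""
    subsets = [
        frozenset(c)
        for c in chain.from_iterable(
            combinations(names, k) for k in range(1, len(names) + 1)
        )
    ]
    count = 0
    for s in subsets:
        for t in subsets:
            if s & t:
                continue
            if covering and s | t != frozenset(names):
                continue
            count += 1
    return count


class TestEnumeration:
    def test_three_channels_give_twelve(self):
        assert len(enumerate_bipartitions(["x", "y", "z"])) == 12

    def test_two_channels_covering(self):
        bps = enumerate_bipartitions(["a", "b"], mode="covering")
        assert {(bp.source, bp.target) for bp in bps} == {
            (("a",), ("b",)),
            (("b",), ("a",)),
        }

    @pytest.mark.parametrize("n", range(2, 9))
    @pytest.mark.parametrize("mode", ["disjoint_pairs", "covering"])
    def test_counts_match_closed_form_and_brute_force(self, n, mode):
        names = [f"c{i}" for i in range(n)]
        bps = enumerate_bipartitions(names, mode)
        assert len(bps) == n_bipartitions(n, mode)
        assert len(bps) == _brute_force_pairs(names, mode == "covering")
        assert len(set(bps)) == len(bps)  # no duplicates

    def test_seven_channel_counts(self):
        assert n_bipartitions(7, "disjoint_pairs") == 1932
        assert n_bipartitions(7, "covering") == 126

    def test_order_is_deterministic_and_canonical(self):
        bps = enumerate_bipartitions(["x", "y", "z"])
        assert bps == enumerate_bipartitions(["x", "y", "z"])
        sizes = [len(bp.source) for bp in bps]
        assert sizes == sorted(sizes)  # sources in size order

    def test_fewer_than_two_channels_raises(self):
        with pytest.raises(ValueError):
            enumerate_bipartitions(["solo"])

    def test_invalid_bipartition_construction(self):
        with pytest.raises(ValueError):
            Bipartition(("a",), ("a",))
        with pytest.raises(ValueError):
            Bipartition((), ("a",))


@pytest.fixture(scope="module")
def fig_style_model():
    """Y and Z drive X; X drives nothing: dominant flow is {Y,Z} -> {X}."""
    F = np.array(
        [
            [0.5, 0.4, 0.4],  # X <- Y, Z
            [0.0, 0.5, 0.3],  # Y <- Z
            [0.0, 0.0, 0.5],
        ]
    )
    return VARModel(F, labels=("X", "Y", "Z"))


class TestTeTable:
    def test_dominant_flow_found_on_analytic_covariances(self, fig_style_model):
        cov2n = lagged_stationary_cov(fig_style_model, tau=1)
        table = te_table_from_cov(cov2n, ["X", "Y", "Z"], tau=1)
        value, bp = index_tmax(table)
        assert set(bp.source) == {"Y", "Z"}
        assert bp.target == ("X",)
        # T_max equals the independently computed TE of that bipartition
        from doaflow import analytic_te

        assert value == pytest.approx(
            analytic_te(fig_style_model, ["X"], ["Y", "Z"], tau=1), abs=1e-12
        )

    def test_independent_noise_gives_near_zero_table(self, rng):
        from doaflow import EEGRecording

        rec = EEGRecording(["a", "b", "c"], 256.0, rng.standard_normal((60_000, 3)))
        table = te_table(rec, tau=1)
        assert len(table) == 12
        assert np.max(table.values) < 2e-4

    def test_reproducible_bit_identically(self, noise_recording):
        t1 = te_table(noise_recording, tau=2)
        t2 = te_table(noise_recording, tau=2)
        np.testing.assert_array_equal(t1.values, t2.values)

    def test_label_permutation_invariance(self, fig_style_model):
        cov2n = lagged_stationary_cov(fig_style_model, tau=1)
        table = te_table_from_cov(cov2n, ["X", "Y", "Z"], tau=1)
        perm = [2, 1, 0]
        sel = np.array(perm + [p + 3 for p in perm])
        table_p = te_table_from_cov(cov2n[np.ix_(sel, sel)], ["Z", "Y", "X"], tau=1)
        for bp, v in zip(table.bipartitions, table.values):
            assert table_p[bp] == pytest.approx(v, abs=1e-12)

    def test_csv_serialization(self, noise_recording, tmp_path):
        table = te_table(noise_recording, tau=2)
        path = table.to_csv(tmp_path / "table.csv")
        lines = path.read_text().strip().split("\n")
        assert lines[0] == "window_start_s,source,target,te_nats"
        assert len(lines) == len(table) + 1


def _toy_table(values):
    bps = enumerate_bipartitions(["a", "b", "c"])[: len(values)]
    return TETable(None, bps, np.array(values))


class TestIndices:
    def test_tmax_picks_largest(self):
        value, bp = index_tmax(_toy_table([0.1, 0.3, 0.2]))
        assert value == 0.3 and bp == _toy_table([0, 0, 0]).bipartitions[1]

    def test_single_entry_table(self):
        table = TETable(None, [Bipartition(("a",), ("b",))], np.array([0.7]))
        assert index_tmax(table) == (0.7, table.bipartitions[0])
        assert index_tmin(table) == (0.7, table.bipartitions[0])
        assert index_tmean(table) == 0.7

    def test_tmin_rules(self):
        bps = [Bipartition(("c1",), ("c2",)), Bipartition(("c2",), ("c1",))]
        table = TETable(None, bps, np.array([0.4, 0.1]))
        assert index_tmin(table, rule="min")[0] == pytest.approx(0.1)
        assert index_tmin(table, rule="maxmin")[0] == pytest.approx(0.1)

    def test_maxmin_selects_strongest_weak_direction(self):
        bps = [
            Bipartition(("a",), ("b",)), Bipartition(("b",), ("a",)),
            Bipartition(("a",), ("c",)), Bipartition(("c",), ("a",)),
        ]
        table = TETable(None, bps, np.array([0.5, 0.05, 0.3, 0.2]))
        value, bp = index_tmin(table, rule="maxmin")
        assert value == pytest.approx(0.2)  # pair (a,c): min=0.2 beats (a,b): 0.05
        assert bp == bps[3]

    def test_tmean_is_arithmetic_mean(self):
        table = _toy_table([0.1, 0.3, 0.2])
        assert index_tmean(table) == pytest.approx(0.2)
        # brute-force accumulation
        acc = 0.0
        for v in table.values:
            acc += float(v)
        assert index_tmean(table) == pytest.approx(acc / len(table))

    def test_all_zero_table(self):
        assert index_tmean(_toy_table([0.0, 0.0, 0.0])) == 0.0

    def test_empty_table_rejected(self):
        with pytest.raises(ValueError):
            TETable(None, [], np.array([]))

    @pytest.mark.parametrize("seed", range(4))
    def test_min_le_mean_le_max_on_random_vars(self, seed):
        model = random_stable_var(4, seed=seed, coupling=0.8)
        rec = simulate_var(model, 20_000, seed=seed)
        table = te_table(rec, tau=1)
        tmin = index_tmin(table)[0]
        tmax = index_tmax(table)[0]
        tmean = index_tmean(table)
        assert tmin <= tmean <= tmax

    def test_driven_channel_lands_in_target_group(self):
        """One strong unidirectional coupling: T_max target contains
        the driven channel (on analytic covariances)."""
        F = np.eye(4) * 0.4
        F[2, 0] = 0.7  # channel 0 drives channel 2
        model = VARModel(F)
        cov2n = lagged_stationary_cov(model, tau=1)
        table = te_table_from_cov(cov2n, list(model.labels), tau=1)
        _, bp = index_tmax(table)
        assert "ch2" in bp.target and "ch0" in bp.source
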