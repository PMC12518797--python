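"""Hommola statistic against brute-force oracles, node filters at
their printed boundaries, tier nesting, outgroup handling and the
second-order shuffle test."""

import itertools

import dendropy
import numpy as np
import pandas as pd
import pytest

from beesym import cophylo as cp
from beesym import simdata as sd
from beesym._distance import DistanceMatrix
from conftest import make_dm


def _tree(newick):
    return dendropy.Tree.get(data=newick, schema="newick", preserve_underscores=True)


class TestPatristic:
    def test_two_tip_path_sum(self):
        dm = cp.patristic_matrix(_tree("(a:0.1,b:0.2);"))
        assert dm.values[dm.index_of("a"), dm.index_of("b")] == pytest.approx(0.3)

    def test_cherry_example(self):
        dm = cp.patristic_matrix(_tree("((a:1,b:1):1,c:2);"))
        assert dm.values[dm.index_of("a"), dm.index_of("b")] == pytest.approx(2.0)
        assert dm.values[dm.index_of("a"), dm.index_of("c")] == pytest.approx(4.0)

    def test_zero_diagonal_and_missing_length_error(self):
        dm = cp.patristic_matrix(_tree("((a:1,b:1):1,c:2);"))
        assert np.allclose(np.diag(dm.values), 0.0)
        with pytest.raises(ValueError):
            cp.patristic_matrix(_tree("((a:1,b),c:2);"))


def _brute_force_r(dh, ds, links):
    hv, sv = [], []
    for (s1, h1), (s2, h2) in itertools.combinations(links, 2):
        hv.append(dh.values[dh.index_of(h1), dh.index_of(h2)])
        sv.append(ds.values[ds.index_of(s1), ds.index_of(s2)])
    return np.corrcoef(hv, sv)[0, 1]


class TestHommola:
    def _random_instance(self, rng):
        nh, ns = int(rng.integers(3, 6)), int(rng.integers(3, 8))
        L = int(rng.integers(3, 16))
        dh = np.abs(rng.normal(size=(nh, nh)))
        dh = (dh + dh.T) / 2
        np.fill_diagonal(dh, 0)
        ds = np.abs(rng.normal(size=(ns, ns)))
        ds = (ds + ds.T) / 2
        np.fill_diagonal(ds, 0)
        hdm = make_dm(dh, prefix="h")
        sdm = make_dm(ds, prefix="p")
        links = [
            (f"p{rng.integers(ns)}", f"h{rng.integers(nh)}") for _ in range(L)
        ]
        return hdm, sdm, links

    def test_identical_distances_give_r_one(self):
        rng = np.random.default_rng(0)
        y = rng.normal(size=(5, 2))
        d = np.sqrt(((y[:, None, :] - y[None, :, :]) ** 2).sum(-1))
        hdm = make_dm(d, prefix="h")
        sdm = make_dm(d, prefix="p")
        links = [(f"p{i}", f"h{i}") for i in range(5)]
        res = cp.hommola_test(hdm, sdm, links, n_perm=99, seed=0)
        assert res.r == pytest.approx(1.0)

    def test_equal_host_distances_degenerate(self):
        flat = np.ones((4, 4)) - np.eye(4)
        rng = np.random.default_rng(1)
        y = rng.normal(size=(4, 2))
        d = np.sqrt(((y[:, None, :] - y[None, :, :]) ** 2).sum(-1))
        res = cp.hommola_test(
            make_dm(flat, prefix="h"),
            make_dm(d, prefix="p"),
            [(f"p{i}", f"h{i}") for i in range(4)],
            n_perm=99,
            seed=0,
        )
        assert res.degenerate and res.p == 1.0

    def test_r_matches_brute_force_on_random_instances(self):
        rng = np.random.default_rng(99)
        checked = 0
        while checked < 50:
            hdm, sdm, links = self._random_instance(rng)
            if len({h for _, h in links}) < 2 or len({s for s, _ in links}) < 2:
                continue
            res = cp.hommola_test(hdm, sdm, links, n_perm=9, seed=0)
            ref = _brute_force_r(hdm, sdm, links)
            if np.isnan(ref):
                assert res.degenerate
            else:
                assert abs(res.r - ref) < 1e-12
            checked += 1

    def test_exact_p_matches_enumeration_oracle(self):
        dh = np.array(
            [[0, 1, 2, 3], [1, 0, 1.5, 2.5], [2, 1.5, 0, 1], [3, 2.5, 1, 0]], float
        )
        ds = np.array(
            [[0, 0.5, 1.8, 2.6], [0.5, 0, 1.2, 2.2], [1.8, 1.2, 0, 0.9], [2.6, 2.2, 0.9, 0]],
            float,
        )
        hdm, sdm = make_dm(dh, prefix="h"), make_dm(ds, prefix="p")
        links = [(f"p{i}", f"h{i}") for i in range(4)]
        res = cp.hommola_test(hdm, sdm, links, method="exact")
        # independent brute-force over all 4! x 4! relabelings
        iu = [(i, j) for i in range(4) for j in range(i + 1, 4)]

        def r_of(ph, ps):
            hv = np.array([dh[ph[i], ph[j]] for i, j in iu])
            sv = np.array([ds[ps[i], ps[j]] for i, j in iu])
            return np.corrcoef(hv, sv)[0, 1]

        r0 = r_of(range(4), range(4))
        count = sum(
            r_of(ph, ps) >= r0 - 1e-12
            for ph in itertools.permutations(range(4))
            for ps in itertools.permutations(range(4))
        )
        assert res.p == pytest.approx(count / (24 * 24))
        assert res.r == pytest.approx(r0)

    def test_relabeling_invariance(self):
        rng = np.random.default_rng(13)
        hdm, sdm, links = self._random_instance(rng)
        res = cp.hommola_test(hdm, sdm, links, n_perm=50, seed=3)
        # relabel hosts consistently
        mapping = {l: f"H{i}" for i, l in enumerate(hdm.labels)}
        hdm2 = DistanceMatrix([mapping[l] for l in hdm.labels], hdm.values)
        links2 = [(s, mapping[h]) for s, h in links]
        res2 = cp.hommola_test(hdm2, sdm, links2, n_perm=50, seed=3)
        if not res.degenerate:
            assert res.r == pytest.approx(res2.r)
            assert res.p == res2.p

    def test_r_matches_skbio_implementation(self):
        skbio_evolve = pytest.importorskip("skbio.stats.evolve")
        rng = np.random.default_rng(17)
        for _ in range(10):
            hdm, sdm, links = self._random_instance(rng)
            if len({h for _, h in links}) < 2 or len({s for s, _ in links}) < 2:
                continue
            # skbio consumes an interaction matrix; duplicate links collapse,
            # so restrict to instances with unique (symbiont, host) pairs
            if len(set(links)) != len(links):
                continue
            inter = np.zeros((sdm.n, hdm.n), dtype=int)
            for s, h in links:
                inter[sdm.index_of(s), hdm.index_of(h)] = 1
            res = cp.hommola_test(hdm, sdm, links, n_perm=9, seed=0)
            ref_r, _, _ = skbio_evolve.hommola_cospeciation(
                hdm.values, sdm.values, inter, permutations=9
            )
            if not res.degenerate:
                assert res.r == pytest.approx(ref_r, abs=1e-12)

    def test_p_respects_plus_one_floor(self):
        rng = np.random.default_rng(21)
        y = rng.normal(size=(6, 2))
        d = np.sqrt(((y[:, None, :] - y[None, :, :]) ** 2).sum(-1))
        res = cp.hommola_test(
            make_dm(d, prefix="h"),
            make_dm(d, prefix="p"),
            [(f"p{i}", f"h{i}") for i in range(6)],
            n_perm=100,
            seed=0,
        )
        assert res.p >= 1 / 101


def _star_tree_set(n_tips, hosts, branch=0.05, outgroup_flags=None):
    parts = ",".join(f"t{i}:{branch}" for i in range(n_tips))
    tree = _tree(f"({parts});")
    tip_map = pd.DataFrame(
        {
            "mag_id": [f"t{i}" for i in range(n_tips)],
            "host_species": hosts,
            "is_outgroup": outgroup_flags or [False] * n_tips,
        },
        index=pd.Index([f"t{i}" for i in range(n_tips)], name="tip_id"),
    )
    return cp.SymbiontTreeSet(tree, tip_map)


class TestNodeFilters:
    def test_too_few_mags(self):
        ts = _star_tree_set(6, ["A_mellifera", "A_cerana", "A_dorsata"] * 2)
        recs = cp.enumerate_testable_nodes(ts, cp.CophyloConfig())
        assert not recs[0].passes and recs[0].reason == "too few MAGs"

    def test_too_few_hosts(self):
        ts = _star_tree_set(8, ["A_mellifera", "A_cerana"] * 4)
        recs = cp.enumerate_testable_nodes(ts, cp.CophyloConfig())
        assert not recs[0].passes and recs[0].reason == "too few hosts"

    def test_max_tip_tip_distance(self):
        ts = _star_tree_set(8, ["A_mellifera", "A_cerana", "A_dorsata", "A_florea"] * 2,
                            branch=0.6)  # tip-tip 1.2 > 1
        recs = cp.enumerate_testable_nodes(ts, cp.CophyloConfig())
        assert not recs[0].passes and "distance" in recs[0].reason

    def test_passing_node(self):
        ts = _star_tree_set(8, ["A_mellifera", "A_cerana", "A_dorsata", "A_florea"] * 2)
        recs = cp.enumerate_testable_nodes(ts, cp.CophyloConfig())
        assert recs[0].passes

    def test_filter_order_independent(self, host_tree):
        params = sd.SymbiontSimParams(dup_rate=0.3, n0=2, tips_per_lineage=2, seed=4)
        ts = sd.simulate_symbiont_tree(host_tree, params)
        recs = cp.enumerate_testable_nodes(ts, cp.CophyloConfig())
        shuffled = cp.SymbiontTreeSet(ts.tree, ts.tip_map.sample(frac=1, random_state=0))
        recs2 = cp.enumerate_testable_nodes(shuffled, cp.CophyloConfig())
        assert [(r.node_id, r.passes) for r in recs] == [
            (r.node_id, r.passes) for r in recs2
        ]


class TestNodeScan:
    def test_pure_cospeciation_detected_strict(self, host_tree):
        params = sd.SymbiontSimParams(
            cospec_prob=1.0, dup_rate=0.2, n0=3, tips_per_lineage=2, seed=42
        )
        ts = sd.simulate_symbiont_tree(host_tree, params)
        results = cp.node_scan(ts, host_tree, cp.CophyloConfig(seed=42))
        sig = cp.significant_nodes(results, "strict")
        assert len(sig) >= 1
        assert all(r.p == pytest.approx(1 / 101) for r in sig)

    def test_single_host_tree_has_no_testable_nodes(self):
        ts = _star_tree_set(10, ["A_mellifera"] * 10)
        results = cp.node_scan(ts, sd.default_host_tree(), cp.CophyloConfig(seed=0))
        assert results == []

    def test_tier_nesting(self, host_tree):
        params = sd.SymbiontSimParams(
            cospec_prob=0.8, dup_rate=0.4, switch_rate=0.5, n0=3,
            tips_per_lineage=2, seed=7,
        )
        ts = sd.simulate_symbiont_tree(host_tree, params)
        results = cp.node_scan(ts, host_tree, cp.CophyloConfig(seed=7))
        for r in results:
            if "strict" in r.significant_at:
                assert "medium" in r.significant_at
            if "medium" in r.significant_at:
                assert "relaxed" in r.significant_at

    def test_outgroup_nodes_reported_but_not_counted(self, host_tree):
        params = sd.SymbiontSimParams(
            cospec_prob=1.0, dup_rate=0.2, n0=3, tips_per_lineage=2, seed=42
        )
        ts = sd.simulate_symbiont_tree(host_tree, params)
        tip_map = ts.tip_map.copy()
        tip_map["is_outgroup"] = True  # every node now contains outgroup tips
        ts_out = cp.SymbiontTreeSet(ts.tree, tip_map)
        results = cp.node_scan(ts_out, host_tree, cp.CophyloConfig(seed=42))
        assert any("strict" in r.significant_at for r in results)
        assert cp.significant_nodes(results, "strict") == []

    def test_unknown_host_rejected(self):
        ts = _star_tree_set(8, ["A_mellifera", "A_cerana", "Bombus_sp", "A_florea"] * 2)
        with pytest.raises(ValueError):
            cp.node_scan(ts, sd.default_host_tree(), cp.CophyloConfig(seed=0))


class TestSecondOrder:
    def test_cospeciation_signal_beats_shuffled_null(self, host_tree):
        params = sd.SymbiontSimParams(
            cospec_prob=1.0, dup_rate=0.2, n0=3, tips_per_lineage=2, seed=42
        )
        ts = sd.simulate_symbiont_tree(host_tree, params)
        so = cp.second_order_test(ts, host_tree, cp.CophyloConfig(seed=42), n_shuffles=50)
        assert so.observed_count >= 1
        assert so.observed_count > np.median(so.null_counts)
        assert so.empirical_p == pytest.approx(1 / 51)

    def test_zero_shuffles_rejected(self, host_tree):
        params = sd.SymbiontSimParams(dup_rate=0.2, n0=2, tips_per_lineage=2, seed=1)
        ts = sd.simulate_symbiont_tree(host_tree, params)
        with pytest.raises(ValueError):
            cp.second_order_test(ts, host_tree, cp.CophyloConfig(seed=1), n_shuffles=0)
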