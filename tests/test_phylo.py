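import networkx as nx
import numpy as np
import pytest
from skbio import DistanceMatrix as SkDM
from skbio.tree import nj as skbio_nj

from actinoprint.dna import random_dna, revcomp
from actinoprint.io import SequenceRecord
from actinoprint.phylo import (
    DistanceMatrix,
    _bipartitions,
    bootstrap_support,
    jc_correct,
    neighbor_joining,
    p_distance,
    translate_fragment,
)
from actinoprint.util import ParameterError


class TestPDistance:
    def test_identical_rows(self):
        assert p_distance("ACGTACGT", "ACGTACGT") == 0.0

    def test_one_mismatch_in_ten(self):
        assert p_distance("ACGTACGTAC", "ACGTACGTAA") == pytest.approx(0.1)

    def test_gap_columns_excluded(self):
        assert p_distance("AC-T", "ACGT") == 0.0

    def test_ambiguity_columns_excluded(self):
        assert p_distance("ACNT", "ACGT") == 0.0

    def test_no_comparable_columns(self):
        with pytest.raises(ParameterError):
            p_distance("--", "AC")


class TestJukesCantor:
    def test_zero(self):
        assert jc_correct(0.0) == 0.0

    def test_closed_form_value(self):
        assert jc_correct(0.1) == pytest.approx(0.107326, abs=1e-6)

    def test_monotone_on_grid(self):
        grid = np.linspace(0.0, 0.74, 100)
        vals = [jc_correct(p) for p in grid]
        assert all(b > a for a, b in zip(vals, vals[1:]))
        assert all(jc_correct(p) >= p for p in grid)  # correction expands

    def test_saturation(self):
        with pytest.raises(ParameterError):
            jc_correct(0.75)


def random_additive_tree(n_leaves, rng):
    """Random unrooted binary tree with uniform branch lengths (networkx)."""
    g = nx.Graph()
    center = "i0"
    for k in range(3):
        g.add_edge(center, f"L{k}", weight=float(rng.uniform(0.1, 1.0)))
    next_internal = 1
    for k in range(3, n_leaves):
        u, v = list(g.edges())[rng.integers(g.number_of_edges())]
        w = g[u][v]["weight"]
        g.remove_edge(u, v)
        mid = f"i{next_internal}"
        next_internal += 1
        split = float(rng.uniform(0.2, 0.8))
        g.add_edge(u, mid, weight=w * split)
        g.add_edge(mid, v, weight=w * (1 - split))
        g.add_edge(mid, f"L{k}", weight=float(rng.uniform(0.1, 1.0)))
    leaves = [f"L{k}" for k in range(n_leaves)]
    dist = dict(nx.all_pairs_dijkstra_path_length(g, weight="weight"))
    d = np.array([[dist[a][b] for b in leaves] for a in leaves])
    return leaves, d, g


def graph_bipartitions(g, leaves, ref):
    parts = set()
    leafset = frozenset(leaves)
    for u, v in list(g.edges()):
        h = g.copy()
        h.remove_edge(u, v)
        side = frozenset(x for x in nx.node_connected_component(h, u) if x in leafset)
        if ref in side:
            side = leafset - side
        if len(side) >= 2 and len(leafset) - len(side) >= 2:
            parts.add(side)
    return parts


class TestNeighborJoining:
    def test_three_taxa_closed_form(self):
        d = np.array([[0.0, 0.3, 0.5], [0.3, 0.0, 0.6], [0.5, 0.6, 0.0]])
        tree = neighbor_joining(DistanceMatrix(["a", "b", "c"], d, "p-distance"))
        lengths = {t.name: t.length for t in tree.tips()}
        assert lengths["a"] == pytest.approx(0.5 * (0.3 + 0.5 - 0.6))
        assert lengths["b"] == pytest.approx(0.5 * (0.3 + 0.6 - 0.5))
        assert lengths["c"] == pytest.approx(0.5 * (0.5 + 0.6 - 0.3))

    def test_additive_matrix_recovered_exactly(self, rng):
        # randomized property: NJ is exact on additive distances (n <= 8)
        for _ in range(25):
            n = int(rng.integers(4, 9))
            leaves, d, g = random_additive_tree(n, rng)
            tree = neighbor_joining(DistanceMatrix(leaves, d, "p-distance"))
            got = tree.tip_tip_distances(endpoints=leaves)
            order = [got.ids.index(x) for x in leaves]
            recon = got.data[np.ix_(order, order)]
            assert np.allclose(recon, d, atol=1e-9)
            assert _bipartitions(tree, leaves[0]) == graph_bipartitions(
                g, leaves, leaves[0]
            )

    def test_agrees_with_skbio_nj_topology(self, rng):
        for _ in range(5):
            n = 7
            ids = [f"s{i}" for i in range(n)]
            d = rng.uniform(0.1, 1.0, size=(n, n))
            d = (d + d.T) / 2
            np.fill_diagonal(d, 0.0)
            mine = neighbor_joining(DistanceMatrix(ids, d, "p-distance"))
            theirs = skbio_nj(SkDM(d, ids))
            assert _bipartitions(mine, ids[0]) == _bipartitions(theirs, ids[0])

    def test_ultrametric_matrix_matches_upgma_topology(self, rng):
        import pandas as pd

        from actinoprint.cluster import upgma

        n = 6
        ids = [f"s{i}" for i in range(n)]
        sim = rng.uniform(0.2, 0.9, size=(n, n))
        sim = (sim + sim.T) / 2
        np.fill_diagonal(sim, 1.0)
        dend = upgma(pd.DataFrame(sim, index=ids, columns=ids))
        tree = dend.to_treenode()
        coph = tree.tip_tip_distances(endpoints=ids)
        order = [coph.ids.index(x) for x in ids]
        ultra = coph.data[np.ix_(order, order)]
        njt = neighbor_joining(DistanceMatrix(ids, ultra, "p-distance"))
        assert _bipartitions(njt, ids[0]) == _bipartitions(tree, ids[0])

    def test_rejects_small_or_nonfinite(self):
        with pytest.raises(ParameterError):
            neighbor_joining(
                DistanceMatrix(["a", "b"], np.zeros((2, 2)), "p-distance")
            )
        bad = np.array([[0.0, np.inf, 1.0], [np.inf, 0.0, 1.0], [1.0, 1.0, 0.0]])
        with pytest.raises(ParameterError):
            neighbor_joining(DistanceMatrix(["a", "b", "c"], bad, "p-distance"))


def two_clade_alignment(rng, n_per_clade=3, length=300, seed_div=0.02):
    ta = random_dna(length, rng)
    tb = random_dna(length, rng)
    recs = []
    for k in range(n_per_clade):
        for name, t in (("A", ta), ("B", tb)):
            seq = list(t)
            for i in range(length):
                if rng.random() < seed_div:
                    seq[i] = "ACGT"[rng.integers(4)]
            recs.append(SequenceRecord(f"{name}{k}", "", "".join(seq)))
    return recs


class TestBootstrap:
    def test_well_separated_clades_have_high_support(self, rng):
        recs = two_clade_alignment(rng)
        tree = bootstrap_support(recs, n_reps=50, rng_seed=9)
        clade_a = frozenset(r.id for r in recs if r.id.startswith("A"))
        all_ids = frozenset(r.id for r in recs)
        ref = recs[0].id
        side = clade_a if ref not in clade_a else all_ids - clade_a
        supports = {}
        for node in tree.non_tips(include_self=False):
            s = frozenset(t.name for t in node.tips())
            if ref in s:
                s = all_ids - s
            supports[s] = node.support
        assert supports[side] >= 90.0

    def test_single_replicate_supports_binary(self, rng):
        recs = two_clade_alignment(rng, n_per_clade=2, length=100)
        tree = bootstrap_support(recs, n_reps=1, rng_seed=4)
        for node in tree.non_tips(include_self=False):
            assert node.support in (0.0, 100.0)

    def test_deterministic_given_seed(self, rng):
        recs = two_clade_alignment(rng, n_per_clade=2, length=120)
        t1 = bootstrap_support(recs, n_reps=20, rng_seed=11)
        t2 = bootstrap_support(recs, n_reps=20, rng_seed=11)
        s1 = sorted(n.support for n in t1.non_tips(include_self=False))
        s2 = sorted(n.support for n in t2.non_tips(include_self=False))
        assert s1 == s2

    def test_invariant_to_leaf_order(self, rng):
        recs = two_clade_alignment(rng, n_per_clade=2, length=150)
        perm = recs[::-1]
        ref = recs[0].id
        all_ids = frozenset(r.id for r in recs)

        def support_map(tree):
            out = {}
            for node in tree.non_tips(include_self=False):
                s = frozenset(t.name for t in node.tips())
                if ref in s:
                    s = all_ids - s
                out[s] = node.support
            return out

        m1 = support_map(bootstrap_support(recs, n_reps=30, rng_seed=5))
        m2 = support_map(bootstrap_support(perm, n_reps=30, rng_seed=5))
        assert m1 == m2


class TestTranslateFragment:
    def test_frame_plus_one(self):
        assert translate_fragment("ATGAAA", min_quality=1) == "MK"

    def test_reverse_complement_same_protein(self):
        # coding frame is the unique longest stop-free frame in both
        # orientations, so the minus-strand scan must recover it
        cds = "ATGCCTCAATGTAAAACTTCTCCTTTATCTAATTGG"
        fwd = translate_fragment(cds, min_quality=1)
        rev = translate_fragment(revcomp(cds), min_quality=1)
        assert fwd == rev == "MPQCKTSPLSNW"

    def test_matches_bruteforce_six_frame_scan(self, rng):
        from Bio.Seq import Seq

        for _ in range(20):
            nt = random_dna(300, rng)
            rc = revcomp(nt)
            best = None
            for fi, (src, off) in enumerate(
                [(nt, 0), (nt, 1), (nt, 2), (rc, 0), (rc, 1), (rc, 2)]
            ):
                sub = src[off:]
                sub = sub[: len(sub) - len(sub) % 3]
                aa = str(Seq(sub).translate())
                run = max((len(x) for x in aa.split("*")), default=0)
                if best is None or run > best[0]:
                    best = (run, fi, aa)
            with pytest.warns() if best[0] < 10 else _nullcontext():
                assert translate_fragment(nt) == best[2]

    def test_short_fragment_rejected(self):
        with pytest.raises(ParameterError):
            translate_fragment("AT")

    def test_low_quality_warns_but_returns(self):
        with pytest.warns(UserWarning):
            out = translate_fragment("TAATAATAA")
        assert out  # still returns the best frame


class _nullcontext:
    def __enter__(self):
        return self

    def __exit__(self, *exc):
        return False
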