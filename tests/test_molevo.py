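import itertools
import math
import random

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from iceclock.errors import FrameError, SaturationError, UndefinedRateError
from iceclock.molevo import (
    CODON_TO_AA,
    STOP_CODONS,
    DistanceMatrix,
    MultipleAlignment,
    aa_substitution_rate,
    bootstrap_support,
    jc69_distance,
    jc_distance_matrix,
    nei_gojobori,
    nj_tree,
    p_distance,
)

SENSE_CODONS = sorted(set(CODON_TO_AA) - STOP_CODONS)


# ---------------------------------------------------------------------------
# distances


class TestPDistance:
    def test_identical_rows(self):
        assert p_distance("ACGTACGT", "ACGTACGT") == 0.0

    def test_one_difference_in_ten(self):
        assert p_distance("ACGTACGTAC", "ACGTACGTAA") == pytest.approx(0.1)

    def test_gap_columns_excluded(self):
        # 2 comparable columns, 1 difference
        assert p_distance("A-GT", "AC-A") == pytest.approx(0.5)

    def test_ambiguity_excluded(self):
        assert p_distance("ANGT", "ACGT") == pytest.approx(0.0)

    def test_no_comparable_positions(self):
        with pytest.raises(UndefinedRateError):
            p_distance("--", "AC")

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            p_distance("ACG", "AC")


class TestJC69:
    def test_zero(self):
        assert jc69_distance(0.0) == 0.0

    def test_derived_value(self):
        # independent evaluation of -(3/4) ln(1 - 4*0.1/3) = 0.10732563...
        assert jc69_distance(0.1) == pytest.approx(0.107326, abs=1e-6)
        assert jc69_distance(0.1) == pytest.approx(
            -0.75 * math.log(1 - 0.4 / 3), abs=1e-15
        )

    def test_saturation_boundary(self):
        with pytest.raises(SaturationError):
            jc69_distance(0.75)

    @given(st.floats(0.0, 0.7499))
    @settings(max_examples=200, deadline=None)
    def test_monotone_and_dominates_p(self, p):
        d = jc69_distance(p)
        assert d >= p * (1 - 1e-12)  # tolerate 1-ulp rounding at tiny p
        eps = 1e-4
        if p + eps < 0.75:
            assert jc69_distance(p + eps) > d


# ---------------------------------------------------------------------------
# neighbor joining


def random_additive_tree(n_taxa, rng):
    """Independent oracle: random unrooted binary tree as an edge list.

    Returns (labels, distance matrix, set of non-trivial splits).
    """
    labels = [f"t{i}" for i in range(n_taxa)]
    # adjacency: node -> list of (node, weight); leaves are labels,
    # internal nodes are ints
    next_internal = [0]

    def new_internal():
        next_internal[0] += 1
        return -next_internal[0]

    edges = {}

    def add_edge(a, b, w):
        edges.setdefault(a, []).append((b, w))
        edges.setdefault(b, []).append((a, w))

    def remove_edge(a, b):
        edges[a] = [(n, w) for n, w in edges[a] if n != b]
        edges[b] = [(n, w) for n, w in edges[b] if n != a]

    c = new_internal()
    for l in labels[:3]:
        add_edge(c, l, rng.uniform(0.5, 2.0))
    for l in labels[3:]:
        # pick a random existing edge and subdivide it
        pairs = {tuple(sorted((a, b), key=str)) for a in edges for b, _ in edges[a]}
        a, b = random.Random(int(rng.integers(1 << 30))).choice(sorted(pairs, key=str))
        w = next(w for n, w in edges[a] if n == b)
        mid = new_internal()
        remove_edge(a, b)
        s = rng.uniform(0.2, 0.8)
        add_edge(a, mid, w * s)
        add_edge(mid, b, w * (1 - s))
        add_edge(mid, l, rng.uniform(0.5, 2.0))

    # pairwise path lengths by BFS from each leaf
    def paths_from(src):
        dist = {src: 0.0}
        stack = [src]
        while stack:
            node = stack.pop()
            for nxt, w in edges[node]:
                if nxt not in dist:
                    dist[nxt] = dist[node] + w
                    stack.append(nxt)
        return dist

    m = np.zeros((n_taxa, n_taxa))
    for i, l in enumerate(labels):
        d = paths_from(l)
        for j, l2 in enumerate(labels):
            m[i, j] = d[l2]

    # non-trivial splits: removing each internal-internal / internal-leaf edge
    leafset = frozenset(labels)
    splits = set()
    for a in edges:
        for b, _ in edges[a]:
            # side of b when edge (a, b) removed
            seen = {b}
            stack = [b]
            while stack:
                node = stack.pop()
                for nxt, _w in edges[node]:
                    if nxt != a and nxt not in seen:
                        seen.add(nxt)
                        stack.append(nxt)
            side = frozenset(l for l in seen if isinstance(l, str))
            if 1 < len(side) < n_taxa - 1:
                splits.add(frozenset({side, leafset - side}))
    return labels, m, splits


class TestNJTree:
    def test_three_taxa_exact(self):
        m = np.array([[0.0, 3.0, 5.0], [3.0, 0.0, 6.0], [5.0, 6.0, 0.0]])
        tree = nj_tree(DistanceMatrix(labels=("a", "b", "c"), matrix=m))
        # three-point formulas: la = (3+5-6)/2 = 1, lb = 2, lc = 4
        lengths = {c.name: c.length for c in tree.root.children}
        assert lengths == {"a": pytest.approx(1.0), "b": pytest.approx(2.0),
                           "c": pytest.approx(4.0)}

    def test_four_taxa_additive_recovery_vs_least_squares(self):
        # known tree: ((A:2,B:3):1,(C:4,D:5)) -> additive matrix by hand
        m = np.array(
            [
                [0.0, 5.0, 7.0, 8.0],
                [5.0, 0.0, 8.0, 9.0],
                [7.0, 8.0, 0.0, 9.0],
                [8.0, 9.0, 9.0, 0.0],
            ]
        )
        labels = ("A", "B", "C", "D")
        tree = nj_tree(DistanceMatrix(labels=labels, matrix=m))
        # oracle: brute-force over the 3 unrooted topologies with LS edge fit
        best_topo, best_rss = None, np.inf
        for split in (("A", "B"), ("A", "C"), ("A", "D")):
            pair = set(split)
            other = [l for l in labels if l not in pair]
            # design: 5 edges (4 pendant + internal); distances decompose
            idx = {l: i for i, l in enumerate(labels)}
            rows, targets = [], []
            for i, j in itertools.combinations(labels, 2):
                row = np.zeros(5)
                row[idx[i]] = row[idx[j]] = 1
                same = ({i, j} == pair) or ({i, j} == set(other))
                if not same:
                    row[4] = 1
                rows.append(row)
                targets.append(m[idx[i], idx[j]])
            sol, rss, *_ = np.linalg.lstsq(np.array(rows), np.array(targets), rcond=None)
            rss = float(rss[0]) if len(rss) else 0.0
            if rss < best_rss:
                best_rss, best_topo = rss, frozenset(
                    {frozenset(pair), frozenset(other)}
                )
        assert tree.bipartitions() == {best_topo}
        # additive matrix reproduced exactly
        rec = tree.path_distance_matrix()
        order = [rec.labels.index(l) for l in labels]
        assert np.allclose(rec.matrix[np.ix_(order, order)], m, atol=1e-9)

    def test_ultrametric_five_taxa_additivity(self):
        # caterpillar ((((a,b)@1,c)@2,d)@3,e)@4: d(i,j) = 2 * MRCA height
        labels = ("a", "b", "c", "d", "e")
        m = np.array(
            [
                [0.0, 2.0, 4.0, 6.0, 8.0],
                [2.0, 0.0, 4.0, 6.0, 8.0],
                [4.0, 4.0, 0.0, 6.0, 8.0],
                [6.0, 6.0, 6.0, 0.0, 8.0],
                [8.0, 8.0, 8.0, 8.0, 0.0],
            ]
        )
        tree = nj_tree(DistanceMatrix(labels=labels, matrix=m))
        rec = tree.path_distance_matrix()
        order = [rec.labels.index(l) for l in labels]
        assert np.allclose(rec.matrix[np.ix_(order, order)], m, atol=1e-9)

    def test_random_additive_recovery_property(self):
        rng = np.random.default_rng(42)
        for _ in range(100):
            n = int(rng.integers(4, 8))
            labels, m, true_splits = random_additive_tree(n, rng)
            tree = nj_tree(DistanceMatrix(labels=tuple(labels), matrix=m))
            assert tree.bipartitions() == true_splits  # RF distance 0
            rec = tree.path_distance_matrix()
            order = [rec.labels.index(l) for l in labels]
            assert np.allclose(rec.matrix[np.ix_(order, order)], m, atol=1e-8)

    def test_invalid_matrices_rejected(self):
        with pytest.raises(ValueError):
            nj_tree(
                DistanceMatrix(
                    labels=("a", "b", "c"),
                    matrix=np.array([[0, 1, 2], [1.5, 0, 1], [2, 1, 0.0]]),
                )
            )
        with pytest.raises(ValueError):
            nj_tree(
                DistanceMatrix(
                    labels=("a", "b", "c"),
                    matrix=np.array([[0, -1, 2], [-1, 0, 1], [2, 1, 0.0]]),
                )
            )
        with pytest.raises(ValueError):
            nj_tree(DistanceMatrix(labels=("a", "b"), matrix=np.zeros((2, 2))))

    def test_branch_lengths_never_negative(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            n = 6
            m = rng.uniform(0.05, 1.0, size=(n, n))
            m = 0.5 * (m + m.T)
            np.fill_diagonal(m, 0.0)
            tree = nj_tree(
                DistanceMatrix(labels=tuple(f"x{i}" for i in range(n)), matrix=m)
            )

            def walk(node):
                assert node.length >= 0.0
                for c in node.children:
                    walk(c)

            for c in tree.root.children:
                walk(c)


# ---------------------------------------------------------------------------
# bootstrap


def four_taxon_alignment(n_cols=300, n_support=60):
    """Every informative column supports the split {a,b} | {c,d}."""
    cols = [("A", "A", "G", "G")] * n_support  # support ab|cd
    cols += [("C", "C", "C", "C")] * (n_cols - n_support)  # constant
    rows = ["".join(c[i] for c in cols) for i in range(4)]
    # add a few unique differences so pendant branches are positive
    rows[0] = "T" + rows[0][1:]
    rows[2] = rows[2][:-1] + "T"
    return MultipleAlignment(ids=("a", "b", "c", "d"), rows=tuple(rows))


class TestBootstrap:
    def test_determinism_under_seed(self):
        aln = four_taxon_alignment()
        t1 = bootstrap_support(aln, n_reps=200, seed=42)
        t2 = bootstrap_support(aln, n_reps=200, seed=42)
        assert t1.newick() == t2.newick()

    def test_unanimous_split_gets_full_support(self):
        aln = four_taxon_alignment()
        tree = bootstrap_support(aln, n_reps=100, seed=1)
        supports = [n.support for n in _internal_nodes(tree.root)]
        assert supports and all(s == pytest.approx(100.0) for s in supports)

    def test_zero_reps_leaves_supports_unset(self):
        aln = four_taxon_alignment()
        tree = bootstrap_support(aln, n_reps=0, seed=1)
        assert all(n.support is None for n in _internal_nodes(tree.root))

    def test_taxon_permutation_invariance(self):
        rng = np.random.default_rng(9)
        # random alignment with a genuine but imperfect ab|cd signal
        n_cols = 300
        base = rng.choice(list("ACGT"), size=n_cols)
        rows = np.tile(base, (4, 1))
        support_cols = rng.random(n_cols) < 0.25
        noise_cols = rng.random(n_cols) < 0.1
        for i in np.nonzero(support_cols)[0]:
            rows[2, i] = rows[3, i] = "T" if base[i] != "T" else "C"
        for i in np.nonzero(noise_cols)[0]:
            rows[int(rng.integers(4)), i] = "G" if base[i] != "G" else "A"
        aln = MultipleAlignment(
            ids=("a", "b", "c", "d"), rows=tuple("".join(r) for r in rows)
        )
        perm = MultipleAlignment(
            ids=("c", "a", "d", "b"),
            rows=(aln.rows[2], aln.rows[0], aln.rows[3], aln.rows[1]),
        )
        t1 = bootstrap_support(aln, n_reps=1000, seed=5)
        t2 = bootstrap_support(perm, n_reps=1000, seed=987)
        s1 = _supports_by_split(t1)
        s2 = _supports_by_split(t2)
        assert set(s1) == set(s2)
        for split, val in s1.items():
            assert abs(val - s2[split]) <= 5.0

    def test_skipped_replicates_reported(self):
        # every pair differs at exactly 7 of 10 columns (p = 0.7 < 3/4),
        # but a resample drawing >= 8 divergent columns saturates
        aln = MultipleAlignment(
            ids=("a", "b", "c", "d"),
            rows=("AAAAAAAAAA", "CCCCCCCAAA", "GGGGGGGAAA", "TTTTTTTAAA"),
        )
        tree = bootstrap_support(aln, n_reps=50, seed=0)
        assert tree.n_bootstrap_skipped > 0


def _internal_nodes(root):
    stack = list(root.children)
    while stack:
        n = stack.pop()
        if n.children:
            yield n
            stack.extend(n.children)


def _supports_by_split(tree):
    all_leaves = tree.root.leaf_names()
    out = {}
    for n in _internal_nodes(tree.root):
        side = n.leaf_names()
        if 1 < len(side) < len(all_leaves) - 1:
            out[frozenset({side, all_leaves - side})] = n.support
    return out


# ---------------------------------------------------------------------------
# Nei-Gojobori


def oracle_pathway_counts(ca, cb):
    """Brute-force pathway enumeration, written independently of the package."""
    diffs = [i for i in range(3) if ca[i] != cb[i]]
    if not diffs:
        return 0.0, 0.0
    outcomes = []
    for order in itertools.permutations(diffs):
        cur = ca
        s = n = 0
        ok = True
        for i in order:
            nxt = cur[:i] + cb[i] + cur[i + 1 :]
            if nxt in STOP_CODONS:
                ok = False
                break
            if CODON_TO_AA[nxt] == CODON_TO_AA[cur]:
                s += 1
            else:
                n += 1
            cur = nxt
        if ok:
            outcomes.append((s, n))
    if not outcomes:
        return None
    return (
        sum(o[0] for o in outcomes) / len(outcomes),
        sum(o[1] for o in outcomes) / len(outcomes),
    )


def oracle_syn_sites(codon):
    aa = CODON_TO_AA[codon]
    total = 0.0
    for i in range(3):
        alts = [codon[:i] + b + codon[i + 1 :] for b in "ACGT" if b != codon[i]]
        alts = [a for a in alts if a not in STOP_CODONS]
        if alts:
            total += sum(1 for a in alts if CODON_TO_AA[a] == aa) / len(alts)
    return total


class TestNeiGojobori:
    def test_identical_codons(self):
        res = nei_gojobori("TTT", "TTT")
        assert res.syn_differences == 0.0
        assert res.nonsyn_differences == 0.0

    def test_single_synonymous_difference(self):
        res = nei_gojobori("TTT", "TTC")  # both Phe
        assert res.syn_differences == 1.0
        assert res.nonsyn_differences == 0.0

    def test_two_step_pathway_average(self):
        # TTT (Phe) vs GTA (Val): two orderings, average (0.5, 1.5)
        res = nei_gojobori("TTT", "GTA")
        exp = oracle_pathway_counts("TTT", "GTA")
        assert res.syn_differences == pytest.approx(exp[0])
        assert res.nonsyn_differences == pytest.approx(exp[1])
        assert res.syn_differences == pytest.approx(0.5)
        assert res.nonsyn_differences == pytest.approx(1.5)

    def test_site_conservation_exact(self):
        rng = random.Random(1)
        for _ in range(50):
            n = rng.randint(1, 20)
            a = "".join(rng.choice(SENSE_CODONS) for _ in range(n))
            b = "".join(rng.choice(SENSE_CODONS) for _ in range(n))
            try:
                res = nei_gojobori(a, b)
            except FrameError:
                continue
            assert res.syn_sites + res.nonsyn_sites == pytest.approx(
                3.0 * res.compared_codons, abs=1e-12
            )

    def test_agrees_with_pathway_oracle_on_500_random_pairs(self):
        rng = random.Random(2024)
        checked = 0
        while checked < 500:
            ca = rng.choice(SENSE_CODONS)
            cb = rng.choice(SENSE_CODONS)
            exp = oracle_pathway_counts(ca, cb)
            if exp is None:
                continue  # all pathways blocked; convention-dependent
            res = nei_gojobori(ca + "TTT", cb + "TTT")  # pad to avoid trailing-stop path
            assert res.syn_differences == pytest.approx(exp[0], abs=1e-12)
            assert res.nonsyn_differences == pytest.approx(exp[1], abs=1e-12)
            s_exp = 0.5 * (oracle_syn_sites(ca) + oracle_syn_sites(cb)) + oracle_syn_sites("TTT")
            assert res.syn_sites == pytest.approx(s_exp, abs=1e-12)
            checked += 1

    def test_gapped_codons_skipped_whole(self):
        res = nei_gojobori("TTT---AAA", "TTCGGGAAA")
        assert res.compared_codons == 2

    def test_internal_stop_raises_with_index(self):
        with pytest.raises(FrameError, match="codon index 1"):
            nei_gojobori("TTTTAATTT", "TTTTACTTT")

    def test_trailing_stop_skipped(self):
        res = nei_gojobori("TTTTAA", "TTCTAA")
        assert res.compared_codons == 1

    def test_length_validation(self):
        with pytest.raises(ValueError):
            nei_gojobori("TTTA", "TTTA")
        with pytest.raises(ValueError):
            nei_gojobori("TTT", "TTTAAA")

    def test_dnds_ratio_for_divergent_genes(self):
        rng = random.Random(7)
        a = "".join(rng.choice(SENSE_CODONS) for _ in range(100))
        res = nei_gojobori(a, a)
        assert res.pS == 0.0 and res.pN == 0.0
        assert res.ratio is None  # dS == 0


# ---------------------------------------------------------------------------
# amino-acid rate


class TestAaSubstitutionRate:
    def test_one_per_hundred_per_century(self):
        a = "A" * 100
        b = "C" + "A" * 99
        est = aa_substitution_rate(a, b, elapsed=100.0)
        assert est.rate == pytest.approx(1.0)
        assert est.differences == 1
        assert est.compared_positions == 100

    def test_identical_proteins(self):
        assert aa_substitution_rate("MKV", "MKV", 100.0).rate == 0.0

    def test_direct_arithmetic(self):
        a = "A" * 250
        b = "C" * 5 + "A" * 245
        est = aa_substitution_rate(a, b, elapsed=300.0)
        assert est.rate == pytest.approx(2.0 / 3.0)

    def test_gap_deletion(self):
        est = aa_substitution_rate("MK-V", "MKAV", 100.0)
        assert est.compared_positions == 3
        assert est.differences == 0

    def test_errors(self):
        with pytest.raises(UndefinedRateError):
            aa_substitution_rate("MKV", "MKV", 0.0)
        with pytest.raises(UndefinedRateError):
            aa_substitution_rate("---", "MKV", 100.0)


def test_jc_matrix_symmetry():
    aln = four_taxon_alignment()
    dm = jc_distance_matrix(aln)
    assert np.allclose(dm.matrix, dm.matrix.T)
    assert np.all(np.diag(dm.matrix) == 0)
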