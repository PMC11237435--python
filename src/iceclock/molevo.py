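"""Distance, tree, bootstrap and dN/dS machinery for rate calibration.

Implements p-distances with pairwise gap deletion, the Jukes-Cantor
correction, Saitou-Nei neighbor joining, bootstrap support by leaf
bipartitions, the original equal-weight pathway-averaging synonymous /
non-synonymous counting scheme, and the amino-acid substitution-rate
statistic (substitutions per 100 residues per century).
"""

from __future__ import annotations

import itertools
import math

from dataclasses import dataclass

import numpy as np
from Bio import SeqIO
from Bio.Data import CodonTable

from .errors import FrameError, SaturationError, UndefinedRateError

DNA_ALPHABET = frozenset("ACGT")
PROTEIN_ALPHABET = frozenset("ACDEFGHIKLMNPQRSTVWY")

_STANDARD_TABLE = CodonTable.unambiguous_dna_by_id[1]
CODON_TO_AA = dict(_STANDARD_TABLE.forward_table)
STOP_CODONS = frozenset(_STANDARD_TABLE.stop_codons)


# ---------------------------------------------------------------------------
# alignments


@dataclass(frozen=True)
class MultipleAlignment:
    """Equal-length aligned rows keyed by identifier."""

    ids: tuple
    rows: tuple  # uppercase strings, same length

    def __post_init__(self):
        if len(self.ids) != len(self.rows):
            raise ValueError("ids and rows length mismatch")
        if len(set(self.ids)) != len(self.ids):
            raise ValueError("duplicate sequence identifiers")
        lengths = {len(r) for r in self.rows}
        if len(lengths) > 1:
            raise ValueError(f"unequal row lengths: {sorted(lengths)}")

    @property
    def n_taxa(self) -> int:
        return len(self.ids)

    @property
    def length(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    def row(self, ident: str) -> str:
        return self.rows[self.ids.index(ident)]

    def resample_columns(self, columns) -> "MultipleAlignment":
        rows = tuple("".join(r[c] for c in columns) for r in self.rows)
        return MultipleAlignment(ids=self.ids, rows=rows)


def read_alignment(path) -> MultipleAlignment:
    """Read an aligned FASTA file."""
    ids, rows = [], []
    for rec in SeqIO.parse(str(path), "fasta"):
        ids.append(rec.id)
        rows.append(str(rec.seq).upper())
    if not ids:
        raise ValueError(f"no sequences in {path}")
    return MultipleAlignment(ids=tuple(ids), rows=tuple(rows))


# ---------------------------------------------------------------------------
# distances


def p_distance(row_a: str, row_b: str, alphabet=DNA_ALPHABET) -> float:
    """Proportion of differing positions under pairwise deletion.

    Columns where either row carries a gap or a character outside
    ``alphabet`` are excluded from the comparison.

    Raises
    ------
    UndefinedRateError
        If no comparable positions remain.
    """
    if len(row_a) != len(row_b):
        raise ValueError("rows must have equal length")
    compared = 0
    diffs = 0
    for a, b in zip(row_a, row_b):
        if a not in alphabet or b not in alphabet:
            continue
        compared += 1
        if a != b:
            diffs += 1
    if compared == 0:
        raise UndefinedRateError("no comparable positions between rows")
    return diffs / compared


def jc69_distance(p: float) -> float:
    """Jukes-Cantor correction ``d = -(3/4) ln(1 - (4/3) p)``.

    Raises
    ------
    SaturationError
        If ``p >= 3/4`` (the correction diverges).
    """
    if p < 0:
        raise ValueError("proportion must be non-negative")
    if p >= 0.75:
        raise SaturationError(f"proportion {p} >= 3/4: JC69 distance undefined")
    return -0.75 * math.log1p(-(4.0 / 3.0) * p)


@dataclass(frozen=True)
class DistanceMatrix:
    labels: tuple
    matrix: np.ndarray

    def __post_init__(self):
        m = np.asarray(self.matrix, dtype=float)
        if m.shape != (len(self.labels), len(self.labels)):
            raise ValueError("matrix shape does not match labels")
        object.__setattr__(self, "matrix", m)


def jc_distance_matrix(aln: MultipleAlignment, alphabet=DNA_ALPHABET) -> DistanceMatrix:
    """Pairwise JC69 distances over an alignment (pairwise deletion)."""
    n = aln.n_taxa
    m = np.zeros((n, n))
    for i, j in itertools.combinations(range(n), 2):
        d = jc69_distance(p_distance(aln.rows[i], aln.rows[j], alphabet))
        m[i, j] = m[j, i] = d
    return DistanceMatrix(labels=aln.ids, matrix=m)


# ---------------------------------------------------------------------------
# trees


class TreeNode:
    """Node of an unrooted tree (represented rooted at the final join)."""

    __slots__ = ("name", "children", "length", "support")

    def __init__(self, name=None, children=None, length=0.0, support=None):
        self.name = name
        self.children = children or []
        self.length = length  # branch length to parent
        self.support = support  # bootstrap percentage of the edge to parent

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self):
        if self.is_leaf:
            yield self
        else:
            for c in self.children:
                yield from c.leaves()

    def leaf_names(self) -> frozenset:
        return frozenset(l.name for l in self.leaves())

    def newick(self) -> str:
        return self._newick_node() + ";"

    def _newick_node(self) -> str:
        if self.is_leaf:
            return f"{self.name}:{self.length:.10g}"
        inner = ",".join(c._newick_node() for c in self.children)
        label = "" if self.support is None else f"{self.support:.4g}"
        return f"({inner}){label}:{self.length:.10g}"


@dataclass(frozen=True)
class PhyloTree:
    """Unrooted tree with leaf labels, branch lengths and optional supports."""

    root: TreeNode
    labels: tuple
    n_bootstrap_skipped: int = 0

    def newick(self) -> str:
        return self.root.newick()

    def bipartitions(self) -> set:
        """Non-trivial leaf bipartitions, each as a canonical frozenset pair."""
        all_leaves = self.root.leaf_names()
        splits = set()
        for node in _internal_edges(self.root):
            side = node.leaf_names()
            if 1 < len(side) < len(all_leaves) - 1:
                splits.add(frozenset({side, all_leaves - side}))
        return splits

    def path_distance_matrix(self) -> DistanceMatrix:
        """Pairwise leaf-to-leaf path lengths (additivity check)."""
        labels = sorted(self.root.leaf_names())
        idx = {l: i for i, l in enumerate(labels)}
        n = len(labels)
        m = np.zeros((n, n))
        # depth of each leaf below every node via post-order accumulation
        def collect(node):
            if node.is_leaf:
                return {node.name: node.length}
            depths = {}
            child_maps = [collect(c) for c in node.children]
            for a, b in itertools.combinations(range(len(child_maps)), 2):
                for la, da in child_maps[a].items():
                    for lb, db in child_maps[b].items():
                        m[idx[la], idx[lb]] = m[idx[lb], idx[la]] = da + db
            for cm in child_maps:
                for l, d in cm.items():
                    depths[l] = d + node.length
            return depths

        collect(self.root)
        return DistanceMatrix(labels=tuple(labels), matrix=m)


def _internal_edges(root: TreeNode):
    """Yield non-root internal nodes (each defines one internal edge)."""
    stack = list(root.children)
    while stack:
        node = stack.pop()
        if not node.is_leaf:
            yield node
            stack.extend(node.children)


def nj_tree(dm: DistanceMatrix) -> PhyloTree:
    """Saitou-Nei neighbor joining.

    Iteratively joins the pair minimizing
    ``Q(i,j) = (r - 2) D(i,j) - R_i - R_j`` where ``R_i = sum_k D(i,k)``,
    with the standard branch-length and distance-reduction formulas.
    Negative branch lengths are clamped to zero with the deficit moved to
    the sister edge so the pair's length sum is preserved.

    Raises
    ------
    ValueError
        For fewer than 3 taxa or an asymmetric/negative input matrix.
    """
    d = np.array(dm.matrix, dtype=float)
    n = d.shape[0]
    if n < 3:
        raise ValueError("neighbor joining requires at least 3 taxa")
    if not np.allclose(d, d.T, atol=1e-12):
        raise ValueError("distance matrix must be symmetric")
    if np.any(d < -1e-12):
        raise ValueError("distance matrix must be non-negative")

    nodes = [TreeNode(name=l) for l in dm.labels]
    active = list(range(n))

    while len(active) > 3:
        r = len(active)
        sub = d[np.ix_(active, active)]
        rowsum = sub.sum(axis=1)
        q = (r - 2) * sub - rowsum[:, None] - rowsum[None, :]
        np.fill_diagonal(q, np.inf)
        a, b = np.unravel_index(np.argmin(q), q.shape)
        if a > b:
            a, b = b, a
        i, j = active[a], active[b]
        dij = d[i, j]
        li = 0.5 * dij + (rowsum[a] - rowsum[b]) / (2.0 * (r - 2))
        lj = dij - li
        li, lj = _clamp_pair(li, lj)
        ni, nj_ = nodes[i], nodes[j]
        ni.length, nj_.length = li, lj
        parent = TreeNode(children=[ni, nj_])
        # distances from the new node to the remaining taxa
        new_d = 0.5 * (d[i, :] + d[j, :] - dij)
        d = np.vstack([d, new_d])
        new_col = np.append(new_d, 0.0)
        d = np.column_stack([d, new_col])
        nodes.append(parent)
        active = [k for k in active if k not in (i, j)] + [len(nodes) - 1]

    i, j, k = active
    li = 0.5 * (d[i, j] + d[i, k] - d[j, k])
    lj = 0.5 * (d[i, j] + d[j, k] - d[i, k])
    lk = 0.5 * (d[i, k] + d[j, k] - d[i, j])
    li, lj, lk = (max(v, 0.0) for v in (li, lj, lk))
    nodes[i].length, nodes[j].length, nodes[k].length = li, lj, lk
    root = TreeNode(children=[nodes[i], nodes[j], nodes[k]])
    return PhyloTree(root=root, labels=dm.labels)


def _clamp_pair(li: float, lj: float) -> tuple:
    """Clamp a negative length to 0, moving the deficit to the sister edge."""
    if li < 0:
        lj += li
        li = 0.0
    if lj < 0:
        li += lj
        lj = 0.0
    return max(li, 0.0), max(lj, 0.0)


def bootstrap_support(
    aln: MultipleAlignment,
    n_reps: int = 1000,
    seed=None,
    alphabet=DNA_ALPHABET,
) -> PhyloTree:
    """NJ tree from the full alignment with bootstrap supports on its edges.

    ``n_reps`` column resamples with replacement are drawn under ``seed``;
    each replicate is turned into a JC69/NJ tree and the support of each
    internal edge of the full-data tree is the percentage of replicate trees
    containing the same leaf bipartition.  Replicates hitting JC saturation
    (or losing all comparable columns for some pair) are skipped; their
    count is reported on the returned tree.  ``n_reps = 0`` returns the tree
    without supports.
    """
    if aln.length < 1:
        raise ValueError("alignment must have at least one column")
    full = nj_tree(jc_distance_matrix(aln, alphabet))
    if n_reps == 0:
        return full
    rng = np.random.default_rng(seed)
    target_splits = {s: 0 for s in full.bipartitions()}
    skipped = 0
    ok = 0
    for _ in range(n_reps):
        cols = rng.integers(0, aln.length, size=aln.length)
        rep = aln.resample_columns(cols)
        try:
            tree = nj_tree(jc_distance_matrix(rep, alphabet))
        except (SaturationError, UndefinedRateError):
            skipped += 1
            continue
        ok += 1
        rep_splits = tree.bipartitions()
        for s in target_splits:
            if s in rep_splits:
                target_splits[s] += 1
    if ok > 0:
        all_leaves = full.root.leaf_names()
        for node in _internal_edges(full.root):
            side = node.leaf_names()
            if 1 < len(side) < len(all_leaves) - 1:
                split = frozenset({side, all_leaves - side})
                node.support = 100.0 * target_splits[split] / ok
    return PhyloTree(
        root=full.root, labels=full.labels, n_bootstrap_skipped=skipped
    )


# ---------------------------------------------------------------------------
# synonymous / non-synonymous analysis


@dataclass(frozen=True)
class DnDsResult:
    """Synonymous/non-synonymous partition of two codon-aligned sequences."""

    syn_differences: float  # Sd
    nonsyn_differences: float  # Nd
    syn_sites: float  # S
    nonsyn_sites: float  # N
    compared_codons: int
    pS: float
    pN: float
    dS: float
    dN: float
    ratio: float  # dN/dS, None when dS == 0


def _codon_sites(codon: str) -> tuple:
    """Potential (synonymous, non-synonymous) site counts of one codon.

    Per position, the synonymous fraction is computed among the single-base
    changes that do not create a stop codon; the non-synonymous fraction is
    its complement, so the two always sum to 1 per position (3 per codon).
    """
    aa = CODON_TO_AA[codon]
    s = 0.0
    for pos in range(3):
        syn = 0
        sense = 0
        for base in "ACGT":
            if base == codon[pos]:
                continue
            alt = codon[:pos] + base + codon[pos + 1 :]
            if alt in STOP_CODONS:
                continue
            sense += 1
            if CODON_TO_AA[alt] == aa:
                syn += 1
        s += syn / sense if sense else 0.0
    return s, 3.0 - s


def _pathway_counts(codon_a: str, codon_b: str) -> tuple:
    """Average (syn, nonsyn) step counts over equal-weight mutational pathways.

    All orderings of the differing positions are enumerated; pathways passing
    through a stop codon are discarded.  If every pathway is blocked by a
    stop (not possible between sense codons differing at <= 2 positions,
    vanishingly rare at 3), all pathways are used with stop-crossing steps
    counted as non-synonymous.
    """
    diff = [p for p in range(3) if codon_a[p] != codon_b[p]]
    if not diff:
        return 0.0, 0.0
    valid = []
    blocked = []
    for order in itertools.permutations(diff):
        current = codon_a
        sd = nd = 0
        through_stop = False
        for pos in order:
            nxt = current[:pos] + codon_b[pos] + current[pos + 1 :]
            if nxt in STOP_CODONS:
                through_stop = True
                nd += 1
            elif current not in STOP_CODONS and CODON_TO_AA[nxt] == CODON_TO_AA[current]:
                sd += 1
            else:
                nd += 1
            current = nxt
        (blocked if through_stop else valid).append((sd, nd))
    pool = valid if valid else blocked
    sd = sum(p[0] for p in pool) / len(pool)
    nd = sum(p[1] for p in pool) / len(pool)
    return sd, nd


def nei_gojobori(seq_a: str, seq_b: str) -> DnDsResult:
    """Equal-weight pathway-averaging dN/dS for two codon-aligned sequences.

    Codon pairs containing gaps or ambiguity in either sequence are skipped
    whole.  Potential sites are averaged between the two sequences; the
    difference proportions are corrected with the JC69 formula.

    Raises
    ------
    ValueError
        If the sequences are not equal-length with length divisible by 3.
    FrameError
        If either sequence contains an internal stop codon (a trailing stop
        present in a final codon is skipped, not an error).
    """
    if len(seq_a) != len(seq_b):
        raise ValueError("sequences must be equal length")
    if len(seq_a) % 3 != 0:
        raise ValueError("codon-aligned sequences must have length divisible by 3")
    seq_a = seq_a.upper()
    seq_b = seq_b.upper()
    n_codons = len(seq_a) // 3

    s_sites_a = s_sites_b = 0.0
    sd = nd = 0.0
    compared = 0
    for k in range(n_codons):
        ca = seq_a[3 * k : 3 * k + 3]
        cb = seq_b[3 * k : 3 * k + 3]
        if any(c not in DNA_ALPHABET for c in ca + cb):
            continue
        for label, codon in (("a", ca), ("b", cb)):
            if codon in STOP_CODONS:
                if k == n_codons - 1:
                    break  # trailing stop: skip the codon pair
                raise FrameError(
                    f"internal stop codon {codon} at codon index {k} "
                    f"in sequence {label}"
                )
        else:
            compared += 1
            sa, _ = _codon_sites(ca)
            sb, _ = _codon_sites(cb)
            s_sites_a += sa
            s_sites_b += sb
            d_s, d_n = _pathway_counts(ca, cb)
            sd += d_s
            nd += d_n

    if compared == 0:
        raise UndefinedRateError("no comparable codons between sequences")
    S = 0.5 * (s_sites_a + s_sites_b)
    N = 3.0 * compared - S
    pS = sd / S if S > 0 else 0.0
    pN = nd / N if N > 0 else 0.0
    # saturated proportions leave the corrected distance undefined (NaN)
    # but the raw counts are still meaningful
    dS = jc69_distance(pS) if pS < 0.75 else math.nan
    dN = jc69_distance(pN) if pN < 0.75 else math.nan
    ratio = (dN / dS) if (dS > 0 and not math.isnan(dN)) else None
    return DnDsResult(
        syn_differences=sd,
        nonsyn_differences=nd,
        syn_sites=S,
        nonsyn_sites=N,
        compared_codons=compared,
        pS=pS,
        pN=pN,
        dS=dS,
        dN=dN,
        ratio=ratio,
    )


# ---------------------------------------------------------------------------
# amino-acid substitution rate


@dataclass(frozen=True)
class SubstRateEstimate:
    """Protein divergence expressed per 100 residues per century."""

    differences: int
    compared_positions: int
    elapsed: float  # yr
    rate: float  # substitutions per 100 aa per century


def aa_substitution_rate(
    protein_a: str, protein_b: str, elapsed: float
) -> SubstRateEstimate:
    """Amino-acid substitution rate between two aligned protein rows.

    Differences are counted with pairwise gap deletion (columns with '-' or
    a non-standard residue in either row are excluded):
    ``rate = (differences / positions * 100) / (elapsed / 100)``.
    """
    if elapsed <= 0:
        raise UndefinedRateError("elapsed must be positive")
    if len(protein_a) != len(protein_b):
        raise ValueError("protein rows must have equal length")
    compared = 0
    diffs = 0
    for a, b in zip(protein_a.upper(), protein_b.upper()):
        if a not in PROTEIN_ALPHABET or b not in PROTEIN_ALPHABET:
            continue
        compared += 1
        if a != b:
            diffs += 1
    if compared == 0:
        raise UndefinedRateError("no comparable residue positions")
    rate = (diffs / compared * 100.0) / (elapsed / 100.0)
    return SubstRateEstimate(
        differences=diffs,
        compared_positions=compared,
        elapsed=float(elapsed),
        rate=float(rate),
    )
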