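"""Distance phylogenetics for whole-plastome alignments.

Pairwise distances are estimated under a TN93-family model (two
transition classes, one transversion class, unequal base frequencies)
whose substitution-rate parameters are shared across all sequence pairs
and fitted by maximizing the composite (summed pairwise) log-likelihood;
ambiguous columns are dropped pair by pair (pairwise deletion). Trees
are built by neighbor joining and rooted on an outgroup.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import expm
from scipy.optimize import minimize
from skbio import TreeNode

_CODE = {"A": 0, "C": 1, "G": 2, "T": 3}
VALID = "ACGT"


@dataclass
class MultiAlignment:
    """Equal-length aligned sequences over {A, C, G, T, -, N}."""

    taxa: list[str]
    rows: list[str]

    def __post_init__(self) -> None:
        if len(self.taxa) != len(self.rows):
            raise ValueError("taxa and rows differ in number")
        lengths = {len(r) for r in self.rows}
        if len(lengths) > 1:
            raise ValueError("alignment rows differ in length")
        bad = set("".join(self.rows)) - set("ACGT-N")
        if bad:
            raise ValueError(f"invalid alignment characters: {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    @property
    def n_taxa(self) -> int:
        return len(self.taxa)

    def matrix(self) -> np.ndarray:
        """(n_taxa, length) array of base codes; -1 for gap/N."""
        arr = np.frombuffer("".join(self.rows).encode(), dtype="S1")
        arr = arr.reshape(self.n_taxa, len(self))
        out = np.full(arr.shape, -1, dtype=np.int8)
        for b, c in _CODE.items():
            out[arr == b.encode()] = c
        return out

    @classmethod
    def from_fasta(cls, path) -> "MultiAlignment":
        from Bio import SeqIO

        taxa, rows = [], []
        for rec in SeqIO.parse(str(path), "fasta"):
            taxa.append(rec.id)
            rows.append(str(rec.seq).upper())
        return cls(taxa, rows)


def reference_msa(reference, genomes: dict[str, str], params=None
                  ) -> MultiAlignment:
    """Pseudo-MSA on reference coordinates from unaligned genomes.

    Each genome is aligned pairwise to the reference and its bases are
    projected onto reference columns (deletions become '-'; insertions
    relative to the reference occupy no reference column and are
    dropped). Adequate for the near-identical plastomes this package
    targets; it is not a general multiple aligner.
    """
    from .indelscan import GAP, align_pair

    ref_seq = reference.sequence if hasattr(reference, "sequence") else reference
    ref_id = reference.id if hasattr(reference, "id") else "reference"
    taxa = [ref_id]
    rows = [ref_seq]
    for name in sorted(genomes):
        aln = align_pair(ref_seq, genomes[name], params,
                         ref_id=ref_id, qry_id=name)
        row = []
        for a, b in zip(aln.aligned_ref, aln.aligned_qry):
            if a == GAP:
                continue
            row.append(b if b != GAP else "-")
        taxa.append(name)
        rows.append("".join(row))
    return MultiAlignment(taxa, rows)


# ---------------------------------------------------------------------------
# usable sites and site counts


def pairwise_usable_sites(aln: MultiAlignment) -> np.ndarray:
    """Matrix of per-pair usable-site counts: columns where both rows hold
    an unambiguous base (pairwise deletion)."""
    m = aln.matrix()
    ok = (m >= 0).astype(np.int64)
    return ok @ ok.T


def usable_positions_union(aln: MultiAlignment) -> int:
    """Columns usable in at least one pair (i.e. with >= 2 unambiguous
    bases)."""
    m = aln.matrix()
    return int(((m >= 0).sum(axis=0) >= 2).sum())


def count_variable_sites(aln: MultiAlignment,
                         mode: str = "all-variable") -> int:
    """Number of variable columns, ignoring gaps and N.

    mode 'all-variable': >= 2 distinct bases among the rows present;
    mode 'parsimony-informative': >= 2 bases occurring in >= 2 rows each.
    """
    if mode not in ("all-variable", "parsimony-informative"):
        raise ValueError(f"unknown mode {mode!r}")
    m = aln.matrix()
    counts = np.stack([(m == c).sum(axis=0) for c in range(4)])  # 4 x L
    if mode == "all-variable":
        return int(((counts > 0).sum(axis=0) >= 2).sum())
    return int(((counts >= 2).sum(axis=0) >= 2).sum())


# ---------------------------------------------------------------------------
# composite-likelihood TN93 distances


@dataclass
class DistanceMatrix:
    """Symmetric pairwise distances with per-pair usable-site counts."""

    taxa: list[str]
    d: np.ndarray
    usable_sites: np.ndarray | None = None
    flagged: list[tuple[str, str, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        d = np.asarray(self.d, dtype=float)
        if d.shape != (len(self.taxa), len(self.taxa)):
            raise ValueError("distance matrix shape mismatch")
        if not np.allclose(d, d.T, equal_nan=True):
            raise ValueError("distance matrix not symmetric")
        if np.any(np.diag(d) != 0):
            raise ValueError("nonzero diagonal")
        self.d = d

    def loc(self, a: str, b: str) -> float:
        return float(self.d[self.taxa.index(a), self.taxa.index(b)])

    def to_phylip(self) -> str:
        buf = io.StringIO()
        buf.write(f"{len(self.taxa)}\n")
        for name, row in zip(self.taxa, self.d):
            buf.write(name.ljust(12) + " ".join(f"{x:.8f}" for x in row) + "\n")
        return buf.getvalue()


def _pair_counts(aln: MultiAlignment) -> tuple[list[tuple[int, int]],
                                               list[np.ndarray]]:
    m = aln.matrix()
    n = aln.n_taxa
    pairs, counts = [], []
    for i in range(n):
        for j in range(i + 1, n):
            ok = (m[i] >= 0) & (m[j] >= 0)
            c = np.zeros((4, 4), dtype=np.int64)
            np.add.at(c, (m[i][ok], m[j][ok]), 1)
            pairs.append((i, j))
            counts.append(c)
    return pairs, counts


def _tn93_rate_matrix(k1: float, k2: float, pi: np.ndarray) -> np.ndarray:
    """TN93 generator normalized to one expected substitution per unit
    distance. k1, k2 are the purine and pyrimidine transition/transversion
    rate ratios. Base order A, C, G, T."""
    A, C, G, T = range(4)
    q = np.zeros((4, 4))
    for x in range(4):
        for y in range(4):
            if x == y:
                continue
            purines = {A, G}
            if {x, y} == {A, G}:
                rate = k1
            elif {x, y} == {C, T}:
                rate = k2
            else:
                rate = 1.0
            q[x, y] = rate * pi[y]
    np.fill_diagonal(q, -q.sum(axis=1))
    scale = -np.dot(pi, np.diag(q))
    return q / scale


def _composite_nll(theta: np.ndarray, counts: list[np.ndarray],
                   pi: np.ndarray) -> float:
    k1, k2 = np.exp(theta[0]), np.exp(theta[1])
    ds = np.exp(theta[2:])
    q = _tn93_rate_matrix(k1, k2, pi)
    nll = 0.0
    for d, c in zip(ds, counts):
        p = expm(q * d)
        p = np.clip(p, 1e-300, None)
        nll -= float((c * (np.log(p) + np.log(pi)[:, None])).sum())
    return nll


def _tn93_closed_form(c: np.ndarray, pi: np.ndarray) -> float:
    """Closed-form TN93 distance from a pair count matrix with supplied
    (shared) base frequencies; raises on saturation."""
    n = c.sum()
    A, C, G, T = range(4)
    p1 = (c[A, G] + c[G, A]) / n
    p2 = (c[C, T] + c[T, C]) / n
    q = (c[A, C] + c[C, A] + c[A, T] + c[T, A]
         + c[G, C] + c[C, G] + c[G, T] + c[T, G]) / n
    pa, pc, pg, pt = pi
    pr, py = pa + pg, pc + pt
    e1 = 1 - pr * p1 / (2 * pa * pg) - q / (2 * pr)
    e2 = 1 - py * p2 / (2 * pc * pt) - q / (2 * py)
    e3 = 1 - q / (2 * pr * py)
    if e1 <= 0 or e2 <= 0 or e3 <= 0:
        raise FloatingPointError("saturated pair: distance undefined")
    return float(-2 * pa * pg / pr * np.log(e1)
                 - 2 * pc * pt / py * np.log(e2)
                 - 2 * (pr * py - pa * pg * py / pr - pc * pt * pr / py)
                 * np.log(e3))


def _jc_distance(c: np.ndarray) -> float:
    n = c.sum()
    p = (n - np.trace(c)) / n
    arg = 1 - 4 * p / 3
    if arg <= 0:
        raise FloatingPointError("saturated pair: distance undefined")
    return float(-0.75 * np.log(arg))


def mcl_distances(aln: MultiAlignment, force_equal_rates: bool = False,
                  gtol: float = 1e-8) -> DistanceMatrix:
    """Pairwise distances with substitution parameters shared across
    pairs.

    Base frequencies are pooled over all sequences; the two
    transition/transversion rate ratios are estimated once, jointly with
    all pairwise distances, by maximizing the composite (summed pairwise)
    log-likelihood with L-BFGS-B to gradient tolerance `gtol`. With
    force_equal_rates the model collapses to equal rates and uniform
    frequencies, whose per-pair maximum is the Jukes-Cantor closed form
    (evaluated analytically).

    Saturated pairs are flagged (distance +inf with a diagnostic) rather
    than returned as silent NaN.
    """
    if aln.n_taxa < 2:
        raise ValueError("need at least two taxa")
    pairs, counts = _pair_counts(aln)
    for (i, j), c in zip(pairs, counts):
        if c.sum() == 0:
            raise ValueError(
                f"pair ({aln.taxa[i]}, {aln.taxa[j]}) has no usable sites")
    n = aln.n_taxa
    d = np.zeros((n, n))
    flagged: list[tuple[str, str, str]] = []

    if force_equal_rates:
        for (i, j), c in zip(pairs, counts):
            try:
                dist = _jc_distance(c)
            except FloatingPointError as exc:
                dist = np.inf
                flagged.append((aln.taxa[i], aln.taxa[j], str(exc)))
            d[i, j] = d[j, i] = dist
        return DistanceMatrix(aln.taxa, d, pairwise_usable_sites(aln), flagged)

    m = aln.matrix()
    base_counts = np.array([(m == c).sum() for c in range(4)], dtype=float)
    pi = base_counts / base_counts.sum()
    pi = np.clip(pi, 1e-6, None)
    pi /= pi.sum()

    # initialize from per-pair closed forms (JC fallback on saturation)
    d0 = []
    sat = set()
    for idx, ((i, j), c) in enumerate(zip(pairs, counts)):
        try:
            d0.append(max(_tn93_closed_form(c, pi), 1e-9))
        except FloatingPointError as exc:
            d0.append(1.0)
            sat.add(idx)
            flagged.append((aln.taxa[i], aln.taxa[j], str(exc)))
    theta0 = np.concatenate([[0.5, 0.5], np.log(d0)])
    res = minimize(_composite_nll, theta0, args=(counts, pi),
                   method="L-BFGS-B", options={"gtol": gtol, "maxiter": 2000})
    ds = np.exp(res.x[2:])
    for idx, (i, j) in enumerate(pairs):
        d[i, j] = d[j, i] = np.inf if idx in sat else ds[idx]
    # identical sequences: zero exactly
    for idx, ((i, j), c) in enumerate(zip(pairs, counts)):
        if c.sum() == np.trace(c):
            d[i, j] = d[j, i] = 0.0
    return DistanceMatrix(aln.taxa, d, pairwise_usable_sites(aln), flagged)


# ---------------------------------------------------------------------------
# neighbor joining


def nj_tree(dm: DistanceMatrix) -> TreeNode:
    """Saitou-Nei neighbor joining.

    Ties in the Q criterion break toward the lowest (i, j) index pair in
    the current node order; negative branch lengths are clamped to zero
    with the deficit moved to the sister branch, so all branch lengths
    are nonnegative. Returns an unrooted tree (trifurcating root).
    """
    n = len(dm.taxa)
    if n < 3:
        raise ValueError("need at least three taxa")
    if not np.allclose(dm.d, dm.d.T):
        raise ValueError("distance matrix not symmetric")
    D = dm.d.astype(float).copy()
    nodes = [TreeNode(name=t) for t in dm.taxa]
    active = list(range(n))

    while len(active) > 2:
        m = len(active)
        sub = D[np.ix_(active, active)]
        r = sub.sum(axis=1)
        best = None
        for a in range(m):
            for b in range(a + 1, m):
                qv = (m - 2) * sub[a, b] - r[a] - r[b]
                if best is None or qv < best[0] - 1e-12:
                    best = (qv, a, b)
        _, a, b = best
        ia, ib = active[a], active[b]
        dab = sub[a, b]
        la = 0.5 * dab + (r[a] - r[b]) / (2 * (m - 2))
        lb = dab - la
        # clamp negatives, moving the deficit to the sister branch
        if la < 0:
            lb += la
            la = 0.0
        if lb < 0:
            la += lb
            lb = 0.0
        la, lb = max(la, 0.0), max(lb, 0.0)
        parent = TreeNode()
        ca, cb = nodes[ia], nodes[ib]
        ca.length = float(la)
        cb.length = float(lb)
        parent.extend([ca, cb])
        # distances from the new node
        new_row = np.zeros(D.shape[0] + 1)
        for c in range(m):
            if c in (a, b):
                continue
            ic = active[c]
            new_row[ic] = 0.5 * (sub[a, c] + sub[b, c] - dab)
        D = np.pad(D, ((0, 1), (0, 1)))
        D[-1, :-1] = new_row[:-1]
        D[:-1, -1] = new_row[:-1]
        nodes.append(parent)
        active = [x for x in active if x not in (ia, ib)] + [len(nodes) - 1]

    ia, ib = active
    la = float(max(D[ia, ib], 0.0))
    ra, rb = nodes[ia], nodes[ib]
    if not ra.is_tip() and len(ra.children) == 2:
        root = ra
        rb.length = la
        root.append(rb)
    elif not rb.is_tip() and len(rb.children) == 2:
        root = rb
        ra.length = la
        root.append(ra)
    else:
        root = TreeNode()
        ra.length = la / 2
        rb.length = la / 2
        root.extend([ra, rb])
    return root


def root_with_outgroup(tree: TreeNode, outgroup: str) -> TreeNode:
    """Root a tree at the midpoint of the outgroup's pendant branch."""
    tips = {t.name for t in tree.tips()}
    if outgroup not in tips:
        raise ValueError(f"outgroup {outgroup!r} is not a leaf of the tree")
    work = tree.copy()
    tip = next(t for t in work.tips() if t.name == outgroup)
    if tip.parent is work and len(work.children) == 2:
        return work  # already rooted on this pendant branch
    length = tip.length if tip.length is not None else 0.0
    # place a new node at the midpoint of the outgroup branch, then root there
    parent = tip.parent
    mid = TreeNode(length=length / 2)
    parent.remove(tip)
    tip.length = length / 2
    mid.append(tip)
    parent.append(mid)
    rooted = work.root_at(mid)
    # root_at leaves the old root as a degree-2 pass-through; collapse it
    for node in list(rooted.non_tips()):
        if len(node.children) == 1 and node.parent is not None:
            child = node.children[0]
            child.length = (child.length or 0.0) + (node.length or 0.0)
            node.parent.append(child)
            node.parent.remove(node)
    return rooted


def path_distance_matrix(tree: TreeNode, taxa: list[str]) -> np.ndarray:
    """Leaf-to-leaf path-length matrix in the given taxon order."""
    big = tree.tip_tip_distances()
    idx = [list(big.ids).index(t) for t in taxa]
    return np.asarray(big.data)[np.ix_(idx, idx)]


def topology_splits(tree: TreeNode) -> set[frozenset]:
    """Non-trivial splits (as frozensets of one side's tips) of an
    unrooted topology."""
    all_tips = frozenset(t.name for t in tree.tips())
    splits = set()
    for node in tree.non_tips(include_self=False):
        side = frozenset(t.name for t in node.tips())
        if 1 < len(side) < len(all_tips) - 1:
            splits.add(min(side, all_tips - side, key=sorted))
    return splits


def same_topology(t1: TreeNode, t2: TreeNode) -> bool:
    return topology_splits(t1) == topology_splits(t2)
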