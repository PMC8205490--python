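"""Neighbor-joining haplotype trees with outgroup rooting and bootstrap.

The workflow mirrors a standard marker-gene haplotype analysis: a gap-free
pre-aligned FASTA of ingroup accessions plus one outgroup sequence is
turned into a p-distance matrix (pairwise deletion of gaps/ambiguities),
a neighbor-joining tree is built with the Studier-Keppler Q criterion,
rooted on the midpoint of the outgroup's pendant edge, and internal edges
are assigned bootstrap supports from column-resampled replicates.  The
ingroup is then cut into ``k`` clades and each clade is scored for
chemotype purity.

Determinism: taxa are processed in lexicographic label order and Q-matrix
ties are broken by the smallest (i, j) index pair, so identical inputs
yield identical trees.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
from Bio import SeqIO
from skbio import DistanceMatrix
from skbio.tree import TreeNode

VALID_CHARS = set("ACGTN-")


@dataclass
class Alignment:
    """Equal-length aligned sequences keyed by accession id, plus outgroup id."""

    sequences: dict[str, str]
    outgroup_id: str

    def __post_init__(self) -> None:
        if not self.sequences:
            raise ValueError("alignment is empty")
        lengths = {len(s) for s in self.sequences.values()}
        if len(lengths) != 1:
            raise ValueError(f"sequences have unequal lengths: {sorted(lengths)}")
        if self.outgroup_id not in self.sequences:
            raise ValueError(f"outgroup {self.outgroup_id!r} not in alignment")
        for name, seq in self.sequences.items():
            bad = set(seq.upper()) - VALID_CHARS
            if bad:
                raise ValueError(f"sequence {name!r} has invalid characters {bad}")

    @property
    def length(self) -> int:
        return len(next(iter(self.sequences.values())))

    @property
    def ids(self) -> list[str]:
        return list(self.sequences)

    @classmethod
    def read_fasta(cls, path: str | Path, outgroup_id: str) -> "Alignment":
        records = {r.id: str(r.seq).upper() for r in SeqIO.parse(str(path), "fasta")}
        return cls(records, outgroup_id)

    def write_fasta(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for name, seq in self.sequences.items():
                fh.write(f">{name}\n{seq}\n")


def _encode(aln: Alignment, ids: list[str]) -> tuple[np.ndarray, np.ndarray]:
    """Integer-encode sequences; returns (codes, validity mask) arrays."""
    lut = np.full(256, -1, dtype=np.int8)
    for i, base in enumerate("ACGT"):
        lut[ord(base)] = i
    mat = np.frombuffer(
        "".join(aln.sequences[i].upper() for i in ids).encode(), dtype=np.uint8
    ).reshape(len(ids), aln.length)
    codes = lut[mat]
    return codes, codes >= 0


def p_distance_matrix(aln: Alignment, ids: list[str] | None = None) -> DistanceMatrix:
    """Proportion of mismatched sites with pairwise deletion.

    Only sites where both sequences carry an unambiguous A/C/G/T are
    compared; a pair with zero comparable sites raises an error naming it.
    """
    ids = sorted(aln.ids) if ids is None else list(ids)
    if len(ids) < 3:
        raise ValueError("need at least 3 sequences for a distance matrix")
    codes, valid = _encode(aln, ids)
    n = len(ids)
    validf = valid.astype(float)
    comparable = validf @ validf.T
    matches = np.zeros((n, n))
    for b in range(4):
        ind = ((codes == b) & valid).astype(float)
        matches += ind @ ind.T
    off = ~np.eye(n, dtype=bool)
    if (comparable[off] == 0).any():
        i, j = np.argwhere((comparable == 0) & off)[0]
        raise ValueError(
            f"no comparable sites between {ids[i]!r} and {ids[j]!r}"
        )
    with np.errstate(invalid="ignore"):
        d = 1.0 - matches / comparable
    np.fill_diagonal(d, 0.0)
    d = (d + d.T) / 2.0  # exact symmetry against float jitter
    return DistanceMatrix(d, ids)


def neighbor_joining(dm: DistanceMatrix) -> TreeNode:
    """Saitou-Nei neighbor joining with the Studier-Keppler Q criterion.

    Returns an unrooted tree represented with a trifurcating root.  Ties in
    the Q matrix are broken by the smallest (i, j) pair after lexicographic
    ordering of the labels.  Negative branch lengths are clamped to zero
    with the deficit transferred to the sibling edge, preserving the joined
    pair's summed length.
    """
    ids = list(dm.ids)
    if len(ids) < 3:
        raise ValueError("neighbor joining needs at least 3 taxa")
    order = sorted(range(len(ids)), key=lambda i: ids[i])
    labels = [ids[i] for i in order]
    D = dm.data[np.ix_(order, order)].copy()
    if not np.allclose(D, D.T):
        raise ValueError("distance matrix must be symmetric")
    nodes: list[TreeNode] = [TreeNode(name=label) for label in labels]

    while len(nodes) > 3:
        m = len(nodes)
        r = D.sum(axis=1)
        Q = (m - 2) * D - r[:, None] - r[None, :]
        np.fill_diagonal(Q, np.inf)
        iu = np.triu_indices(m, k=1)
        flat = np.argmin(Q[iu])  # first occurrence = smallest (i, j)
        i, j = iu[0][flat], iu[1][flat]
        dij = D[i, j]
        vi = 0.5 * dij + (r[i] - r[j]) / (2 * (m - 2))
        vj = dij - vi
        if vi < 0:
            vi, vj = 0.0, dij
        elif vj < 0:
            vi, vj = dij, 0.0
        parent = TreeNode()
        nodes[i].length = float(vi)
        nodes[j].length = float(vj)
        parent.extend([nodes[i], nodes[j]])
        du = 0.5 * (D[i, :] + D[j, :] - dij)
        keep = [k for k in range(m) if k not in (i, j)]
        newD = np.zeros((m - 1, m - 1))
        newD[:-1, :-1] = D[np.ix_(keep, keep)]
        newD[-1, :-1] = du[keep]
        newD[:-1, -1] = du[keep]
        nodes = [nodes[k] for k in keep] + [parent]
        D = newD

    # resolve the final three nodes around an unrooted center
    (a, b, c) = nodes
    dab, dac, dbc = D[0, 1], D[0, 2], D[1, 2]
    a.length = max(0.0, float((dab + dac - dbc) / 2))
    b.length = max(0.0, float((dab + dbc - dac) / 2))
    c.length = max(0.0, float((dac + dbc - dab) / 2))
    root = TreeNode()
    root.extend([a, b, c])
    return root


def root_by_outgroup(tree: TreeNode, outgroup_id: str) -> TreeNode:
    """Root on the midpoint of the outgroup's pendant edge.

    Accepts either the unrooted NJ tree or an already-rooted tree (the
    operation is idempotent: a binary root is dissolved before re-rooting).
    The ingroup topology and all tip-to-tip path lengths are preserved.
    """
    work = tree.copy()
    if len(work.children) == 2:
        work.unroot()
    try:
        tip = work.find(outgroup_id)
    except Exception as exc:  # skbio MissingNodeError
        raise ValueError(f"outgroup {outgroup_id!r} not found in tree") from exc
    if not tip.is_tip():
        raise ValueError(f"outgroup {outgroup_id!r} is not a tip")
    rooted = work.root_at(tip, above=True, branch_attrs=["support"])
    rooted.length = None
    return rooted


def _bipartitions(tree: TreeNode, anchor: str) -> set[frozenset[str]]:
    """Non-trivial bipartitions as the tip set on the side away from ``anchor``."""
    all_tips = frozenset(t.name for t in tree.tips())
    out: set[frozenset[str]] = set()
    for node in tree.non_tips(include_self=False):
        side = frozenset(t.name for t in node.tips())
        if anchor in side:
            side = all_tips - side
        if 2 <= len(side) <= len(all_tips) - 2:
            out.add(side)
    return out


def bootstrap_support(
    aln: Alignment,
    tree: TreeNode | None = None,
    n_reps: int = 100,
    seed: int | None = 0,
) -> TreeNode:
    """Column-resampling bootstrap supports for the NJ tree of ``aln``.

    Resamples alignment columns with replacement ``n_reps`` times, rebuilds
    the NJ tree each time and scores every internal edge of the original
    tree by the fraction of replicates containing the same bipartition.
    Returns a copy of ``tree`` (the rooted NJ tree of the full alignment if
    not given) with ``support`` set on internal nodes.
    """
    if n_reps <= 0:
        raise ValueError("n_reps must be a positive count")
    ids = sorted(aln.ids)
    anchor = ids[0]
    if tree is None:
        tree = root_by_outgroup(neighbor_joining(p_distance_matrix(aln)), aln.outgroup_id)
    result = tree.copy()
    rng = np.random.default_rng(seed)
    counts: dict[frozenset[str], int] = {}
    L = aln.length
    seq_mat = np.array([list(aln.sequences[i]) for i in ids])
    for _ in range(n_reps):
        cols = rng.integers(0, L, size=L)
        resampled = Alignment(
            {i: "".join(row) for i, row in zip(ids, seq_mat[:, cols])},
            aln.outgroup_id,
        )
        rep_tree = neighbor_joining(p_distance_matrix(resampled))
        for bp in _bipartitions(rep_tree, anchor):
            counts[bp] = counts.get(bp, 0) + 1
    all_tips = frozenset(t.name for t in result.tips())
    for node in result.non_tips(include_self=False):
        side = frozenset(t.name for t in node.tips())
        if anchor in side:
            side = all_tips - side
        if 2 <= len(side) <= len(all_tips) - 2:
            node.support = counts.get(side, 0) / n_reps
        else:
            node.support = 1.0  # trivial (pendant-adjacent) split
    return result


def write_newick(tree: TreeNode, path: str | Path) -> None:
    """Write newick; bootstrap supports become internal node labels
    (scikit-bio serializes the ``support`` attribute natively)."""
    tree.write(str(path))


def read_newick(path: str | Path) -> TreeNode:
    """Read newick, interpreting numeric internal labels as supports."""
    tree = TreeNode.read(str(path))
    for node in tree.non_tips(include_self=True):
        if node.name is not None:
            try:
                node.support = float(node.name)
            except ValueError:
                pass
    return tree


def cut_clades(
    tree: TreeNode, k: int, outgroup_id: str | None = None
) -> dict[str, int]:
    """Cut the rooted ingroup into ``k`` clades; returns tip -> clade label.

    Edges are cut greedily in order of decreasing branch length (ties by
    preorder traversal position); a cut that does not separate a new
    tip-bearing component is skipped.  Long edges separate the deeply
    diverged haplotype groups first, so for clade-structured data the first
    ``k - 1`` effective cuts recover the haplotype clades.  Labels are
    1..k in preorder of each clade's first tip.
    """
    tips = [t for t in tree.tips() if t.name != outgroup_id]
    n = len(tips)
    if not (1 <= k <= n):
        raise ValueError(f"k={k} out of range for {n} ingroup tips")
    if outgroup_id is not None:
        names = {t.name for t in tree.tips()}
        if outgroup_id not in names:
            raise ValueError(f"outgroup {outgroup_id!r} not in tree")

    # restrict to the ingroup: nodes with at least one ingroup tip below
    ingroup_names = {t.name for t in tips}

    preorder = list(tree.preorder(include_self=True))
    index = {id(node): i for i, node in enumerate(preorder)}

    candidates = [
        node
        for node in preorder
        if node.parent is not None
        and any(t.name in ingroup_names for t in node.tips(include_self=True))
        and node.name != outgroup_id
    ]
    candidates.sort(key=lambda nd: (-(nd.length or 0.0), index[id(nd)]))

    cut: set[int] = set()

    def component(tip: TreeNode) -> int:
        node = tip
        while node.parent is not None:
            if id(node) in cut:
                return index[id(node)]
            node = node.parent
        return index[id(node)]

    def n_components() -> int:
        return len({component(t) for t in tips})

    for node in candidates:
        if n_components() >= k:
            break
        before = n_components()
        cut.add(id(node))
        if n_components() == before:  # cut separated no new tip-bearing part
            cut.discard(id(node))
    if n_components() < k:
        raise ValueError(f"could not cut tree into {k} tip-bearing clades")

    comp_of_tip = {t.name: component(t) for t in tips}
    # deterministic labels: order components by the preorder index of their
    # first tip
    first_tip_index: dict[int, int] = {}
    for t in tips:
        c = comp_of_tip[t.name]
        first_tip_index.setdefault(c, index[id(t)])
    ordered = sorted(first_tip_index, key=lambda c: first_tip_index[c])
    relabel = {c: i + 1 for i, c in enumerate(ordered)}
    return {name: relabel[c] for name, c in comp_of_tip.items()}


def clade_chemotype_concordance(
    clades: Mapping[str, int],
    labels: Mapping[str, str] | pd.Series,
) -> tuple[pd.DataFrame, float]:
    """Per-clade label purity and the size-weighted overall purity.

    ``purity(clade)`` is the frequency of the most common label within the
    clade; overall purity weights clades by size.  Accessions present in
    only one of the two mappings are ignored; fully disjoint id sets raise.
    """
    if isinstance(labels, pd.Series):
        labels = labels.to_dict()
    shared = sorted(set(clades) & set(labels))
    if not shared:
        raise ValueError("clade and chemotype labels share no accessions")
    frame = pd.DataFrame(
        {"clade": [clades[a] for a in shared], "label": [labels[a] for a in shared]}
    )
    rows = []
    total_weighted = 0.0
    for clade, sub in frame.groupby("clade", sort=True):
        counts = sub["label"].value_counts()
        purity = counts.iloc[0] / len(sub)
        rows.append(
            {
                "clade": clade,
                "n": len(sub),
                "majority_label": counts.index[0],
                "purity": purity,
            }
        )
        total_weighted += len(sub) * purity
    per_clade = pd.DataFrame(rows)
    overall = total_weighted / len(frame)
    return per_clade, float(overall)
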