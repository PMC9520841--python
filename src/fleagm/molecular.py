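"""cox1 barcoding utilities: haplotypes, Kimura-2-parameter distances and trees.

The molecular identification route works on partial cox1 amplicons
(550-650 bp, protein-coding, no indels expected): sequences are
dereplicated into haplotypes by exact identity over their common overlap,
matched against a reference haplotype panel, and related by
Kimura-2-parameter (K2P) distances.  Trees are built by Saitou-Nei
neighbor joining and refined under the minimum-evolution criterion
(ordinary-least-squares branch lengths, nearest-neighbor-interchange
search); bootstrap supports come from column resampling.

Alignment is by simple end-trimming only: sequences are assumed to share
their 5' start, and length differences beyond 60 bases raise an error.
Sites containing gaps, N or IUPAC ambiguity codes are deleted pairwise
(per sequence pair), the MEGA default.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import dendropy
import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioSeqRecord
from scipy.optimize import brentq

__all__ = [
    "SequenceRecord",
    "Haplotype",
    "HaplotypeTable",
    "DistanceMatrixK2P",
    "K2PSaturationError",
    "HaplotypeIntegrityError",
    "AmbiguousReferenceError",
    "read_fasta",
    "write_fasta",
    "collapse_haplotypes",
    "match_reference",
    "k2p_distance",
    "k2p_inverse",
    "k2p_matrix",
    "max_intragroup_distance",
    "nj_tree",
    "me_refine",
    "tree_length",
    "bootstrap_support",
    "write_newick",
    "read_newick",
]

logger = logging.getLogger(__name__)

_IUPAC = set("ACGTURYSWKMBDHVN-")
_CODE = {"A": 0, "C": 1, "G": 2, "T": 3}
MIN_OVERLAP = 400
MAX_LENGTH_DIFF = 60


class K2PSaturationError(ValueError):
    """Raised when observed divergence exceeds the K2P formula's domain."""


class HaplotypeIntegrityError(ValueError):
    """Raised when sequences of different species collapse into one haplotype."""


class AmbiguousReferenceError(ValueError):
    """Raised when a haplotype matches more than one reference panel entry."""


@dataclass
class SequenceRecord:
    """One cox1 amplicon with its species assignment (uppercased on ingest)."""

    seq_id: str
    sequence: str
    species: str = "unknown"

    def __post_init__(self) -> None:
        self.sequence = self.sequence.upper().replace("U", "T")
        if not self.sequence:
            raise ValueError(f"sequence {self.seq_id!r} is empty")
        bad = set(self.sequence) - _IUPAC
        if bad:
            pos = next(i for i, c in enumerate(self.sequence) if c in bad)
            raise ValueError(
                f"sequence {self.seq_id!r}: illegal character {self.sequence[pos]!r} at position {pos}"
            )


@dataclass
class Haplotype:
    haplotype_id: str
    sequence: str  # representative (longest member)
    members: list[str]
    count: int
    species: str
    matched_reference_id: str | None = None


@dataclass
class HaplotypeTable:
    haplotypes: list[Haplotype]

    @property
    def n_sequences(self) -> int:
        return sum(h.count for h in self.haplotypes)

    def __len__(self) -> int:
        return len(self.haplotypes)

    def write_tsv(self, path: str | Path) -> None:
        lines = ["haplotype_id\tcount\tspecies\tmatched_reference_id\tmembers"]
        for h in self.haplotypes:
            ref = h.matched_reference_id or "novel"
            lines.append(
                f"{h.haplotype_id}\t{h.count}\t{h.species}\t{ref}\t{','.join(h.members)}"
            )
        Path(path).write_text("\n".join(lines) + "\n")


@dataclass
class DistanceMatrixK2P:
    """Symmetric K2P distance matrix; entries where the estimate is undefined are flagged."""

    ids: list[str]
    matrix: np.ndarray  # (n, n); NaN where flagged
    defined: np.ndarray = field(default=None)  # (n, n) bool

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.defined is None:
            self.defined = ~np.isnan(self.matrix)

    def write_tsv(self, path: str | Path) -> None:
        lines = ["\t" + "\t".join(self.ids)]
        for i, tid in enumerate(self.ids):
            row = "\t".join(
                f"{self.matrix[i, j]:.6g}" if self.defined[i, j] else "NA"
                for j in range(len(self.ids))
            )
            lines.append(f"{tid}\t{row}")
        Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path: str | Path) -> list[SequenceRecord]:
    """Read FASTA; headers ``id [species=...]`` carry the species tag."""
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        species = "unknown"
        if "[species=" in rec.description:
            species = rec.description.split("[species=", 1)[1].split("]", 1)[0]
        records.append(SequenceRecord(seq_id=rec.id, sequence=str(rec.seq), species=species))
    if not records:
        logger.warning("no sequences found in %s", path)
    return records


def write_fasta(records: Sequence[SequenceRecord], path: str | Path) -> None:
    bio = []
    for r in records:
        desc = f"[species={r.species}]" if r.species != "unknown" else ""
        bio.append(_BioSeqRecord(Seq(r.sequence), id=r.seq_id, description=desc))
    SeqIO.write(bio, str(path), "fasta")


# ---------------------------------------------------------------------------
# haplotypes


def _same_haplotype(a: str, b: str, mode: str) -> bool:
    if mode == "full_length":
        return a == b
    short, long_ = (a, b) if len(a) <= len(b) else (b, a)
    if len(short) < MIN_OVERLAP:
        return False
    return short in long_


def collapse_haplotypes(
    records: Sequence[SequenceRecord], mode: str = "full_length"
) -> HaplotypeTable:
    """Dereplicate sequences into haplotypes by exact identity.

    ``full_length`` requires identical strings; ``common_overlap`` treats a
    sequence as identical to a longer one when it occurs within it (simple
    end-trimming, overlap >= 400 positions).  Haplotype ids H1, H2, ... are
    assigned in decreasing count order, ties by first appearance.  A
    haplotype whose members span more than one (known) species raises
    :class:`HaplotypeIntegrityError`.
    """
    if mode not in ("full_length", "common_overlap"):
        raise ValueError(f"unknown mode {mode!r}")
    if not records:
        raise ValueError("no sequences to collapse")
    clusters: list[dict] = []  # {"rep": str, "members": [SequenceRecord], "first": int}
    for pos, rec in enumerate(records):
        for cl in clusters:
            if _same_haplotype(rec.sequence, cl["rep"], mode):
                cl["members"].append(rec)
                if len(rec.sequence) > len(cl["rep"]):
                    cl["rep"] = rec.sequence
                break
        else:
            clusters.append({"rep": rec.sequence, "members": [rec], "first": pos})
    clusters.sort(key=lambda c: (-len(c["members"]), c["first"]))
    haps = []
    for i, cl in enumerate(clusters, start=1):
        species = sorted({m.species for m in cl["members"]} - {"unknown"})
        if len(species) > 1:
            ids = ", ".join(m.seq_id for m in cl["members"])
            raise HaplotypeIntegrityError(
                f"haplotype mixes species {species}: members {ids}"
            )
        haps.append(
            Haplotype(
                haplotype_id=f"H{i}",
                sequence=cl["rep"],
                members=[m.seq_id for m in cl["members"]],
                count=len(cl["members"]),
                species=species[0] if species else "unknown",
            )
        )
    return HaplotypeTable(haplotypes=haps)


def match_reference(
    haps: HaplotypeTable, panel: Sequence[SequenceRecord]
) -> HaplotypeTable:
    """Assign each haplotype the reference-panel haplotype it is identical to.

    A haplotype matches a panel entry iff the two sequences are identical
    over their common overlap (one contained in the other, >= 400
    positions).  No match leaves the haplotype novel; an overlap shorter
    than 400 is a no-call with a warning; several distinct matching panel
    entries raise :class:`AmbiguousReferenceError`.
    """
    if not panel:
        raise ValueError("reference panel is empty")
    out = []
    for h in haps.haplotypes:
        candidates = []
        short_overlap = False
        for ref in panel:
            if min(len(ref.sequence), len(h.sequence)) < MIN_OVERLAP:
                short, long_ = sorted((h.sequence, ref.sequence), key=len)
                if short in long_:
                    short_overlap = True
                continue
            if _same_haplotype(h.sequence, ref.sequence, "common_overlap"):
                candidates.append(ref.seq_id)
        if len(candidates) > 1:
            raise AmbiguousReferenceError(
                f"haplotype {h.haplotype_id} matches several panel entries: {candidates}"
            )
        if short_overlap and not candidates:
            logger.warning(
                "haplotype %s: overlap with panel < %d positions, no call",
                h.haplotype_id,
                MIN_OVERLAP,
            )
        out.append(
            Haplotype(
                haplotype_id=h.haplotype_id,
                sequence=h.sequence,
                members=list(h.members),
                count=h.count,
                species=h.species,
                matched_reference_id=candidates[0] if candidates else None,
            )
        )
    return HaplotypeTable(haplotypes=out)


# ---------------------------------------------------------------------------
# K2P distances


def _encode(seq: str) -> np.ndarray:
    return np.fromiter((_CODE.get(c, 4) for c in seq), dtype=np.int8, count=len(seq))


def _trim_pair(a: str, b: str) -> tuple[str, str]:
    if abs(len(a) - len(b)) > MAX_LENGTH_DIFF:
        raise ValueError(
            f"sequence lengths differ by {abs(len(a) - len(b))} > {MAX_LENGTH_DIFF}; "
            "sequences are not alignable by end-trimming"
        )
    m = min(len(a), len(b))
    return a[:m], b[:m]


def k2p_from_counts(n_ts: float, n_tv: float, n_sites: float) -> float:
    """K2P distance from transition/transversion counts over retained sites."""
    if n_sites < 1:
        raise ValueError("no comparable sites after site deletion")
    P = n_ts / n_sites
    Q = n_tv / n_sites
    w1 = 1.0 - 2.0 * P - Q
    w2 = 1.0 - 2.0 * Q
    if w1 <= 0.0 or w2 <= 0.0:
        raise K2PSaturationError(
            f"divergence saturated (P={P:.3f}, Q={Q:.3f}); K2P distance undefined"
        )
    return -0.5 * math.log(w1) - 0.25 * math.log(w2)


def k2p_distance(a: str | SequenceRecord, b: str | SequenceRecord) -> float:
    """Kimura-2-parameter distance between two sequences (substitutions/site).

    Sites where either sequence has a gap, N or ambiguity code are deleted
    pairwise; with transition proportion P and transversion proportion Q
    over the retained sites, ``d = -1/2 ln(1 - 2P - Q) - 1/4 ln(1 - 2Q)``.
    """
    sa = a.sequence if isinstance(a, SequenceRecord) else a.upper()
    sb = b.sequence if isinstance(b, SequenceRecord) else b.upper()
    sa, sb = _trim_pair(sa, sb)
    ca, cb = _encode(sa), _encode(sb)
    valid = (ca < 4) & (cb < 4)
    n_sites = int(valid.sum())
    diff = valid & (ca != cb)
    ts = diff & (np.abs(ca - cb) == 2)  # A<->G (0,2) and C<->T (1,3)
    return k2p_from_counts(int(ts.sum()), int(diff.sum() - ts.sum()), n_sites)


def k2p_inverse(d: float, ts_tv_ratio: float = 2.0) -> tuple[float, float]:
    """Invert the K2P formula: (P, Q) site proportions giving distance ``d``.

    The transition/transversion proportion ratio P/Q is held at
    ``ts_tv_ratio``.  Used to plant exact substitution counts when
    simulating sequences at a target divergence.
    """
    if d <= 0:
        return 0.0, 0.0
    R = ts_tv_ratio

    def f(q: float) -> float:
        return -0.5 * math.log(1.0 - 2.0 * R * q - q) - 0.25 * math.log(1.0 - 2.0 * q) - d

    q_max = min(0.5, 1.0 / (2.0 * R + 1.0)) - 1e-12
    q = brentq(f, 1e-15, q_max)
    return R * q, q


def k2p_matrix(records: Sequence[SequenceRecord]) -> DistanceMatrixK2P:
    """All-pairs K2P distances; saturated pairs are flagged (NaN), not fatal."""
    n = len(records)
    M = np.zeros((n, n))
    defined = np.ones((n, n), dtype=bool)
    for i in range(n):
        for j in range(i + 1, n):
            try:
                d = k2p_distance(records[i], records[j])
            except K2PSaturationError:
                d = math.nan
                defined[i, j] = defined[j, i] = False
            M[i, j] = M[j, i] = d
    return DistanceMatrixK2P(
        ids=[r.seq_id for r in records], matrix=M, defined=defined
    )


def max_intragroup_distance(
    matrix: DistanceMatrixK2P, labels: Sequence[str]
) -> dict[str, float | None]:
    """Maximum within-species pairwise distance; None for single-member groups."""
    labels = list(labels)
    if len(labels) != len(matrix.ids):
        raise ValueError("one species label per taxon required")
    out: dict[str, float | None] = {}
    for sp in dict.fromkeys(labels):
        idx = [i for i, lab in enumerate(labels) if lab == sp]
        if len(idx) < 2:
            out[sp] = None
            continue
        sub = matrix.matrix[np.ix_(idx, idx)]
        out[sp] = float(np.nanmax(sub))
    return out


# ---------------------------------------------------------------------------
# trees: internal unrooted representation


class _UTree:
    """Unrooted tree: integer nodes, adjacency with branch lengths, labelled leaves."""

    def __init__(self) -> None:
        self.adj: dict[int, dict[int, float]] = {}
        self.leaf_label: dict[int, str] = {}
        self._next = 0

    def new_node(self, label: str | None = None) -> int:
        u = self._next
        self._next += 1
        self.adj[u] = {}
        if label is not None:
            self.leaf_label[u] = label
        return u

    def connect(self, u: int, v: int, length: float) -> None:
        self.adj[u][v] = length
        self.adj[v][u] = length

    def disconnect(self, u: int, v: int) -> None:
        del self.adj[u][v]
        del self.adj[v][u]

    def edges(self) -> list[tuple[int, int]]:
        return [(u, v) for u in sorted(self.adj) for v in self.adj[u] if u < v]

    def internal_edges(self) -> list[tuple[int, int]]:
        return [
            (u, v)
            for u, v in self.edges()
            if u not in self.leaf_label and v not in self.leaf_label
        ]

    def leaves(self) -> list[int]:
        return sorted(self.leaf_label)

    def leaf_paths(self) -> dict[int, set[tuple[int, int]]]:
        """Edge set on the path from each leaf to an arbitrary reference node."""
        root = next(u for u in self.adj if u not in self.leaf_label) if len(
            self.adj
        ) > 2 else min(self.adj)
        paths: dict[int, set[tuple[int, int]]] = {}
        stack = [(root, None, set())]
        while stack:
            u, parent, acc = stack.pop()
            if u in self.leaf_label:
                paths[u] = acc
            for v in self.adj[u]:
                if v != parent:
                    e = (min(u, v), max(u, v))
                    stack.append((v, u, acc | {e}))
        return paths

    def bipartitions(self) -> set[frozenset[str]]:
        """Leaf-label bipartitions induced by internal edges (canonical side:
        the one NOT containing the alphabetically smallest leaf)."""
        all_labels = set(self.leaf_label.values())
        anchor = min(all_labels)
        out = set()
        for u, v in self.internal_edges():
            side = self._leafset(v, u)
            if anchor in side:
                side = all_labels - side
            if 1 < len(side) < len(all_labels) - 1 or (
                len(side) >= 2 and len(all_labels) - len(side) >= 2
            ):
                out.add(frozenset(side))
        return out

    def _leafset(self, start: int, blocked: int) -> set[str]:
        seen = set()
        stack = [(start, blocked)]
        while stack:
            u, parent = stack.pop()
            if u in self.leaf_label:
                seen.add(self.leaf_label[u])
            for v in self.adj[u]:
                if v != parent:
                    stack.append((v, u))
        return seen


def _utree_to_dendropy(
    tree: _UTree, supports: dict[frozenset[str], int] | None = None
) -> dendropy.Tree:
    tns = dendropy.TaxonNamespace()
    dtree = dendropy.Tree(taxon_namespace=tns)
    all_labels = set(tree.leaf_label.values())
    anchor = min(all_labels)
    root_u = next(
        (u for u in sorted(tree.adj) if u not in tree.leaf_label), min(tree.adj)
    )

    def build(u: int, parent: int | None) -> dendropy.Node:
        node = dendropy.Node()
        if u in tree.leaf_label:
            node.taxon = tns.require_taxon(label=tree.leaf_label[u])
        else:
            if supports is not None and parent is not None:
                side = tree._leafset(u, parent)
                if anchor in side:
                    side = all_labels - side
                key = frozenset(side)
                if key in supports:
                    node.label = str(supports[key])
        for v in sorted(tree.adj[u]):
            if v != parent:
                child = build(v, u)
                child.edge.length = tree.adj[u][v]
                node.add_child(child)
        return node

    dtree.seed_node = build(root_u, None)
    dtree.is_rooted = False
    return dtree


def _dendropy_to_utree(dtree: dendropy.Tree) -> _UTree:
    tree = _UTree()
    mapping: dict[int, int] = {}
    for node in dtree.preorder_node_iter():
        label = node.taxon.label if node.taxon is not None else None
        u = tree.new_node(label)
        mapping[id(node)] = u
        if node.parent_node is not None:
            length = node.edge.length if node.edge.length is not None else 0.0
            tree.connect(mapping[id(node.parent_node)], u, max(0.0, float(length)))
    # suppress a degree-2 root left over from rooted newick representations
    for u in list(tree.adj):
        if u not in tree.leaf_label and len(tree.adj[u]) == 2:
            (a, la), (b, lb) = tree.adj[u].items()
            tree.disconnect(u, a)
            tree.disconnect(u, b)
            tree.connect(a, b, la + lb)
            del tree.adj[u]
    return tree


# ---------------------------------------------------------------------------
# neighbor joining


def _nj_utree(matrix: DistanceMatrixK2P) -> _UTree:
    n = len(matrix.ids)
    if n < 3:
        raise ValueError("neighbor joining needs >= 3 taxa")
    if not matrix.defined.all():
        raise ValueError("distance matrix contains undefined (saturated) entries")
    tree = _UTree()
    nodes = [tree.new_node(label) for label in matrix.ids]
    D: dict[tuple[int, int], float] = {}
    for i in range(n):
        for j in range(i + 1, n):
            D[(nodes[i], nodes[j])] = float(matrix.matrix[i, j])

    def d(u: int, v: int) -> float:
        return D[(u, v)] if (u, v) in D else D[(v, u)]

    active = list(nodes)
    while len(active) > 3:
        r = len(active)
        sums = {u: sum(d(u, v) for v in active if v != u) for u in active}
        best = None
        best_q = math.inf
        for ii in range(r):
            for jj in range(ii + 1, r):
                u, v = active[ii], active[jj]
                q = (r - 2) * d(u, v) - sums[u] - sums[v]
                if q < best_q:  # strict: ties keep the lowest-index pair
                    best_q = q
                    best = (u, v)
        u, v = best
        w = tree.new_node()
        duv = d(u, v)
        lu = 0.5 * duv + (sums[u] - sums[v]) / (2.0 * (r - 2))
        lv = duv - lu
        tree.connect(u, w, max(0.0, lu))
        tree.connect(v, w, max(0.0, lv))
        for x in active:
            if x is u or x is v:
                continue
            D[(w, x)] = 0.5 * (d(u, x) + d(v, x) - duv)
        active = [x for x in active if x is not u and x is not v] + [w]
    # final star join of the remaining three nodes
    a, b, c = active
    center = tree.new_node()
    la = 0.5 * (d(a, b) + d(a, c) - d(b, c))
    lb = 0.5 * (d(a, b) + d(b, c) - d(a, c))
    lc = 0.5 * (d(a, c) + d(b, c) - d(a, b))
    tree.connect(a, center, max(0.0, la))
    tree.connect(b, center, max(0.0, lb))
    tree.connect(c, center, max(0.0, lc))
    return tree


def nj_tree(matrix: DistanceMatrixK2P) -> dendropy.Tree:
    """Saitou-Nei neighbor joining with the Studier-Keppler Q-criterion.

    Ties in Q are broken deterministically toward the lowest taxon index
    pair; negative branch lengths are clamped to zero.  Returns an
    unrooted :class:`dendropy.Tree`.
    """
    return _utree_to_dendropy(_nj_utree(matrix))


# ---------------------------------------------------------------------------
# minimum evolution refinement


_TRIU_CACHE: dict[int, tuple[np.ndarray, np.ndarray]] = {}


def _triu_cache(n: int) -> tuple[np.ndarray, np.ndarray]:
    if n not in _TRIU_CACHE:
        _TRIU_CACHE[n] = np.triu_indices(n, k=1)
    return _TRIU_CACHE[n]


def _ols_lengths(tree: _UTree, matrix: DistanceMatrixK2P) -> float:
    """Re-estimate branch lengths by OLS on leaf-pair path distances.

    Negative solutions are clamped to zero.  Returns the resulting tree
    length (sum of branch lengths).
    """
    label_to_id = {lab: i for i, lab in enumerate(matrix.ids)}
    edges = tree.edges()
    eidx = {e: k for k, e in enumerate(edges)}
    leaves = tree.leaves()
    n_leaves, n_edges = len(leaves), len(edges)
    # boolean edge-incidence vector of each leaf's path to a reference node;
    # a leaf-pair path is the XOR of the two vectors
    root = next((u for u in tree.adj if u not in tree.leaf_label), leaves[0])
    P = np.zeros((n_leaves, n_edges), dtype=bool)
    leaf_row = {u: i for i, u in enumerate(leaves)}
    stack: list[tuple[int, int | None, np.ndarray]] = [
        (root, None, np.zeros(n_edges, dtype=bool))
    ]
    while stack:
        u, parent, acc = stack.pop()
        if u in tree.leaf_label:
            P[leaf_row[u]] = acc
        for v in tree.adj[u]:
            if v != parent:
                nxt = acc.copy()
                nxt[eidx[(min(u, v), max(u, v))]] = True
                stack.append((v, u, nxt))
    ia, ib = _triu_cache(n_leaves)
    A = np.logical_xor(P[ia], P[ib]).astype(float)
    taxa = np.array([label_to_id[tree.leaf_label[u]] for u in leaves])
    dvec = matrix.matrix[taxa[ia], taxa[ib]]
    try:
        x = np.linalg.solve(A.T @ A, A.T @ dvec)
    except np.linalg.LinAlgError:
        x, *_ = np.linalg.lstsq(A, dvec, rcond=None)
    x = np.clip(x, 0.0, None)
    for e, k in eidx.items():
        tree.adj[e[0]][e[1]] = tree.adj[e[1]][e[0]] = float(x[k])
    return float(x.sum())


def _nni_neighbors(tree: _UTree, u: int, v: int) -> list[tuple[int, int]]:
    """The two NNI swaps across internal edge (u, v) as (neighbor_of_u, neighbor_of_v)."""
    nu = sorted(x for x in tree.adj[u] if x != v)
    nv = sorted(x for x in tree.adj[v] if x != u)
    return [(nu[1], nv[0]), (nu[1], nv[1])]


def _apply_nni(tree: _UTree, u: int, v: int, a: int, c: int) -> None:
    """Swap subtree a (attached to u) with subtree c (attached to v)."""
    la = tree.adj[u][a]
    lc = tree.adj[v][c]
    tree.disconnect(u, a)
    tree.disconnect(v, c)
    tree.connect(u, c, lc)
    tree.connect(v, a, la)


def me_refine(
    tree: dendropy.Tree, matrix: DistanceMatrixK2P, *, max_sweeps: int = 200
) -> dendropy.Tree:
    """Minimum-evolution refinement of a tree topology.

    Branch lengths are re-estimated by ordinary least squares; over
    repeated sweeps every internal edge's two nearest-neighbor-interchange
    alternatives are evaluated and a move is accepted only when it strictly
    decreases the OLS tree length.  Terminates at a local optimum.
    """
    ut = _dendropy_to_utree(tree)
    _me_refine_utree(ut, matrix, max_sweeps=max_sweeps)
    return _utree_to_dendropy(ut)


def _me_refine_utree(ut: _UTree, matrix: DistanceMatrixK2P, *, max_sweeps: int = 200) -> float:
    best_len = _ols_lengths(ut, matrix)
    for _ in range(max_sweeps):
        improved = False
        # the edge set changes after an accepted swap, so restart the sweep
        # from a fresh enumeration after every accepted move
        for u, v in ut.internal_edges():
            for a, c in _nni_neighbors(ut, u, v):
                _apply_nni(ut, u, v, a, c)
                cand_len = _ols_lengths(ut, matrix)
                if cand_len < best_len - 1e-12:
                    best_len = cand_len
                    improved = True
                    break
                _apply_nni(ut, u, v, c, a)  # revert
            if improved:
                break
        if not improved:
            break
    return _ols_lengths(ut, matrix)


def tree_length(tree: dendropy.Tree) -> float:
    return float(
        sum(e.length or 0.0 for e in tree.preorder_edge_iter() if e.head_node.parent_node)
    )


# ---------------------------------------------------------------------------
# bootstrap


def _pair_site_classes(records: Sequence[SequenceRecord]) -> tuple[np.ndarray, ...]:
    """Per leaf pair, boolean site masks (valid, transition, transversion)."""
    L = len(records[0].sequence)
    codes = np.stack([_encode(r.sequence) for r in records])
    n = len(records)
    pairs = [(i, j) for i in range(n) for j in range(i + 1, n)]
    valid = np.empty((len(pairs), L), dtype=bool)
    ts = np.empty_like(valid)
    tv = np.empty_like(valid)
    for k, (i, j) in enumerate(pairs):
        ci, cj = codes[i], codes[j]
        v = (ci < 4) & (cj < 4)
        diff = v & (ci != cj)
        t = diff & (np.abs(ci - cj) == 2)
        valid[k] = v
        ts[k] = t
        tv[k] = diff & ~t
    return valid, ts, tv


def _matrix_from_weights(
    valid: np.ndarray, ts: np.ndarray, tv: np.ndarray, w: np.ndarray, ids: list[str]
) -> DistanceMatrixK2P:
    n = len(ids)
    nv = valid @ w
    nts = ts @ w
    ntv = tv @ w
    M = np.zeros((n, n))
    k = 0
    for i in range(n):
        for j in range(i + 1, n):
            M[i, j] = M[j, i] = k2p_from_counts(nts[k], ntv[k], nv[k])
            k += 1
    return DistanceMatrixK2P(ids=ids, matrix=M)


def bootstrap_support(
    records: Sequence[SequenceRecord],
    *,
    n_reps: int = 1000,
    seed: int | None = None,
    refine: bool = True,
) -> dendropy.Tree:
    """Point-estimate ME tree with bootstrap supports on internal edges.

    Alignment columns are resampled with replacement ``n_reps`` times; each
    replicate rebuilds the tree (K2P -> NJ -> ME refinement) and the
    support of an internal bipartition of the point-estimate tree is the
    percentage of successful replicates containing it.  Replicates with
    saturated or undefined distances are skipped and counted.
    """
    if len(records) < 4:
        raise ValueError("bootstrap needs >= 4 taxa")
    lengths = {len(r.sequence) for r in records}
    if len(lengths) != 1:
        raise ValueError("bootstrap requires an equal-length alignment")
    L = lengths.pop()
    ids = [r.seq_id for r in records]
    valid, ts, tv = _pair_site_classes(records)
    ones = np.ones(L)
    point_matrix = _matrix_from_weights(valid, ts, tv, ones, ids)
    point = _nj_utree(point_matrix)
    if refine:
        _me_refine_utree(point, point_matrix)
    target_bips = point.bipartitions()
    counts = {bip: 0 for bip in target_bips}
    rng = np.random.default_rng(seed)
    n_ok = 0
    n_skipped = 0
    for _ in range(n_reps):
        w = np.bincount(rng.integers(0, L, size=L), minlength=L).astype(float)
        try:
            rep_matrix = _matrix_from_weights(valid, ts, tv, w, ids)
        except (K2PSaturationError, ValueError):
            n_skipped += 1
            continue
        rep = _nj_utree(rep_matrix)
        if refine:
            _me_refine_utree(rep, rep_matrix)
        n_ok += 1
        for bip in rep.bipartitions() & target_bips:
            counts[bip] += 1
    if n_skipped:
        logger.warning("%d bootstrap replicates skipped (saturated distances)", n_skipped)
    supports = {
        bip: int(round(100.0 * c / n_ok)) if n_ok else 0 for bip, c in counts.items()
    }
    return _utree_to_dendropy(point, supports=supports)


# ---------------------------------------------------------------------------
# newick I/O


def write_newick(tree: dendropy.Tree, path: str | Path) -> None:
    Path(path).write_text(
        tree.as_string(
            schema="newick",
            suppress_rooting=True,
            unquoted_underscores=True,
        )
    )


def read_newick(path: str | Path) -> dendropy.Tree:
    try:
        return dendropy.Tree.get(
            path=str(path),
            schema="newick",
            preserve_underscores=True,
            suppress_internal_node_taxa=True,
        )
    except Exception as exc:  # dendropy raises assorted error types
        raise ValueError(f"malformed newick in {path}: {exc}") from exc
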