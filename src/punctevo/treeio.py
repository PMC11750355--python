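"""Tree and metadata I/O plus branch-level transforms.

The central container is :class:`LineageTree`, an array-backed rooted
bifurcating tree whose branch lengths are expected nucleotide
substitutions.  Trees are parsed from Newick/NEXUS via dendropy and then
converted to flat parent/length arrays, which makes the numerical work
downstream (covariance assembly, pruning likelihoods, repeated traversals
over 1000-tree posteriors) orders of magnitude faster than object-graph
traversal.

Conventions
-----------
* Tips occupy node indices ``0 .. n_tips-1`` in the order of
  ``tip_labels``; internal nodes follow.
* The root carries no branch; its stored length is 0.
* ``DE`` (diversification events on a root-to-tip path) counts internal
  nodes on the path *including the root and excluding the tip*, i.e. the
  number of edges on the path.  Every tip of a two-tip tree has DE = 1.
  An alternative convention excluding the root would shift DE by a
  constant and change only the regression intercept, never the slope.
"""

from __future__ import annotations

import io
from dataclasses import dataclass
from typing import Iterable, Iterator, Mapping, Sequence

import dendropy
import numpy as np
import pandas as pd

from .errors import (
    ConsistencyError,
    DegenerateDataError,
    MetadataError,
    ParameterError,
    TreeFormatError,
    TreeStructureError,
)

__all__ = [
    "LineageTree",
    "PosteriorTreeSet",
    "read_trees",
    "write_trees",
    "scale_to_mean_branch_length",
    "kappa_transform",
    "prune_to_tips",
    "path_table",
    "read_metadata",
    "write_metadata",
    "assemble_alignment",
    "TARGET_SITE_LENGTH",
    "BARCODE_PREFIX_LENGTH",
    "TRIMMED_SITE_LENGTH",
]

#: Raw length of one CRISPR target site (bp).
TARGET_SITE_LENGTH = 296
#: 14-bp integration barcode plus the 20 bp preceding it.
BARCODE_PREFIX_LENGTH = 34
#: Length of a target site after stripping the barcode prefix.
TRIMMED_SITE_LENGTH = TARGET_SITE_LENGTH - BARCODE_PREFIX_LENGTH  # 262


class LineageTree:
    """Rooted bifurcating tree with branch lengths, backed by flat arrays.

    Parameters
    ----------
    parent
        Integer array of length ``n_nodes``; ``parent[i]`` is the parent
        node index of node ``i`` and ``-1`` for the root.
    length
        Float array of branch lengths (substitutions); ``length[root]``
        is ignored and stored as 0.
    tip_labels
        Cell identifiers for nodes ``0 .. n_tips-1``.
    """

    __slots__ = ("parent", "length", "tip_labels", "_children", "_postorder")

    def __init__(
        self,
        parent: np.ndarray,
        length: np.ndarray,
        tip_labels: Sequence[str],
        validate: bool = True,
    ):
        self.parent = np.asarray(parent, dtype=np.int64)
        self.length = np.asarray(length, dtype=np.float64).copy()
        self.tip_labels: tuple[str, ...] = tuple(str(t) for t in tip_labels)
        self._children: list[list[int]] | None = None
        self._postorder: np.ndarray | None = None
        if validate:
            self.validate()
        if self.parent.size:
            self.length[self.root] = 0.0

    # -- structure ----------------------------------------------------------
    @property
    def n_nodes(self) -> int:
        return int(self.parent.size)

    @property
    def n_tips(self) -> int:
        return len(self.tip_labels)

    @property
    def root(self) -> int:
        roots = np.flatnonzero(self.parent < 0)
        if roots.size != 1:
            raise TreeStructureError(f"tree must have exactly one root, found {roots.size}")
        return int(roots[0])

    def children(self) -> list[list[int]]:
        if self._children is None:
            ch: list[list[int]] = [[] for _ in range(self.n_nodes)]
            for i, p in enumerate(self.parent):
                if p >= 0:
                    ch[p].append(i)
            self._children = ch
        return self._children

    def postorder(self) -> np.ndarray:
        """Node indices, children before parents (iterative DFS)."""
        if self._postorder is None:
            ch = self.children()
            order = np.empty(self.n_nodes, dtype=np.int64)
            stack = [self.root]
            k = self.n_nodes
            while stack:
                v = stack.pop()
                k -= 1
                order[k] = v
                stack.extend(ch[v])
            self._postorder = order
        return self._postorder

    def preorder(self) -> np.ndarray:
        return self.postorder()[::-1]

    def validate(self) -> None:
        n = self.n_nodes
        if self.length.size != n:
            raise TreeStructureError("parent and length arrays differ in size")
        if self.n_tips < 1 or self.n_tips > n:
            raise TreeStructureError("tip count inconsistent with node count")
        if len(set(self.tip_labels)) != self.n_tips:
            raise TreeStructureError("tip labels are not unique")
        if not np.all(np.isfinite(self.length)):
            raise TreeStructureError("branch lengths must be finite")
        root = self.root
        nonroot = np.delete(np.arange(n), root)
        if np.any(self.length[nonroot] < 0):
            raise TreeStructureError("branch lengths must be >= 0")
        ch = self.children()
        for i in range(n):
            deg = len(ch[i])
            if i < self.n_tips:
                if deg != 0:
                    raise TreeStructureError(f"tip node {i} has children")
            elif deg != 2:
                raise TreeStructureError(
                    f"internal node {i} has {deg} children; tree must be bifurcating"
                )
        # reachability (also guards against cycles)
        if self.postorder().size != n:
            raise TreeStructureError("tree graph is not connected")

    # -- numerics -----------------------------------------------------------
    def copy(self) -> "LineageTree":
        t = LineageTree(self.parent, self.length, self.tip_labels, validate=False)
        t._children = self._children
        t._postorder = self._postorder
        return t

    def with_lengths(self, length: np.ndarray) -> "LineageTree":
        t = self.copy()
        t.length = np.asarray(length, dtype=np.float64).copy()
        t.length[self.root] = 0.0
        return t

    def node_depths(self) -> np.ndarray:
        """Distance from the root to every node."""
        depth = np.zeros(self.n_nodes)
        for v in self.preorder():
            p = self.parent[v]
            if p >= 0:
                depth[v] = depth[p] + self.length[v]
        return depth

    def tip_depths(self) -> np.ndarray:
        """Root-to-tip path length (LD) for tips ``0..n_tips-1``."""
        return self.node_depths()[: self.n_tips]

    def tip_path_node_counts(self) -> np.ndarray:
        """Number of edges on each root-to-tip path (the DE count)."""
        cnt = np.zeros(self.n_nodes, dtype=np.int64)
        for v in self.preorder():
            p = self.parent[v]
            if p >= 0:
                cnt[v] = cnt[p] + 1
        return cnt[: self.n_tips]

    @property
    def total_length(self) -> float:
        return float(self.length.sum())

    @property
    def mean_branch_length(self) -> float:
        return self.total_length / (self.n_nodes - 1)

    def subtree_tips(self) -> list[np.ndarray]:
        """Per node: sorted array of descendant tip indices (tips include
        themselves)."""
        out: list[np.ndarray | None] = [None] * self.n_nodes
        ch = self.children()
        for v in self.postorder():
            if v < self.n_tips:
                out[v] = np.array([v], dtype=np.int64)
            else:
                out[v] = np.concatenate([out[c] for c in ch[v]])
        return out  # type: ignore[return-value]

    # -- interchange --------------------------------------------------------
    @classmethod
    def from_dendropy(cls, tree: dendropy.Tree) -> "LineageTree":
        seed = tree.seed_node
        # collapse a unifurcating seed node (root edge remnant)
        while len(seed.child_nodes()) == 1:
            seed = seed.child_nodes()[0]
        leaves = [nd for nd in seed.leaf_iter()]
        labels = []
        for nd in leaves:
            lab = nd.taxon.label if nd.taxon is not None else nd.label
            if lab is None:
                raise TreeFormatError("tip without a label")
            labels.append(lab)
        n_tips = len(labels)
        index: dict[int, int] = {id(nd): i for i, nd in enumerate(leaves)}
        internal = [nd for nd in seed.preorder_iter() if nd is not seed and not nd.is_leaf()]
        nxt = n_tips
        index[id(seed)] = n_tips + len(internal)
        for nd in internal:
            index[id(nd)] = nxt
            nxt += 1
        n = n_tips + len(internal) + 1
        parent = np.full(n, -1, dtype=np.int64)
        length = np.zeros(n)
        for nd in seed.preorder_iter():
            i = index[id(nd)]
            if nd is not seed:
                parent[i] = index[id(nd.parent_node)]
                length[i] = float(nd.edge.length) if nd.edge.length is not None else 0.0
        return cls(parent, length, labels)

    def to_dendropy(
        self, taxon_namespace: dendropy.TaxonNamespace | None = None
    ) -> dendropy.Tree:
        tns = taxon_namespace if taxon_namespace is not None else dendropy.TaxonNamespace()
        tree = dendropy.Tree(taxon_namespace=tns)
        nodes = [dendropy.Node() for _ in range(self.n_nodes)]
        for i, lab in enumerate(self.tip_labels):
            nodes[i].taxon = tns.require_taxon(label=lab)
        for i, p in enumerate(self.parent):
            nodes[i].edge.length = float(self.length[i])
            if p >= 0:
                nodes[p].add_child(nodes[i])
        tree.seed_node = nodes[self.root]
        tree.seed_node.edge.length = None
        tree.is_rooted = True
        return tree

    def to_newick(self) -> str:
        ch = self.children()

        def rec(v: int) -> str:
            if v < self.n_tips:
                body = self.tip_labels[v]
            else:
                body = "(" + ",".join(rec(c) for c in ch[v]) + ")"
            if self.parent[v] < 0:
                return body
            return f"{body}:{self.length[v]:.17g}"

        import sys

        old = sys.getrecursionlimit()
        sys.setrecursionlimit(max(old, 10 * self.n_nodes + 100))
        try:
            return rec(self.root) + ";"
        finally:
            sys.setrecursionlimit(old)

    @classmethod
    def from_newick(cls, newick: str) -> "LineageTree":
        tree = dendropy.Tree.get(
            data=newick, schema="newick", suppress_internal_node_taxa=True
        )
        return cls.from_dendropy(tree)

    def __repr__(self) -> str:  # pragma: no cover
        return f"<LineageTree n_tips={self.n_tips} total_length={self.total_length:.4g}>"


@dataclass
class PosteriorTreeSet:
    """Ordered sample of trees over an identical tip-label set."""

    trees: list[LineageTree]
    lineage_id: str = "lineage"
    source: str | None = None

    def __post_init__(self) -> None:
        if not self.trees:
            raise ConsistencyError("posterior tree set must contain at least one tree")
        ref = set(self.trees[0].tip_labels)
        for k, t in enumerate(self.trees):
            if set(t.tip_labels) != ref:
                raise ConsistencyError(
                    f"tree {k} of '{self.lineage_id}' has a different tip set"
                )

    def __len__(self) -> int:
        return len(self.trees)

    def __iter__(self) -> Iterator[LineageTree]:
        return iter(self.trees)

    def __getitem__(self, i: int) -> LineageTree:
        return self.trees[i]

    @property
    def tip_labels(self) -> tuple[str, ...]:
        return self.trees[0].tip_labels


def _resolve_polytomies(tree: dendropy.Tree) -> None:
    tree.resolve_polytomies(limit=2, update_bipartitions=False)
    for e in tree.preorder_edge_iter():
        if e.length is None:
            e.length = 0.0


def read_trees(
    path: str,
    format: str = "newick",
    lineage_id: str | None = None,
    resolve_polytomies: bool = False,
) -> PosteriorTreeSet:
    """Read a file of rooted bifurcating trees into a posterior set.

    Polytomies are rejected unless ``resolve_polytomies`` is set, in which
    case they are resolved arbitrarily with zero-length branches.
    """
    if format not in ("newick", "nexus"):
        raise ParameterError(f"unknown tree format '{format}'")
    try:
        tl = dendropy.TreeList.get(
            path=path, schema=format, suppress_internal_node_taxa=True
        )
    except Exception as exc:  # dendropy raises many parse error types
        raise TreeFormatError(f"could not parse '{path}' as {format}: {exc}") from exc
    if len(tl) == 0:
        raise TreeFormatError(f"no trees found in '{path}'")
    trees = []
    for k, dt in enumerate(tl):
        if resolve_polytomies:
            _resolve_polytomies(dt)
        try:
            trees.append(LineageTree.from_dendropy(dt))
        except TreeStructureError as exc:
            raise TreeStructureError(f"tree {k} in '{path}': {exc}") from exc
    name = lineage_id if lineage_id is not None else str(path)
    return PosteriorTreeSet(trees, lineage_id=name, source=str(path))


def write_trees(trees: PosteriorTreeSet | Iterable[LineageTree], path: str,
                format: str = "newick") -> None:
    """Write trees to Newick or NEXUS with full-precision branch lengths."""
    if format not in ("newick", "nexus"):
        raise ParameterError(f"unknown tree format '{format}'")
    seq = list(trees) if not isinstance(trees, PosteriorTreeSet) else list(trees.trees)
    tns = dendropy.TaxonNamespace()
    tl = dendropy.TreeList(taxon_namespace=tns)
    for t in seq:
        tl.append(t.to_dendropy(taxon_namespace=tns))
    tl.write(path=path, schema=format, real_value_format_specifier=".17g",
             suppress_rooting=(format == "newick"))


# ---------------------------------------------------------------------------
# Branch transforms
# ---------------------------------------------------------------------------

def scale_to_mean_branch_length(tree: LineageTree, target: float = 0.1) -> LineageTree:
    """Multiply every branch by one constant so the mean branch length
    equals ``target`` (the convention used before every model fit)."""
    if target <= 0:
        raise ParameterError("target mean branch length must be positive")
    mean = tree.mean_branch_length
    if mean <= 0:
        raise DegenerateDataError("cannot rescale a tree with all-zero branch lengths")
    return tree.with_lengths(tree.length * (target / mean))


def kappa_transform(tree: LineageTree, kappa: float) -> LineageTree:
    """Raise each branch length to the power kappa.

    kappa = 1 is the identity; kappa = 0 sets every positive branch to 1
    (the punctuational limit where only the number of nodes matters).
    Zero-length branches stay 0 for kappa > 0.
    """
    if not (0.0 <= kappa <= 3.0):
        raise ParameterError("kappa must lie in [0, 3]")
    bl = tree.length.copy()
    pos = bl > 0
    if kappa == 0.0:
        bl[pos] = 1.0
    else:
        bl[pos] = bl[pos] ** kappa
    bl[tree.root] = 0.0
    return tree.with_lengths(bl)


def prune_to_tips(tree: LineageTree, keep: Iterable[str]) -> LineageTree:
    """Restrict the tree to a subset of tips, collapsing unifurcations by
    summing branch lengths.  Used e.g. to drop cells without CNV calls."""
    keep_set = set(keep)
    unknown = keep_set - set(tree.tip_labels)
    if unknown:
        raise MetadataError(f"labels not in tree: {sorted(unknown)[:5]}")
    if len(keep_set) < 2:
        raise DegenerateDataError("cannot prune below 2 tips")
    keep_tip = np.array([lab in keep_set for lab in tree.tip_labels])
    ch = tree.children()
    alive = np.zeros(tree.n_nodes, dtype=bool)
    alive[: tree.n_tips] = keep_tip
    for v in tree.postorder():
        if v >= tree.n_tips:
            alive[v] = any(alive[c] for c in ch[v])
    # effective parent/length after dropping dead nodes and collapsing
    # single-child internals
    new_labels = [lab for lab, k in zip(tree.tip_labels, keep_tip) if k]
    n_new_tips = len(new_labels)
    live_children = {
        v: [c for c in ch[v] if alive[c]] for v in range(tree.n_nodes) if alive[v]
    }
    # nodes that remain as structural nodes: kept tips and internals with 2
    # live children; find the new root (deepest node from which all kept
    # tips descend)
    def is_struct(v: int) -> bool:
        return (v < tree.n_tips and alive[v]) or len(live_children.get(v, [])) == 2

    root = tree.root
    while len(live_children.get(root, [])) == 1:
        root = live_children[root][0]
    index: dict[int, int] = {}
    k_tip = 0
    for v in range(tree.n_tips):
        if alive[v]:
            index[v] = k_tip
            k_tip += 1
    nxt = n_new_tips
    order = [v for v in tree.postorder() if alive[v] and v >= tree.n_tips and is_struct(v)]
    for v in order:
        index[v] = nxt
        nxt += 1
    parent = np.full(nxt, -1, dtype=np.int64)
    length = np.zeros(nxt)

    def assign(v: int, struct_parent: int, acc: float) -> None:
        stack = [(v, struct_parent, acc)]
        while stack:
            u, sp, a = stack.pop()
            a2 = a + float(tree.length[u])
            if is_struct(u) and u != root:
                parent[index[u]] = index[sp] if sp is not None else -1
                length[index[u]] = a2
                nsp, na = u, 0.0
            else:
                nsp, na = sp, a2
            for c in live_children.get(u, []):
                stack.append((c, nsp, na))

    for c in live_children.get(root, []):
        assign(c, root, 0.0)
    parent[index[root]] = -1
    return LineageTree(parent, length, new_labels)


# ---------------------------------------------------------------------------
# Metadata and path tables
# ---------------------------------------------------------------------------

METADATA_COLUMNS = ["cell_id", "location", "site", "cnv_count"]


def read_metadata(path: str) -> pd.DataFrame:
    """Read the tab-separated per-cell metadata table.

    Expected header columns: cell_id, location (P or M), site (optional
    anatomical site name), cnv_count (optional non-negative integer).
    """
    df = pd.read_csv(path, sep="\t", dtype={"cell_id": str})
    return _check_metadata(df)


def _check_metadata(df: pd.DataFrame) -> pd.DataFrame:
    if "cell_id" not in df.columns or "location" not in df.columns:
        raise MetadataError("metadata requires 'cell_id' and 'location' columns")
    df = df.copy()
    df["cell_id"] = df["cell_id"].astype(str)
    bad = ~df["location"].isin(["P", "M"])
    if bad.any():
        raise MetadataError(
            f"location must be 'P' or 'M'; offending rows: {df.loc[bad, 'cell_id'].tolist()[:5]}"
        )
    if df["cell_id"].duplicated().any():
        raise MetadataError("duplicate cell ids in metadata")
    if "site" not in df.columns:
        df["site"] = np.where(df["location"] == "P", "primary", "metastasis")
    if "cnv_count" in df.columns:
        cnv = pd.to_numeric(df["cnv_count"], errors="coerce")
        if (cnv.dropna() < 0).any():
            raise MetadataError("cnv_count must be non-negative")
        df["cnv_count"] = cnv
    else:
        df["cnv_count"] = np.nan
    return df


def write_metadata(meta: pd.DataFrame, path: str) -> None:
    cols = [c for c in METADATA_COLUMNS if c in meta.columns]
    meta.to_csv(path, sep="\t", index=False, columns=cols)


def path_table(tree: LineageTree, meta: pd.DataFrame | None = None) -> pd.DataFrame:
    """Per-tip root-to-tip summaries: LD, DE, location, cnv_count.

    LD is the sum of branch lengths root-to-tip; DE is the number of
    diversification events (internal nodes, root included) on that path.
    """
    ld = tree.tip_depths()
    de = tree.tip_path_node_counts()
    out = pd.DataFrame(
        {"cell_id": list(tree.tip_labels), "LD": ld, "DE": de}
    ).set_index("cell_id")
    if meta is not None:
        meta = _check_metadata(meta)
        m = meta.set_index("cell_id")
        missing = [t for t in tree.tip_labels if t not in m.index]
        if missing:
            raise MetadataError(f"tips missing from metadata: {missing[:10]}")
        out["location"] = m.loc[out.index, "location"].to_numpy()
        out["cnv_count"] = m.loc[out.index, "cnv_count"].to_numpy()
    return out


# ---------------------------------------------------------------------------
# Target-site alignment assembly
# ---------------------------------------------------------------------------

def assemble_alignment(
    sites: pd.DataFrame,
    reference: str | Mapping[str, str] | None = None,
    missing_char: str = "?",
) -> tuple[dict[str, str], str]:
    """Concatenate trimmed target sites into one alignment per cell.

    ``sites`` has columns cell_id, barcode, sequence; each present
    sequence is 296 bp.  The first 34 characters of every site (the 14-bp
    integration barcode and the 20 bp preceding it) are removed, leaving
    262 bp.  Sites are ordered by integration barcode (lexicographic)
    identically for every cell; a site recovered in the lineage but
    absent for a given cell is filled with 262 missing-data characters to
    preserve indexing.  Returns ``(rows, nexus_text)`` where ``rows`` maps
    cell id to its concatenated sequence and ``nexus_text`` is a NEXUS
    DATA block (DATATYPE=DNA, MISSING=?, GAP=-) with the unedited
    reference included as outgroup row when provided.
    """
    req = {"cell_id", "barcode", "sequence"}
    if not req.issubset(sites.columns):
        raise MetadataError(f"target-site table requires columns {sorted(req)}")
    df = sites.copy()
    df["cell_id"] = df["cell_id"].astype(str)
    df["barcode"] = df["barcode"].astype(str)
    if df.duplicated(subset=["cell_id", "barcode"]).any():
        raise MetadataError("duplicate (cell, barcode) pairs in target-site table")
    barcodes = sorted(df["barcode"].unique())
    lookup: dict[tuple[str, str], str] = {}
    for row in df.itertuples(index=False):
        seq = row.sequence
        if seq is None or (isinstance(seq, float) and np.isnan(seq)):
            continue
        seq = str(seq)
        if len(seq) != TARGET_SITE_LENGTH:
            raise MetadataError(
                f"sequence for cell {row.cell_id}, barcode {row.barcode} has length "
                f"{len(seq)}; expected {TARGET_SITE_LENGTH}"
            )
        lookup[(row.cell_id, row.barcode)] = seq[BARCODE_PREFIX_LENGTH:]
    blank = missing_char * TRIMMED_SITE_LENGTH
    rows: dict[str, str] = {}
    for cell in sorted(df["cell_id"].unique()):
        rows[cell] = "".join(lookup.get((cell, bc), blank) for bc in barcodes)
    if reference is not None:
        if isinstance(reference, str):
            refmap = {bc: reference for bc in barcodes}
        else:
            refmap = dict(reference)
        for bc, seq in refmap.items():
            if len(seq) != TARGET_SITE_LENGTH:
                raise MetadataError("reference sequences must be 296 bp")
        ref_row = "".join(
            refmap[bc][BARCODE_PREFIX_LENGTH:] if bc in refmap else blank
            for bc in barcodes
        )
        rows = {"reference": ref_row, **rows}
    nexus = _nexus_data_block(rows, missing_char=missing_char)
    return rows, nexus


def _nexus_data_block(rows: Mapping[str, str], missing_char: str = "?") -> str:
    nchar = len(next(iter(rows.values()))) if rows else 0
    buf = io.StringIO()
    buf.write("#NEXUS\n\nBEGIN DATA;\n")
    buf.write(f"    DIMENSIONS NTAX={len(rows)} NCHAR={nchar};\n")
    buf.write(
        f"    FORMAT DATATYPE=DNA MISSING={missing_char} GAP=-;\n    MATRIX\n"
    )
    width = max((len(k) for k in rows), default=0) + 2
    for name, seq in rows.items():
        if len(seq) != nchar:
            raise MetadataError("alignment rows differ in length")
        buf.write(f"    {name:<{width}}{seq}\n")
    buf.write("    ;\nEND;\n")
    return buf.getvalue()
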