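"""Trees, tree samples, alignments and character matrices.

This module holds the substrate types for all downstream analyses:

* :class:`RootedTree` — an immutable rooted phylogeny with branch lengths,
  indexed by integer node ids (tips carry labels).
* :class:`TreeSample` — an ordered collection of rooted trees sharing a tip
  set, standing in for a posterior sample ("tree file") from a Bayesian
  phylogenetic analysis.
* :class:`Alignment` — a rectangular multiple sequence alignment.
* :class:`CharacterMatrix` — taxon -> discrete state with an explicit
  missing-data marker; state labels are interned and indexed in sorted
  (lexicographic) order, a fixed convention so that state indices are
  reproducible across runs.

Parsing of Newick strings and NEXUS blocks is delegated to dendropy; FASTA
I/O to Biopython.  Serialization back to Newick is plain formatting.
"""

from __future__ import annotations

import io
import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import dendropy
import numpy as np
import pandas as pd
from Bio import SeqIO


class TreeFormatError(ValueError):
    """Raised for malformed Newick/NEXUS input."""


ALIGNMENT_ALPHABET = set("ACGTUacgtu-Nn?RYSWKMBDHVryswkmbdhv")


# ---------------------------------------------------------------------------
# RootedTree
# ---------------------------------------------------------------------------

class RootedTree:
    """A rooted tree over integer node ids 0..n-1.

    Parameters
    ----------
    parent
        ``parent[i]`` is the parent id of node ``i`` (-1 for the root).
    branch_lengths
        Length of the branch subtending each node (ignored for the root);
        non-negative, in substitutions per site or arbitrary time units.
    labels
        Tip labels; ``None`` for internal nodes.  Tip labels must be unique.
    """

    __slots__ = ("parent", "children", "branch_lengths", "labels", "root",
                 "_postorder", "_clades")

    def __init__(self, parent: Sequence[int], branch_lengths: Sequence[float],
                 labels: Sequence[str | None]):
        self.parent = np.asarray(parent, dtype=np.int64)
        self.branch_lengths = np.asarray(branch_lengths, dtype=float)
        self.labels = tuple(labels)
        n = len(self.parent)
        if not (len(self.branch_lengths) == len(self.labels) == n):
            raise ValueError("parent, branch_lengths and labels must have equal length")
        roots = np.flatnonzero(self.parent < 0)
        if len(roots) != 1:
            raise TreeFormatError(f"tree must have exactly one root, found {len(roots)}")
        self.root = int(roots[0])
        kids: list[list[int]] = [[] for _ in range(n)]
        for i, p in enumerate(self.parent):
            if p >= 0:
                kids[p].append(i)
        self.children = tuple(tuple(c) for c in kids)
        # connectivity / acyclicity: every node must reach the root
        for i in range(n):
            seen = 0
            j = i
            while self.parent[j] >= 0:
                j = int(self.parent[j])
                seen += 1
                if seen > n:
                    raise TreeFormatError("cycle detected in parent map")
        tips = [self.labels[i] for i in range(n) if not self.children[i]]
        if any(t is None for t in tips):
            raise TreeFormatError("every tip must carry a label")
        if len(set(tips)) != len(tips):
            dup = sorted({t for t in tips if tips.count(t) > 1})
            raise TreeFormatError(f"duplicate tip label(s): {', '.join(dup)}")
        if np.any(self.branch_lengths[np.arange(n) != self.root] < 0):
            raise TreeFormatError("negative branch length")
        self._postorder: tuple[int, ...] | None = None
        self._clades: dict[int, frozenset[str]] | None = None

    # -- basic accessors ----------------------------------------------------
    @property
    def n_nodes(self) -> int:
        return len(self.labels)

    def is_tip(self, node: int) -> bool:
        return not self.children[node]

    def tips(self) -> list[int]:
        return [i for i in range(self.n_nodes) if self.is_tip(i)]

    def tip_labels(self) -> frozenset[str]:
        return frozenset(self.labels[i] for i in self.tips())

    def postorder(self) -> tuple[int, ...]:
        """Node ids with every child before its parent (cached)."""
        if self._postorder is None:
            order: list[int] = []
            stack = [self.root]
            while stack:
                v = stack.pop()
                order.append(v)
                stack.extend(self.children[v])
            self._postorder = tuple(reversed(order))
        return self._postorder

    def clade_tips(self, node: int) -> frozenset[str]:
        """Set of tip labels descending from ``node`` (node included if tip)."""
        if self._clades is None:
            clades: dict[int, frozenset[str]] = {}
            for v in self.postorder():
                if self.is_tip(v):
                    clades[v] = frozenset((self.labels[v],))
                else:
                    clades[v] = frozenset().union(*(clades[c] for c in self.children[v]))
            self._clades = clades
        return self._clades[node]

    def mrca(self, tip_labels: Iterable[str]) -> int:
        """Most recent common ancestor of the given tips."""
        want = frozenset(tip_labels)
        missing = want - self.tip_labels()
        if missing:
            raise KeyError(f"tips not in tree: {sorted(missing)}")
        for v in self.postorder():
            if want <= self.clade_tips(v):
                return v
        return self.root  # unreachable

    def find_clade(self, tip_labels: Iterable[str]) -> int | None:
        """Node whose descendant tip set equals ``tip_labels`` exactly, if any."""
        want = frozenset(tip_labels)
        v = self.mrca(want)
        return v if self.clade_tips(v) == want else None

    def bipartitions(self) -> frozenset[frozenset[str]]:
        """Non-trivial clades, for topology comparison of rooted trees."""
        out = set()
        for v in range(self.n_nodes):
            if v != self.root and not self.is_tip(v):
                out.add(self.clade_tips(v))
        return frozenset(out)

    def with_branch_lengths(self, new_lengths: Sequence[float]) -> "RootedTree":
        return RootedTree(self.parent, new_lengths, self.labels)

    # -- serialization ------------------------------------------------------
    def newick(self, precision: int = 10) -> str:
        def fmt(v: int) -> str:
            if self.is_tip(v):
                core = _quote_label(self.labels[v])
            else:
                core = "(" + ",".join(fmt(c) for c in self.children[v]) + ")"
            if v == self.root:
                return core
            return f"{core}:{self.branch_lengths[v]:.{precision}g}"

        return fmt(self.root) + ";"

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"<RootedTree {len(self.tips())} tips, {self.n_nodes} nodes>"


def _quote_label(label: str) -> str:
    if any(c in label for c in "()[]{}/\\,;:=*'\"`<> \t\n"):
        return "'" + label.replace("'", "''") + "'"
    return label


# ---------------------------------------------------------------------------
# TreeSample
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TreeSample:
    """An ordered posterior-like sample of rooted trees sharing one tip set."""

    trees: tuple[RootedTree, ...]
    run_ids: tuple[int, ...]

    def __post_init__(self):
        if len(self.trees) != len(self.run_ids):
            raise ValueError("one run_id per tree required")
        if self.trees:
            ref = self.trees[0].tip_labels()
            for t in self.trees[1:]:
                if t.tip_labels() != ref:
                    raise ValueError("all trees in a sample must share a tip set")

    def __len__(self) -> int:
        return len(self.trees)

    def __iter__(self):
        return iter(self.trees)

    def __getitem__(self, i: int) -> RootedTree:
        return self.trees[i]

    @classmethod
    def from_trees(cls, trees: Sequence[RootedTree], run_id: int = 0) -> "TreeSample":
        return cls(tuple(trees), tuple([run_id] * len(trees)))


# ---------------------------------------------------------------------------
# dendropy-backed parsing
# ---------------------------------------------------------------------------

def _from_dendropy(dtree: dendropy.Tree) -> RootedTree:
    nodes = list(dtree.preorder_node_iter())
    index = {id(nd): i for i, nd in enumerate(nodes)}
    parent = np.full(len(nodes), -1, dtype=np.int64)
    blen = np.zeros(len(nodes))
    labels: list[str | None] = [None] * len(nodes)
    missing_len = 0
    for i, nd in enumerate(nodes):
        if nd.parent_node is not None:
            parent[i] = index[id(nd.parent_node)]
            if nd.edge.length is None:
                missing_len += 1
            else:
                blen[i] = float(nd.edge.length)
        if nd.is_leaf():
            labels[i] = nd.taxon.label if nd.taxon is not None else nd.label
    if missing_len:
        warnings.warn(f"{missing_len} branch length(s) missing; defaulting to 0",
                      stacklevel=3)
    return RootedTree(parent, blen, labels)


def parse_newick(text: str) -> RootedTree:
    """Parse a single rooted Newick statement.

    Quoted labels are allowed, bracket comments are stripped, and internal
    node labels are tolerated but unused.  Missing branch lengths default to
    0 with a warning.  Duplicate tip labels raise :class:`TreeFormatError`.
    """
    if not text.strip():
        raise TreeFormatError("empty Newick input")
    try:
        dtree = dendropy.Tree.get(
            data=text, schema="newick", rooting="force-rooted",
            preserve_underscores=True, suppress_internal_node_taxa=True,
        )
    except Exception as exc:  # dendropy raises several error classes
        raise TreeFormatError(f"Newick parse error: {exc}") from exc
    return _from_dendropy(dtree)


def parse_nexus_trees(text: str, run_id: int = 0) -> TreeSample:
    """Parse the TREES block of a NEXUS document into a :class:`TreeSample`.

    Translate tables are applied so that every tip carries its taxon name.
    Tree order is preserved.  An absent or empty TREES block is an error.
    """
    try:
        tl = dendropy.TreeList.get(
            data=text, schema="nexus", rooting="force-rooted",
            preserve_underscores=True, suppress_internal_node_taxa=True,
        )
    except Exception as exc:
        raise TreeFormatError(f"NEXUS parse error: {exc}") from exc
    if len(tl) == 0:
        raise TreeFormatError("no trees found in NEXUS TREES block")
    return TreeSample.from_trees([_from_dendropy(t) for t in tl], run_id=run_id)


def write_nexus_trees(sample: TreeSample, path: str) -> None:
    with open(path, "w") as fh:
        fh.write("#NEXUS\nBEGIN TREES;\n")
        for i, tree in enumerate(sample):
            fh.write(f"  TREE tree_{i + 1} = {tree.newick()}\n")
        fh.write("END;\n")


# ---------------------------------------------------------------------------
# Burn-in / thinning
# ---------------------------------------------------------------------------

def thin_tree_sample(runs: Sequence[TreeSample] | TreeSample,
                     burnin_fraction: float, step: int) -> TreeSample:
    """Discard burn-in and subsample each run of saved trees.

    Per run the first ``floor(burnin_fraction * n)`` trees are discarded and
    every ``step``-th tree of the remainder is kept, counting from the
    ``step``-th; the runs are then concatenated.  Two runs of 10,000 saved
    trees at 25% burn-in and step 10 therefore yield 750 + 750 = 1,500 trees.
    """
    if isinstance(runs, TreeSample):
        runs = [runs]
    if step <= 0:
        raise ValueError("step must be a positive integer")
    if not 0 <= burnin_fraction < 1:
        raise ValueError("burnin_fraction must lie in [0, 1)")
    trees: list[RootedTree] = []
    run_ids: list[int] = []
    for run in runs:
        n = len(run)
        if n == 0:
            raise ValueError("each run must be non-empty")
        start = math.floor(burnin_fraction * n)
        kept = list(range(start + step - 1, n, step))
        trees.extend(run[i] for i in kept)
        run_ids.extend(run.run_ids[i] for i in kept)
    if not trees:
        raise ValueError("thinning produced an empty sample; use a smaller step")
    return TreeSample(tuple(trees), tuple(run_ids))


# ---------------------------------------------------------------------------
# Alignments
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Alignment:
    """A rectangular alignment with unique taxon labels.

    ``part_ranges`` records the half-open column range contributed by each
    source partition after concatenation (provenance only).
    """

    labels: tuple[str, ...]
    sequences: tuple[str, ...]
    part_ranges: tuple[tuple[int, int], ...] = field(default_factory=tuple)

    def __post_init__(self):
        if len(self.labels) != len(self.sequences):
            raise ValueError("one sequence per label required")
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("duplicate taxon labels in alignment")
        widths = {len(s) for s in self.sequences}
        if len(widths) > 1:
            raise ValueError("sequences must all have the same length")

    @property
    def n_columns(self) -> int:
        return len(self.sequences[0]) if self.sequences else 0

    def sequence(self, label: str) -> str:
        return self.sequences[self.labels.index(label)]


def read_fasta_alignment(path: str) -> Alignment:
    records = list(SeqIO.parse(path, "fasta"))
    if not records:
        raise ValueError(f"no sequences in {path}")
    return Alignment(tuple(r.id for r in records), tuple(str(r.seq) for r in records))


def write_fasta_alignment(aln: Alignment, path: str) -> None:
    with open(path, "w") as fh:
        for label, seq in zip(aln.labels, aln.sequences):
            fh.write(f">{label}\n{seq}\n")


def concatenate_alignments(parts: Sequence[Alignment]) -> Alignment:
    """Concatenate gene alignments; taxa absent from a part are filled with '?'.

    The result's width is the sum of part widths, and per-part column ranges
    are recorded in ``part_ranges``.
    """
    if not parts:
        raise ValueError("cannot concatenate an empty list of alignments")
    taxa: list[str] = []
    for part in parts:
        for label in part.labels:
            if label not in taxa:
                taxa.append(label)
    chunks: dict[str, list[str]] = {t: [] for t in taxa}
    ranges: list[tuple[int, int]] = []
    offset = 0
    for part in parts:
        width = part.n_columns
        ranges.append((offset, offset + width))
        offset += width
        lookup = dict(zip(part.labels, part.sequences))
        for t in taxa:
            chunks[t].append(lookup.get(t, "?" * width))
    return Alignment(tuple(taxa), tuple("".join(chunks[t]) for t in taxa),
                     tuple(ranges))


# ---------------------------------------------------------------------------
# Character matrices
# ---------------------------------------------------------------------------

MISSING = None  # sentinel for missing tip data


class CharacterMatrix:
    """Taxon -> discrete-state mapping with an explicit missing marker.

    State labels are sorted lexicographically and assigned indices 0..k-1
    (e.g. for a specialist/generalist character with labels "G" and "S",
    G = 0 and S = 1).  This convention is fixed for reproducibility.
    """

    def __init__(self, assignments: Mapping[str, str | None],
                 state_labels: Sequence[str] | None = None):
        observed = sorted({s for s in assignments.values() if s is not None})
        if state_labels is None:
            state_labels = observed
        else:
            state_labels = sorted(state_labels)
            unknown = set(observed) - set(state_labels)
            if unknown:
                raise ValueError(f"states {sorted(unknown)} not in state_labels")
        if len(state_labels) < 1:
            raise ValueError("character matrix defines no states")
        self.state_labels: tuple[str, ...] = tuple(state_labels)
        index = {s: i for i, s in enumerate(self.state_labels)}
        self.data: dict[str, int | None] = {
            taxon: (None if state is None else index[state])
            for taxon, state in assignments.items()
        }

    @property
    def k(self) -> int:
        return len(self.state_labels)

    @property
    def taxa(self) -> frozenset[str]:
        return frozenset(self.data)

    def state_index(self, taxon: str) -> int | None:
        return self.data[taxon]

    def is_missing(self, taxon: str) -> bool:
        return self.data[taxon] is None

    def __len__(self) -> int:
        return len(self.data)

    def __repr__(self) -> str:  # pragma: no cover
        return f"<CharacterMatrix {len(self.data)} taxa, k={self.k}>"


def read_character_matrix(path_or_text: str, missing_token: str = "?",
                          state_labels: Sequence[str] | None = None) -> CharacterMatrix:
    """Read a character matrix from CSV (columns ``taxon,state``) or a NEXUS
    DATA/CHARACTERS block (sniffed by the ``#NEXUS`` magic)."""
    text = path_or_text
    if "\n" not in path_or_text and not path_or_text.lstrip().startswith("#NEXUS"):
        with open(path_or_text) as fh:
            text = fh.read()
    if text.lstrip().startswith("#NEXUS"):
        cm = dendropy.StandardCharacterMatrix.get(data=text, schema="nexus")
        assignments: dict[str, str | None] = {}
        for taxon in cm:
            sym = str(cm[taxon][0].symbol)
            assignments[taxon.label] = None if sym == missing_token else sym
        if not assignments:
            raise ValueError("empty NEXUS character matrix")
        return CharacterMatrix(assignments, state_labels)
    df = pd.read_csv(io.StringIO(text), dtype=str)
    if df.empty:
        raise ValueError("empty character matrix file")
    if not {"taxon", "state"} <= set(df.columns):
        raise ValueError("CSV character matrix needs 'taxon' and 'state' columns")
    if df["taxon"].duplicated().any():
        dups = sorted(df.loc[df["taxon"].duplicated(), "taxon"])
        raise ValueError(f"duplicate taxon rows: {dups}")
    assignments = {
        row.taxon: (None if row.state == missing_token or pd.isna(row.state)
                    else row.state)
        for row in df.itertuples()
    }
    return CharacterMatrix(assignments, state_labels)


def write_character_matrix(char: CharacterMatrix, path: str,
                           missing_token: str = "?") -> None:
    rows = [(t, missing_token if i is None else char.state_labels[i])
            for t, i in sorted(char.data.items())]
    pd.DataFrame(rows, columns=["taxon", "state"]).to_csv(path, index=False)
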