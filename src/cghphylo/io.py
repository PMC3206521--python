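"""Core data containers and file formats.

Trees are stored as unrooted, leaf-labelled split sets: each internal
edge of a tree induces a bipartition of the leaves, and every
topology-level question downstream (Robinson-Foulds distance, consensus,
restriction, agreement subtrees) is a question about split sets.  Newick
text is parsed and written through dendropy; any rooting present in the
input string is discarded.

Slide-level data use pandas: a :class:`SlideTable` is one two-color
hybridization (per-spot channel signals plus metadata), a
:class:`RatioMatrix` is the gene x slide matrix of orientation-corrected
log2(test/reference) ratios with an explicit missing-value mask (NaN).
"""

from __future__ import annotations

import io as _stdio
import math
import re
from dataclasses import dataclass, field, replace

import dendropy
import numpy as np
import pandas as pd

__all__ = [
    "Tree",
    "SlideTable",
    "RatioMatrix",
    "Split",
    "read_newick",
    "write_newick",
    "read_spot_table",
    "write_spot_table",
    "read_ratio_matrix",
    "write_ratio_matrix",
    "write_nexus_binary",
]

#: A canonical split: the side of the bipartition that does not contain
#: the anchor leaf (the lexicographically smallest leaf label).
Split = frozenset


class NewickParseError(ValueError):
    """Raised for malformed newick input."""


class SchemaError(ValueError):
    """Raised when a tabular file lacks required columns."""


def _canonical(side: frozenset, leaves: frozenset) -> frozenset:
    anchor = min(leaves)
    return frozenset(leaves - side) if anchor in side else frozenset(side)


@dataclass(frozen=True)
class Tree:
    """An unrooted leaf-labelled tree, possibly multifurcating.

    Parameters
    ----------
    leaves:
        The leaf label set.  Labels must be unique and non-empty.
    splits:
        The nontrivial splits (internal edges).  Each split is stored
        canonically as the frozenset of leaf labels on the side *not*
        containing the anchor (smallest) label, so two splits are
        compatible iff they are nested or disjoint.
    branch_lengths:
        Optional mapping edge -> length; internal edges are keyed by
        their canonical split, pendant edges by the leaf label.
    """

    leaves: frozenset
    splits: frozenset = frozenset()
    branch_lengths: dict | None = None

    def __post_init__(self):
        n = len(self.leaves)
        if n < 2:
            raise ValueError("a tree needs at least 2 leaves")
        anchor = min(self.leaves)
        for s in self.splits:
            if not (2 <= len(s) <= n - 2):
                raise ValueError(f"trivial or invalid split {set(s)}")
            if anchor in s or not s <= self.leaves:
                raise ValueError(f"split {set(s)} not in canonical form")
        splits = sorted(self.splits, key=len)
        for i, a in enumerate(splits):
            for b in splits[i + 1 :]:
                if not (a <= b or not (a & b)):
                    raise ValueError(
                        f"incompatible splits {set(a)} and {set(b)}"
                    )

    # -- topology queries -------------------------------------------------

    @property
    def n_leaves(self) -> int:
        return len(self.leaves)

    def is_binary(self) -> bool:
        """True iff the unrooted tree is fully resolved."""
        return len(self.splits) == max(self.n_leaves - 3, 0)

    def has_split(self, side) -> bool:
        """True if the bipartition with one side ``side`` is an edge."""
        side = frozenset(side)
        if not side <= self.leaves:
            return False
        return _canonical(side, self.leaves) in self.splits

    def topology_equal(self, other: "Tree") -> bool:
        return self.leaves == other.leaves and self.splits == other.splits

    def without_lengths(self) -> "Tree":
        return replace(self, branch_lengths=None)

    # -- path lengths -----------------------------------------------------

    def path_length(self, a: str, b: str) -> float:
        """Sum of branch lengths on the path between two leaves."""
        if self.branch_lengths is None:
            raise ValueError("tree has no branch lengths")
        if a == b:
            return 0.0
        total = self.branch_lengths.get(a, 0.0) + self.branch_lengths.get(b, 0.0)
        for s in self.splits:
            # edge s lies on the a-b path iff it separates a from b
            in_s = {a in s, b in s}
            if in_s == {True, False}:
                total += self.branch_lengths.get(s, 0.0)
        return total


# ---------------------------------------------------------------------------
# newick
# ---------------------------------------------------------------------------


def read_newick(text: str) -> Tree:
    """Parse one newick string into an unrooted :class:`Tree`.

    Rooting encoded in the string is discarded; internal node labels are
    ignored; quoted labels are supported.  Malformed input raises
    :class:`NewickParseError` naming the offending position where
    dendropy reports one; duplicate leaf labels raise ``ValueError``.
    """
    try:
        dtree = dendropy.Tree.get(
            data=text,
            schema="newick",
            preserve_underscores=True,
            suppress_internal_node_taxa=True,
        )
    except Exception as exc:  # dendropy raises several error classes
        raise NewickParseError(f"malformed newick: {exc}") from exc
    labels = [lf.taxon.label for lf in dtree.leaf_node_iter()]
    if any(l is None or l == "" for l in labels):
        raise NewickParseError("leaf without label")
    if len(set(labels)) != len(labels):
        dup = sorted({l for l in labels if labels.count(l) > 1})
        raise ValueError(f"duplicate leaf labels: {dup}")
    leaves = frozenset(labels)
    n = len(leaves)

    split_len: dict = {}
    pendant: dict = {}
    lengths_ok = True
    for node in dtree.preorder_node_iter():
        if node is dtree.seed_node:
            continue
        clade = frozenset(lf.taxon.label for lf in node.leaf_iter())
        elen = node.edge.length
        if elen is None:
            lengths_ok = False
            elen = 0.0
        if len(clade) == 1:
            (label,) = clade
            pendant[label] = pendant.get(label, 0.0) + elen
        elif len(clade) == n - 1:
            # complement of a pendant edge (rooted between a leaf and the rest)
            (label,) = leaves - clade
            pendant[label] = pendant.get(label, 0.0) + elen
        elif len(clade) <= n - 2:
            key = _canonical(clade, leaves)
            # a rooted bifurcation at the seed node yields the same split
            # from both root children; merge the two edge lengths
            split_len[key] = split_len.get(key, 0.0) + elen
    bl = None
    if lengths_ok:
        bl = dict(pendant)
        bl.update(split_len)
    return Tree(leaves=leaves, splits=frozenset(split_len), branch_lengths=bl)


_QUOTE_NEEDED = re.compile(r"[\s()\[\]{}:;,'\"]")


def _quote(label: str) -> str:
    if _QUOTE_NEEDED.search(label):
        return "'" + label.replace("'", "''") + "'"
    return label


def write_newick(tree: Tree) -> str:
    """Serialize a :class:`Tree` to newick, rooted (arbitrarily) at the
    anchor leaf's attachment node.  Multifurcations are emitted where the
    tree is unresolved; branch lengths are emitted when present."""
    anchor = min(tree.leaves)
    others = sorted(tree.leaves - {anchor})
    bl = tree.branch_lengths

    def fmt_len(key) -> str:
        if bl is None:
            return ""
        return f":{bl.get(key, 0.0):g}"

    # children of a clade-set = maximal proper subsets among splits and
    # singletons; the split sets form a laminar family so this nests
    sets = sorted(tree.splits, key=len, reverse=True)

    def render(members: list, available: list) -> str:
        """Render the subtree over `members`; `available` holds unused splits."""
        parts = []
        member_set = frozenset(members)
        maximal = []
        for s in available:
            if s <= member_set and not any(s < m for m in maximal):
                maximal.append(s)
        covered = set()
        for s in maximal:
            inner = [x for x in available if x < s]
            parts.append("(" + render(sorted(s), inner) + ")" + fmt_len(s))
            covered |= s
        for label in members:
            if label not in covered:
                parts.append(_quote(label) + fmt_len(label))
        return ",".join(parts)

    body = render(others, sets)
    return "(" + _quote(anchor) + fmt_len(anchor) + "," + body + ");"


# ---------------------------------------------------------------------------
# slide tables
# ---------------------------------------------------------------------------

SPOT_COLUMNS = [
    "gene_id",
    "block_id",
    "ch1_signal",
    "ch2_signal",
    "flag",
    "saturation_pct",
    "roundness",
]

STANDARD = "standard"
SWAPPED = "swapped"


@dataclass
class SlideTable:
    """Per-spot measurements of one hybridization.

    ``ch1_signal`` holds the channel-1 (Cy3-like) and ``ch2_signal`` the
    channel-2 intensity.  In ``standard`` orientation channel 1 carries
    the test sample and channel 2 the reference; a ``swapped`` slide has
    the dyes reversed.  ``flag`` is 0 for good spots and negative for
    spots flagged bad, following the GenePix convention.
    """

    spots: pd.DataFrame
    taxon: str
    dye_orientation: str = STANDARD
    slide_id: str = ""

    def __post_init__(self):
        if self.dye_orientation not in (STANDARD, SWAPPED):
            raise ValueError(f"bad dye orientation {self.dye_orientation!r}")
        missing = [c for c in SPOT_COLUMNS if c not in self.spots.columns]
        if missing:
            raise SchemaError(f"spot table missing columns: {missing}")
        if (self.spots[["ch1_signal", "ch2_signal"]] < 0).any().any():
            raise ValueError("negative channel signals")

    @property
    def swapped(self) -> bool:
        return self.dye_orientation == SWAPPED

    def oriented_log2_ratio(self) -> pd.Series:
        """log2(test/reference) per spot, correcting dye orientation.

        Nonpositive signals yield NaN (masked), never a pseudocount.
        """
        ch1 = self.spots["ch1_signal"].to_numpy(float)
        ch2 = self.spots["ch2_signal"].to_numpy(float)
        test, ref = (ch2, ch1) if self.swapped else (ch1, ch2)
        with np.errstate(divide="ignore", invalid="ignore"):
            m = np.where((test > 0) & (ref > 0), np.log2(
                np.where(test > 0, test, 1.0) / np.where(ref > 0, ref, 1.0)
            ), np.nan)
        return pd.Series(m, index=self.spots["gene_id"].to_numpy(), name=self.slide_id)

    def mean_log2_intensity(self) -> pd.Series:
        """A-value per spot: (log2 ch1 + log2 ch2) / 2; NaN if a channel is 0."""
        ch1 = self.spots["ch1_signal"].to_numpy(float)
        ch2 = self.spots["ch2_signal"].to_numpy(float)
        with np.errstate(divide="ignore"):
            a = 0.5 * (np.log2(np.where(ch1 > 0, ch1, np.nan))
                       + np.log2(np.where(ch2 > 0, ch2, np.nan)))
        return pd.Series(a, index=self.spots["gene_id"].to_numpy(), name=self.slide_id)


def read_spot_table(path_or_buf) -> SlideTable:
    """Read a TSV spot table (GenePix-like dialect).

    Metadata lines ``#key=value`` precede a tab-separated header naming
    at least the columns in :data:`SPOT_COLUMNS`.
    """
    if hasattr(path_or_buf, "read"):
        text = path_or_buf.read()
    else:
        with open(path_or_buf) as fh:
            text = fh.read()
    meta = {}
    lines = text.splitlines()
    body_start = 0
    for i, line in enumerate(lines):
        if line.startswith("#"):
            key, _, val = line[1:].partition("=")
            meta[key.strip()] = val.strip()
            body_start = i + 1
        else:
            break
    df = pd.read_csv(_stdio.StringIO("\n".join(lines[body_start:])), sep="\t")
    missing = [c for c in SPOT_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"spot table missing columns: {missing}")
    return SlideTable(
        spots=df,
        taxon=meta.get("taxon", ""),
        dye_orientation=meta.get("dye_orientation", STANDARD),
        slide_id=meta.get("slide_id", ""),
    )


def write_spot_table(slide: SlideTable, path) -> None:
    with open(path, "w") as fh:
        fh.write(f"#taxon={slide.taxon}\n")
        fh.write(f"#dye_orientation={slide.dye_orientation}\n")
        fh.write(f"#slide_id={slide.slide_id}\n")
        slide.spots.to_csv(fh, sep="\t", index=False)


# ---------------------------------------------------------------------------
# ratio matrices
# ---------------------------------------------------------------------------


@dataclass
class RatioMatrix:
    """Gene x slide matrix of oriented log2(test/reference) ratios.

    Missing entries are NaN and stay NaN: no stage ever zero-fills.
    ``slide_taxa`` maps each slide column to its test taxon;
    ``gene_blocks`` records the print-tip block of each gene's spot
    (constant across slides for a fixed array layout).
    """

    values: pd.DataFrame
    slide_taxa: dict
    gene_blocks: pd.Series | None = None
    provenance: tuple = ()  # processing steps applied, oldest first

    def __post_init__(self):
        unknown = [s for s in self.values.columns if s not in self.slide_taxa]
        if unknown:
            raise ValueError(f"slides without a taxon assignment: {unknown}")

    @property
    def genes(self):
        return self.values.index

    @property
    def slides(self):
        return self.values.columns

    def taxa(self) -> list:
        seen = dict.fromkeys(self.slide_taxa[s] for s in self.values.columns)
        return list(seen)

    def copy_with(self, values: pd.DataFrame, step: str | None = None) -> "RatioMatrix":
        gb = self.gene_blocks
        if gb is not None:
            gb = gb.reindex(values.index)
        prov = self.provenance + ((step,) if step else ())
        return RatioMatrix(
            values=values, slide_taxa=dict(self.slide_taxa), gene_blocks=gb, provenance=prov
        )


def write_ratio_matrix(rm: RatioMatrix, path) -> None:
    with open(path, "w") as fh:
        for s in rm.values.columns:
            fh.write(f"#taxon\t{s}\t{rm.slide_taxa[s]}\n")
        if rm.gene_blocks is not None:
            fh.write("#has_blocks\t1\n")
        df = rm.values.copy()
        if rm.gene_blocks is not None:
            df.insert(0, "block_id", rm.gene_blocks.reindex(df.index))
        df.to_csv(fh, sep="\t", index_label="gene_id")


def read_ratio_matrix(path) -> RatioMatrix:
    slide_taxa = {}
    has_blocks = False
    with open(path) as fh:
        lines = fh.read().splitlines()
    body = 0
    for i, line in enumerate(lines):
        if line.startswith("#taxon\t"):
            _, slide, taxon = line.split("\t")
            slide_taxa[slide] = taxon
            body = i + 1
        elif line.startswith("#has_blocks"):
            has_blocks = True
            body = i + 1
        else:
            break
    df = pd.read_csv(_stdio.StringIO("\n".join(lines[body:])), sep="\t", index_col="gene_id")
    gene_blocks = None
    if has_blocks:
        gene_blocks = df.pop("block_id")
    return RatioMatrix(values=df, slide_taxa=slide_taxa, gene_blocks=gene_blocks)


# ---------------------------------------------------------------------------
# NEXUS export of binary matrices (for external parsimony programs)
# ---------------------------------------------------------------------------


def write_nexus_binary(binary, path) -> None:
    """Write a taxon x gene presence/absence matrix as a NEXUS data block.

    Missing calls become ``?``.  Accepts any object with a ``calls``
    DataFrame attribute (taxa as index) or a bare DataFrame.
    """
    df = getattr(binary, "calls", binary)
    with open(path, "w") as fh:
        fh.write("#NEXUS\nBEGIN DATA;\n")
        fh.write(f"  DIMENSIONS NTAX={df.shape[0]} NCHAR={df.shape[1]};\n")
        fh.write('  FORMAT DATATYPE=STANDARD SYMBOLS="01" MISSING=?;\n')
        fh.write("  MATRIX\n")
        for taxon, row in df.iterrows():
            chars = "".join(
                "?" if (isinstance(v, float) and math.isnan(v)) else str(int(v))
                for v in row
            )
            fh.write(f"    {str(taxon).replace(' ', '_')}  {chars}\n")
        fh.write("  ;\nEND;\n")
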