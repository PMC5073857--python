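"""Trees and alignment columns: parsing, domain types, and metric output.

The two domain types shared by the whole package live here:

``TimeTree``
    a rooted phylogeny whose branch lengths are durations in millions of
    years (My).  The quantity every downstream metric needs is the *total
    time elapsed on the tree* — the sum of all branch durations.

``SiteColumn``
    the per-species residues observed at one human genomic position,
    distinguishing a real base (A/C/G/T) from a gap (the position does not
    exist in that lineage's alignment row) and from missing data (``N`` or
    an absent row).

Newick text is parsed with dendropy and converted into a small in-package
node structure so that pruning and parsimony traversals stay simple and
fully under our control.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import IO, Iterable, Iterator, Mapping, Sequence, Union

import dendropy

logger = logging.getLogger(__name__)

#: Residue sentinel: the position does not exist in that species' row ('-').
GAP = "-"
#: Residue sentinel: no information for that species ('N' or absent row).
MISSING = "?"

BASES = frozenset("ACGT")
VALID_RESIDUES = BASES | {GAP, MISSING}


class NewickError(ValueError):
    """Raised for malformed Newick input (message carries the offset)."""


class ColumnError(ValueError):
    """Raised for invalid alignment-column input."""


# ---------------------------------------------------------------------------
# TimeTree
# ---------------------------------------------------------------------------

@dataclass
class TreeNode:
    """One node of a :class:`TimeTree`.

    ``branch_length_my`` is the duration of the edge to the parent; the root
    carries 0.  Leaves have a non-empty ``label``.
    """

    label: str | None = None
    branch_length_my: float = 0.0
    children: list["TreeNode"] = field(default_factory=list)
    parent: "TreeNode | None" = field(default=None, repr=False, compare=False)

    @property
    def is_leaf(self) -> bool:
        return not self.children


class TimeTree:
    """Rooted tree with branch durations in millions of years.

    Invariants enforced at construction: every branch length is ≥ 0 and
    present, leaf labels are unique and non-empty, and the tree is connected
    (a single root).
    """

    def __init__(self, root: TreeNode):
        self.root = root
        self._wire_parents(root)
        self._validate()

    @staticmethod
    def _wire_parents(node: TreeNode) -> None:
        for child in node.children:
            child.parent = node
            TimeTree._wire_parents(child)

    def _validate(self) -> None:
        labels: list[str] = []
        for node in self.preorder():
            if node is not self.root:
                bl = node.branch_length_my
                if bl is None or (isinstance(bl, float) and math.isnan(bl)):
                    raise NewickError(
                        f"unlengthed edge above node {node.label or '<internal>'}"
                    )
                if bl < 0:
                    raise NewickError(f"negative branch length {bl}")
            if node.is_leaf:
                if not node.label:
                    raise NewickError("leaf without a label")
                labels.append(node.label)
        dupes = {l for l in labels if labels.count(l) > 1}
        if dupes:
            raise NewickError(f"duplicate leaf label(s): {sorted(dupes)}")

    # -- traversal ---------------------------------------------------------

    def preorder(self) -> Iterator[TreeNode]:
        stack = [self.root]
        while stack:
            node = stack.pop()
            yield node
            stack.extend(reversed(node.children))

    def postorder(self) -> Iterator[TreeNode]:
        out: list[TreeNode] = []
        stack = [self.root]
        while stack:
            node = stack.pop()
            out.append(node)
            stack.extend(node.children)
        return iter(reversed(out))

    def leaves(self) -> list[TreeNode]:
        return [n for n in self.preorder() if n.is_leaf]

    def leaf_labels(self) -> list[str]:
        return [n.label for n in self.leaves()]  # type: ignore[misc]

    @property
    def total_time_my(self) -> float:
        """Total time elapsed on the tree: the sum of all branch durations."""
        return sum(
            n.branch_length_my for n in self.preorder() if n is not self.root
        )

    # -- serialisation -----------------------------------------------------

    def to_newick(self) -> str:
        def fmt(node: TreeNode) -> str:
            if node.is_leaf:
                core = node.label or ""
            else:
                core = "(" + ",".join(fmt(c) for c in node.children) + ")"
            if node.parent is None:
                return core
            return f"{core}:{node.branch_length_my:g}"

        return fmt(self.root) + ";"

    def copy(self) -> "TimeTree":
        def clone(node: TreeNode) -> TreeNode:
            return TreeNode(
                label=node.label,
                branch_length_my=node.branch_length_my,
                children=[clone(c) for c in node.children],
            )

        return TimeTree(clone(self.root))

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"TimeTree(n_leaves={len(self.leaves())}, "
            f"total_time_my={self.total_time_my:g})"
        )


def parse_newick(text: str) -> TimeTree:
    """Parse a Newick string into a :class:`TimeTree`.

    Branch lengths are interpreted as millions of years and are mandatory on
    every non-root edge; an edge without one raises :class:`NewickError`
    rather than silently defaulting.
    """
    try:
        dtree = dendropy.Tree.get(
            data=text,
            schema="newick",
            suppress_internal_node_taxa=True,
        )
    except Exception as exc:  # dendropy raises a zoo of DataError subclasses
        line = getattr(exc, "line_num", None)
        col = getattr(exc, "col_num", None)
        loc = f" (line {line}, column {col})" if col is not None else ""
        raise NewickError(f"malformed Newick{loc}: {exc}") from exc

    def convert(dnode: dendropy.Node, is_root: bool) -> TreeNode:
        label = dnode.taxon.label if dnode.taxon is not None else None
        length = dnode.edge.length
        if not is_root and length is None:
            raise NewickError(
                f"unlengthed edge above node {label or '<internal>'}"
            )
        node = TreeNode(
            label=label,
            branch_length_my=0.0 if is_root else float(length),
        )
        node.children = [convert(c, False) for c in dnode.child_nodes()]
        return node

    return TimeTree(convert(dtree.seed_node, True))


def total_tree_time(tree: TimeTree) -> float:
    """Sum of all branch durations of *tree*, in millions of years."""
    return tree.total_time_my


# ---------------------------------------------------------------------------
# SiteColumn
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SiteColumn:
    """Per-species residues at one reference (human) genomic position.

    ``residues`` maps taxon label to one of A/C/G/T, :data:`GAP` or
    :data:`MISSING`.  The reference taxon must carry a real base — a column
    without a human base has no human coordinate and is never constructed.
    Coordinates are 1-based; ``assembly`` is opaque metadata (e.g.
    ``"B37/hg19"``).
    """

    chrom: str
    pos: int
    reference_taxon: str
    residues: Mapping[str, str]
    assembly: str = "B37/hg19"

    def __post_init__(self) -> None:
        ref = self.residues.get(self.reference_taxon)
        if ref not in BASES:
            raise ColumnError(
                f"reference taxon {self.reference_taxon!r} has no base "
                f"(got {ref!r}) at {self.chrom}:{self.pos}"
            )
        bad = {r for r in self.residues.values() if r not in VALID_RESIDUES}
        if bad:
            raise ColumnError(f"unknown residue character(s): {sorted(bad)}")

    @property
    def position_id(self) -> str:
        return f"{self.chrom}:{self.pos}"

    def present_taxa(self) -> list[str]:
        """Taxa with a real base (gap and missing both count as absent)."""
        return sorted(t for t, r in self.residues.items() if r in BASES)


def _normalise_residue(ch: str) -> str:
    c = ch.upper()
    if c in BASES:
        return c
    if c == "-":
        return GAP
    if c in {"N", "?", "*"}:
        return MISSING
    raise ColumnError(f"unknown residue character {ch!r}")


# -- aligned FASTA ----------------------------------------------------------

def _columns_from_rows(
    rows: Mapping[str, str],
    reference_taxon: str,
    chrom: str,
    start_pos: int,
    assembly: str,
) -> Iterator[SiteColumn]:
    """Columns of an aligned block keyed to reference coordinates.

    Alignment columns where the reference has a gap have no human coordinate
    and are skipped; a reference ``N`` consumes a coordinate but yields no
    column (no human base), with a logged warning.
    """
    ref_row = rows[reference_taxon]
    pos = start_pos
    for i, ref_ch in enumerate(ref_row):
        ref_res = _normalise_residue(ref_ch)
        if ref_res == GAP:
            continue
        if ref_res == MISSING:
            logger.warning(
                "skipping %s:%d: reference base is N/unknown", chrom, pos
            )
            pos += 1
            continue
        residues = {
            taxon: _normalise_residue(row[i]) for taxon, row in rows.items()
        }
        yield SiteColumn(
            chrom=chrom,
            pos=pos,
            reference_taxon=reference_taxon,
            residues=residues,
            assembly=assembly,
        )
        pos += 1


def read_columns_fasta(
    source: Union[str, IO[str]],
    reference_taxon: str,
    chrom: str = "chrUn",
    start_pos: int = 1,
    assembly: str = "B37/hg19",
) -> list[SiteColumn]:
    """Read aligned FASTA rows and emit one column per reference base.

    Rows must be equal length; the record ids are the taxon labels.
    """
    from Bio import SeqIO

    rows: dict[str, str] = {}
    for rec in SeqIO.parse(source, "fasta"):
        rows[rec.id] = str(rec.seq)
    if reference_taxon not in rows:
        raise ColumnError(f"reference taxon {reference_taxon!r} absent from FASTA")
    lengths = {len(s) for s in rows.values()}
    if len(lengths) > 1:
        raise ColumnError(f"unequal aligned row lengths: {sorted(lengths)}")
    return list(
        _columns_from_rows(rows, reference_taxon, chrom, start_pos, assembly)
    )


# -- MAF --------------------------------------------------------------------

def read_columns_maf(
    source: Union[str, IO[str]],
    reference_taxon: str,
    assembly: str = "B37/hg19",
) -> list[SiteColumn]:
    """Read UCSC MAF blocks and emit one column per reference base.

    Sequence ids are ``species.chrom``; the species part is matched against
    ``reference_taxon``.  Species absent from a block are recorded as
    :data:`MISSING` for the positions of that block.  MAF ``start`` is
    0-based; emitted coordinates are 1-based.  All known species (union over
    blocks) get a residue in every column.
    """
    from Bio import AlignIO

    blocks = []
    all_species: set[str] = set()
    for alignment in AlignIO.parse(source, "maf"):
        rows: dict[str, tuple[str, str, int]] = {}
        for rec in alignment:
            species, _, seqchrom = rec.id.partition(".")
            rows[species] = (str(rec.seq), seqchrom, rec.annotations["start"])
        all_species.update(rows)
        blocks.append(rows)
    if not any(reference_taxon in rows for rows in blocks):
        raise ColumnError(f"reference taxon {reference_taxon!r} absent from MAF")

    columns: list[SiteColumn] = []
    for rows in blocks:
        if reference_taxon not in rows:
            continue
        ref_seq, ref_chrom, ref_start = rows[reference_taxon]
        aligned = {sp: seq for sp, (seq, _, _) in rows.items()}
        padded = dict(aligned)
        for sp in all_species - set(aligned):
            padded[sp] = "N" * len(ref_seq)
        columns.extend(
            _columns_from_rows(
                padded,
                reference_taxon,
                chrom=ref_chrom or "chrUn",
                start_pos=ref_start + 1,
                assembly=assembly,
            )
        )
    return columns


# -- per-position TSV -------------------------------------------------------

def read_columns_tsv(
    source: Union[str, IO[str]],
    reference_taxon: str,
    assembly: str = "B37/hg19",
) -> list[SiteColumn]:
    """Read a per-position table: one row per position, one column per taxon.

    Optional leading ``chrom`` and ``pos`` columns give coordinates;
    otherwise positions are enumerated from 1 on ``chrUn``.
    """
    import pandas as pd

    df = pd.read_csv(source, sep="\t", dtype=str)
    meta = [c for c in df.columns if c.lower() in {"chrom", "pos"}]
    taxa = [c for c in df.columns if c not in meta]
    if reference_taxon not in taxa:
        raise ColumnError(f"reference taxon {reference_taxon!r} absent from TSV")

    columns: list[SiteColumn] = []
    for i, row in df.iterrows():
        chrom = str(row["chrom"]) if "chrom" in df.columns else "chrUn"
        pos = int(row["pos"]) if "pos" in df.columns else i + 1
        residues = {t: _normalise_residue(str(row[t])) for t in taxa}
        if residues[reference_taxon] not in BASES:
            logger.warning("skipping %s:%s: no reference base", chrom, pos)
            continue
        columns.append(
            SiteColumn(
                chrom=chrom,
                pos=pos,
                reference_taxon=reference_taxon,
                residues=residues,
                assembly=assembly,
            )
        )
    return columns


def read_columns(
    source: Union[str, IO[str]],
    reference_taxon: str,
    fmt: str = "tsv",
    **kwargs,
) -> list[SiteColumn]:
    """Dispatch to the MAF / aligned-FASTA / TSV column readers by *fmt*."""
    readers = {
        "maf": read_columns_maf,
        "fasta": read_columns_fasta,
        "tsv": read_columns_tsv,
    }
    if fmt not in readers:
        raise ValueError(f"unknown column format {fmt!r}; use one of {sorted(readers)}")
    return readers[fmt](source, reference_taxon, **kwargs)


# ---------------------------------------------------------------------------
# Metric output
# ---------------------------------------------------------------------------

SITE_METRIC_FIELDS = [
    "chrom",
    "pos",
    "evol_rate",
    "evol_span_fraction",
    "evol_span_my",
    "n_present_taxa",
    "conservation_class",
]


def write_site_metrics(records: Sequence, sink: Union[str, IO[str]]) -> None:
    """Write per-position metrics as TSV, 6 significant digits.

    *records* is a non-empty sequence of ``(SiteColumn, SiteEvolution)``
    pairs; an undefined rate (human-only position) is written as ``NA``.
    """
    if not records:
        raise ValueError("no site metric records to write")

    def fmt(x) -> str:
        if x is None:
            return "NA"
        if isinstance(x, float):
            return f"{x:.6g}"
        return str(x)

    lines = ["\t".join(SITE_METRIC_FIELDS)]
    for column, ev in records:
        lines.append(
            "\t".join(
                fmt(v)
                for v in (
                    column.chrom,
                    column.pos,
                    ev.evol_rate,
                    ev.evol_span_fraction,
                    ev.evol_span_my,
                    ev.n_present_taxa,
                    ev.conservation_class,
                )
            )
        )
    text = "\n".join(lines) + "\n"
    if hasattr(sink, "write"):
        sink.write(text)
    else:
        with open(sink, "w") as fh:
            fh.write(text)


def read_site_metrics(source: Union[str, IO[str]]):
    """Read a site-metrics TSV back into a DataFrame (``NA`` → NaN rate)."""
    import pandas as pd

    return pd.read_csv(source, sep="\t", na_values=["NA"])
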