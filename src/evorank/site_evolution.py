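"""Per-position evolutionary rate, timespan and conservation class.

Given a time-calibrated species tree and the per-species residues at one
human genomic position, this module computes:

``evol_rate``
    the minimum number of nucleotide substitutions needed to explain the
    observed bases on the phylogeny (small-parsimony count), divided by the
    total time elapsed on the subtree of species in which the position
    exists, reported in substitutions per site per billion years.  Low
    values indicate conservation.

``evol_span``
    the fraction of total evolutionary time on the tree during which the
    position has existed — the summed branch time of the minimal spanning
    subtree connecting the species that carry a base, over the full tree's
    total time.

``conservation_class``
    ultra-conserved (rate = 0), well-conserved (0 < rate ≤ 1) or
    less-conserved (rate > 1).

A position present only in the reference lineage permits no cross-species
comparison: its rate is *undefined* (``None``, class ``unclassified``), not
zero, because zero would assert perfect conservation.
"""

from __future__ import annotations

from dataclasses import dataclass

from .phylo_io import BASES, SiteColumn, TimeTree, TreeNode

ULTRA = "ultra"
WELL = "well"
LESS = "less"
UNCLASSIFIED = "unclassified"

#: My → Gy conversion; rates are reported per billion years.
MY_PER_GY = 1000.0


@dataclass(frozen=True)
class SiteEvolution:
    """Evolutionary context of one genomic position.

    ``evol_rate`` is ``None`` when the position exists only in the
    reference lineage (no comparison possible).
    """

    evol_rate: float | None
    evol_span_fraction: float
    evol_span_my: float
    n_substitutions: int
    n_present_taxa: int
    conservation_class: str


class PruningError(ValueError):
    """Raised when a column and tree disagree about which taxa exist."""


def prune_to_present(tree: TimeTree, column: SiteColumn) -> TimeTree:
    """Minimal spanning subtree over the taxa where the position exists.

    Keeps exactly the leaves whose residue is a real base, drops everything
    else, collapses the resulting degree-2 internal nodes (summing their
    branch durations) and re-roots at the MRCA of the kept leaves.  A
    column private to the reference yields a single-leaf tree with zero
    total time — valid, not an error.
    """
    present = set(column.present_taxa())
    leaf_labels = set(tree.leaf_labels())
    unknown = present - leaf_labels
    if unknown:
        raise PruningError(
            f"taxa with bases but absent from tree: {sorted(unknown)}"
        )

    def build(node: TreeNode) -> TreeNode | None:
        if node.is_leaf:
            if node.label in present:
                return TreeNode(
                    label=node.label, branch_length_my=node.branch_length_my
                )
            return None
        kept = [c for c in (build(ch) for ch in node.children) if c is not None]
        if not kept:
            return None
        if len(kept) == 1:
            # degree-2 collapse: fold this node's own branch into the child
            child = kept[0]
            child.branch_length_my += node.branch_length_my
            return child
        new = TreeNode(branch_length_my=node.branch_length_my, children=kept)
        return new

    sub = build(tree.root)
    if sub is None:  # unreachable: reference always present
        raise PruningError("no present taxa to prune to")
    # the new root is the MRCA; its own (collapsed) stem carries no time
    sub.branch_length_my = 0.0
    return TimeTree(sub)


def count_substitutions_fitch(tree: TimeTree, column: SiteColumn) -> int:
    """Minimum number of base changes on *tree* explaining *column*.

    Small-parsimony count via the Fitch–Hartigan downpass, which is exact
    for multifurcating trees as well (pruning can create polytomies when
    the input tree is not binary).  The tree must already be pruned: every
    leaf must carry a real base in the column.
    """
    cost = 0
    sets: dict[int, frozenset[str]] = {}
    for node in tree.postorder():
        if node.is_leaf:
            base = column.residues.get(node.label)  # type: ignore[arg-type]
            if base not in BASES:
                raise PruningError(
                    f"leaf {node.label!r} has no base in column "
                    f"{column.position_id} (pruning contract violated)"
                )
            sets[id(node)] = frozenset((base,))
            continue
        counts: dict[str, int] = {}
        for child in node.children:
            for state in sets[id(child)]:
                counts[state] = counts.get(state, 0) + 1
        m = max(counts.values())
        sets[id(node)] = frozenset(s for s, c in counts.items() if c == m)
        cost += len(node.children) - m
    return cost


def evol_rate(tree: TimeTree, column: SiteColumn) -> float | None:
    """Substitutions per site per billion years at this position.

    Counts parsimony substitutions on the pruned (present-taxa) subtree and
    divides by that subtree's total time.  Returns ``None`` when the
    position exists only in the reference lineage — no comparison is
    possible there and 0 would wrongly assert conservation.
    """
    pruned = prune_to_present(tree, column)
    if len(pruned.leaves()) < 2:
        return None
    time_gy = pruned.total_time_my / MY_PER_GY
    if time_gy <= 0:
        raise ValueError(
            f"pruned subtree at {column.position_id} has zero total time"
        )
    return count_substitutions_fitch(pruned, column) / time_gy


def evol_span(tree: TimeTree, column: SiteColumn) -> tuple[float, float]:
    """(fraction, My) of evolutionary time during which the position existed.

    The absolute span is the total time of the pruned subtree; the fraction
    divides by the *full* tree's total time so values are comparable across
    positions.  A reference-private position spans 0.
    """
    pruned = prune_to_present(tree, column)
    span_my = pruned.total_time_my if len(pruned.leaves()) >= 2 else 0.0
    total = tree.total_time_my
    fraction = span_my / total if total > 0 else 0.0
    return fraction, span_my


def classify_conservation(rate: float | None) -> str:
    """Conservation class from the evolutionary rate.

    rate = 0 → ``ultra``; 0 < rate ≤ 1 → ``well``; rate > 1 → ``less``.
    The boundary at exactly 1 belongs to ``well`` (only "greater than one"
    is less-conserved).  An undefined rate is ``unclassified`` — never a
    default class.
    """
    if rate is None:
        return UNCLASSIFIED
    if rate < 0:
        raise ValueError(f"negative evolutionary rate {rate}")
    if rate == 0:
        return ULTRA
    if rate <= 1.0:
        return WELL
    return LESS


def site_evolution(tree: TimeTree, column: SiteColumn) -> SiteEvolution:
    """Full evolutionary context of one position on one tree."""
    pruned = prune_to_present(tree, column)
    n_present = len(pruned.leaves())
    if n_present < 2:
        return SiteEvolution(
            evol_rate=None,
            evol_span_fraction=0.0,
            evol_span_my=0.0,
            n_substitutions=0,
            n_present_taxa=n_present,
            conservation_class=UNCLASSIFIED,
        )
    n_subs = count_substitutions_fitch(pruned, column)
    span_my = pruned.total_time_my
    rate = n_subs / (span_my / MY_PER_GY)
    total = tree.total_time_my
    return SiteEvolution(
        evol_rate=rate,
        evol_span_fraction=span_my / total,
        evol_span_my=span_my,
        n_substitutions=n_subs,
        n_present_taxa=n_present,
        conservation_class=classify_conservation(rate),
    )
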