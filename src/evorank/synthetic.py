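"""Synthetic trees, alignment columns and association tables with truth.

Everything downstream is testable without any external download: a
Yule-type ultrametric time tree stands in for the mammalian species
phylogeny, a Poisson substitution process with uniform base changes
(Jukes–Cantor-like) generates alignment columns with a known per-site rate,
clade-level deletions emulate lineage-level loss of a position (the
biological reading of evolutionary timespan), and a two-component P-value
mixture emulates a GWAS catalogue study export.

All generators are deterministic per seed; substreams are derived from the
single global seed via ``numpy.random.SeedSequence.spawn`` keyed by
generator order, so each fixture is reproducible in isolation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .phylo_io import GAP, SiteColumn, TimeTree, TreeNode

REGION_CHOICES = [
    "intron",
    "missense",
    "synonymous",
    "3'UTR",
    "5'UTR",
    "intergenic",
    "other",
]

GENE_POOL = ["LTA", "TNF", "APOE", "TCF7L2", "FTO", "IL6", "BRCA2", ""]


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic generators.

    The defaults are the conditions under which the package's recovery and
    ranking properties are exercised: an 8-taxon, 100-My-deep ultrametric
    tree; per-site true rates spanning ultra- to less-conserved
    (0–4 subs/site/Gy); a 5% chance per internal edge of losing the
    subtending clade; and a GWAS-catalogue-like table in which 10% of SNPs
    are "signal" (P = 10^−U, U ~ Uniform(5, 10)) and the rest draw P
    uniformly from (10^−5, 0.05], with MAF ~ Uniform(0.01, 0.5).
    """

    n_taxa: int = 8
    tree_depth_my: float = 100.0
    rate_grid: tuple[float, ...] = (0.0, 0.25, 0.5, 1.0, 2.0, 4.0)
    gap_prob: float = 0.05
    n_sites: int = 200
    n_snps: int = 100
    n_studies: int = 3
    n_phenotypes: int = 5
    signal_fraction: float = 0.1
    maf_range: tuple[float, float] = (0.01, 0.5)
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.gap_prob < 1:
            raise ValueError("gap_prob must be in [0, 1)")
        if not 0 <= self.signal_fraction <= 1:
            raise ValueError("signal_fraction must be in [0, 1]")


def _rng(seed: int, *key: int) -> np.random.Generator:
    """Substream generator: global seed + integer key path."""
    return np.random.default_rng(np.random.SeedSequence([int(seed), *key]))


def simulate_time_tree(
    n_taxa: int, depth_my: float, seed: int
) -> TimeTree:
    """Rooted ultrametric tree from a Yule-type pure-birth process.

    Starting from the root split, a uniformly chosen extant lineage splits
    at each of n−1 event times; node heights are then scaled so every leaf
    sits exactly ``depth_my`` below the root.  Deterministic per seed.
    """
    if n_taxa < 2:
        raise ValueError("need at least 2 taxa")
    if depth_my <= 0:
        raise ValueError("tree depth must be positive")
    rng = _rng(seed, 1)

    # event times: exponential waits with rate = current lineage count
    times = [0.0]
    t = 0.0
    for k in range(2, n_taxa):
        t += rng.exponential(1.0 / k)
        times.append(t)
    # leaves sit at max event time + one more wait
    t_leaf = t + rng.exponential(1.0 / n_taxa)
    scale = depth_my / t_leaf

    # grow topology: active = list of (parent_node, height_of_parent)
    root = TreeNode()
    active: list[tuple[TreeNode, float]] = []
    heights: dict[int, float] = {id(root): 0.0}

    def split(node: TreeNode, height: float) -> None:
        for _ in range(2):
            child = TreeNode()
            node.children.append(child)
            active.append((child, height))

    split(root, 0.0)
    for event_time in times[1:]:
        i = int(rng.integers(len(active)))
        node, parent_h = active.pop(i)
        h = event_time * scale
        node.branch_length_my = h - parent_h
        heights[id(node)] = h
        split(node, h)
    labels = iter(f"t{i+1}" for i in range(n_taxa))
    for node, parent_h in active:
        node.label = next(labels)
        node.branch_length_my = depth_my - parent_h
    return TimeTree(root)


@dataclass
class ColumnTruth:
    """Ground truth behind one simulated column."""

    true_rate: float
    n_events_total: int
    n_events_observable: int  # events on the spanning subtree of present taxa
    deleted_clades: list[str] = field(default_factory=list)
    events: list[tuple[str, str, str]] = field(default_factory=list)


def simulate_column(
    tree: TimeTree,
    rate: float,
    gap_prob: float,
    seed: int,
    reference_taxon: str | None = None,
    chrom: str = "chrSim",
    pos: int = 1,
) -> tuple[SiteColumn, ColumnTruth]:
    """One alignment column evolved on *tree* at a known rate.

    The root base is uniform on {A,C,G,T}; on each branch the substitution
    count is Poisson(rate × branch_time_Gy) and each substitution moves to
    a uniformly chosen *different* base.  Independently, each internal edge
    deletes its whole subtending clade (all leaves become gaps) with
    probability ``gap_prob`` — edges on the root-to-reference path are
    exempt so the reference always keeps a base.

    Returns the column plus a :class:`ColumnTruth` with the event list,
    deleted clades, and the count of events on the spanning subtree of the
    surviving taxa (the observable ones).
    """
    if rate < 0:
        raise ValueError("rate must be ≥ 0")
    if not 0 <= gap_prob < 1:
        raise ValueError("gap_prob must be in [0, 1)")
    rng = _rng(seed, 2)
    leaves = tree.leaves()
    if reference_taxon is None:
        reference_taxon = leaves[0].label

    # path from root to reference (node ids) — exempt from deletion
    ref_path: set[int] = set()

    def find(node: TreeNode) -> bool:
        if node.label == reference_taxon:
            ref_path.add(id(node))
            return True
        for c in node.children:
            if find(c):
                ref_path.add(id(node))
                return True
        return False

    if not find(tree.root):
        raise ValueError(f"reference taxon {reference_taxon!r} not in tree")

    bases = "ACGT"
    root_base = bases[rng.integers(4)]
    truth = ColumnTruth(true_rate=rate, n_events_total=0, n_events_observable=0)
    residues: dict[str, str] = {}
    events_by_node: dict[int, int] = {}

    def walk(node: TreeNode, state: str, deleted: bool) -> None:
        if node is not tree.root:
            # deletion of the subtending clade (internal edges only)
            if (
                not deleted
                and not node.is_leaf
                and id(node) not in ref_path
                and rng.random() < gap_prob
            ):
                deleted = True
                truth.deleted_clades.append(
                    ",".join(l.label for l in _subtree_leaves(node))
                )
            k = rng.poisson(rate * node.branch_length_my / 1000.0)
            events_by_node[id(node)] = k
            for _ in range(k):
                new_state = rng.choice([b for b in bases if b != state])
                truth.events.append((node.label or "<internal>", state, new_state))
                state = new_state
                truth.n_events_total += 1
        if node.is_leaf:
            residues[node.label] = GAP if deleted else state  # type: ignore[index]
        for c in node.children:
            walk(c, state, deleted)

    walk(tree.root, root_base, False)

    column = SiteColumn(
        chrom=chrom,
        pos=pos,
        reference_taxon=reference_taxon,
        residues=residues,
    )

    # observable events: those on edges of the spanning subtree of the
    # present leaves, i.e. below their MRCA and leading to ≥1 present leaf
    present = set(column.present_taxa())

    def mrca(node: TreeNode) -> TreeNode:
        while True:
            kids = [c for c in node.children if _subtree_leafset(c) & present]
            if len(kids) == 1:
                node = kids[0]
            else:
                return node

    anchor = mrca(tree.root)

    def count_obs(node: TreeNode) -> None:
        for c in node.children:
            if _subtree_leafset(c) & present:
                truth.n_events_observable += events_by_node.get(id(c), 0)
                count_obs(c)

    count_obs(anchor)
    return column, truth


def _subtree_leaves(node: TreeNode) -> list[TreeNode]:
    if node.is_leaf:
        return [node]
    out: list[TreeNode] = []
    for c in node.children:
        out.extend(_subtree_leaves(c))
    return out


def _subtree_leafset(node: TreeNode) -> set[str]:
    return {l.label for l in _subtree_leaves(node)}  # type: ignore[misc]


def simulate_columns(
    tree: TimeTree,
    config: SimulationConfig,
    reference_taxon: str | None = None,
) -> list[tuple[SiteColumn, ColumnTruth]]:
    """``n_sites`` columns cycling through the config's true-rate grid."""
    out = []
    for i in range(config.n_sites):
        rate = config.rate_grid[i % len(config.rate_grid)]
        col, truth = simulate_column(
            tree,
            rate,
            config.gap_prob,
            seed=config.seed * 1_000_003 + i,
            reference_taxon=reference_taxon,
            pos=i + 1,
        )
        out.append((col, truth))
    return out


def simulate_association_table(
    config: SimulationConfig,
) -> tuple[pd.DataFrame, pd.Series]:
    """A GWAS-catalogue-like study export plus per-SNP truth labels.

    Returns ``(table, is_signal)``.  Signal SNPs draw P = 10^−U with
    U ~ Uniform(5, 10); null SNPs draw P ~ Uniform(10^−5, 0.05].  Every row
    satisfies the store's ingest invariants (P ≤ 0.05, unique keys), so
    ingest accepts the table with zero rejections.
    """
    rng = _rng(config.seed, 3)
    n = config.n_snps
    n_signal = int(round(config.signal_fraction * n))
    is_signal = np.zeros(n, dtype=bool)
    is_signal[rng.choice(n, size=n_signal, replace=False)] = True

    p = np.empty(n)
    u = rng.uniform(5.0, 10.0, size=n)
    p_null = rng.uniform(1e-5, 0.05, size=n)
    p[is_signal] = 10.0 ** (-u[is_signal])
    p[~is_signal] = p_null[~is_signal]

    maf = rng.uniform(*config.maf_range, size=n)
    alleles = rng.choice(list("ACGT"), size=n)
    chroms = rng.integers(1, 23, size=n)
    positions = rng.integers(1, 250_000_000, size=n)
    regions = rng.choice(REGION_CHOICES, size=n)
    genes = rng.choice(GENE_POOL, size=n)
    pmids = rng.integers(0, config.n_studies, size=n)
    phenos = rng.integers(0, config.n_phenotypes, size=n)

    table = pd.DataFrame(
        {
            "rsid": [f"rs{1_000_000 + i}" for i in range(n)],
            "pmid": [f"{20000000 + int(j)}" for j in pmids],
            "study_title": [
                f"Genome-wide study {int(j) + 1} of simulated traits"
                for j in pmids
            ],
            "phenotype": [f"trait_{int(j) + 1}" for j in phenos],
            "phenotype_category": [
                f"category_{int(j) % 3 + 1}" for j in phenos
            ],
            "p_value": p,
            "allele": alleles,
            "maf": maf,
            "chrom": [f"chr{int(c)}" for c in chroms],
            "pos": positions,
            "region_type": regions,
            "gene": genes,
            "aa_change": ["" for _ in range(n)],
            "polyphen2": ["" for _ in range(n)],
            "sift": ["" for _ in range(n)],
            "evod": ["" for _ in range(n)],
        }
    )
    return table, pd.Series(is_signal, index=table["rsid"].to_numpy(), name="is_signal")


def simulate_ranked_input(
    config: SimulationConfig,
) -> pd.DataFrame:
    """Association table joined with simulated per-SNP evolutionary context.

    One alignment column per SNP is evolved on a fresh tree at a rate drawn
    from the config's grid; the measured rate/span (not the truth) annotate
    the table, so the output is exactly what the ranking step consumes in
    practice.
    """
    from .site_evolution import site_evolution

    table, _ = simulate_association_table(config)
    tree = simulate_time_tree(config.n_taxa, config.tree_depth_my, config.seed)
    rng = _rng(config.seed, 4)
    rates, spans = [], []
    for i in range(len(table)):
        true_rate = config.rate_grid[int(rng.integers(len(config.rate_grid)))]
        col, _ = simulate_column(
            tree,
            true_rate,
            config.gap_prob,
            seed=config.seed * 2_000_003 + i,
            pos=i + 1,
        )
        ev = site_evolution(tree, col)
        rates.append(ev.evol_rate)
        spans.append(ev.evol_span_fraction)
    table = table.copy()
    table["evol_rate"] = rates
    table["evol_span"] = spans
    return table
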