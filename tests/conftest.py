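import itertools
import math
from pathlib import Path

import pytest

from evorank.phylo_io import BASES, SiteColumn, TimeTree, parse_newick

DATA = Path(__file__).parent / "data"

#: ((H,B),(C,D)) with 100-My leaf edges and 400-My internal edges.
FOUR_TAXON_NEWICK = "((H:100,B:100):400,(C:100,D:100):400);"


@pytest.fixture
def four_taxon_tree() -> TimeTree:
    return parse_newick(FOUR_TAXON_NEWICK)


@pytest.fixture
def fixture_associations_path() -> Path:
    return DATA / "associations_5.tsv"


def make_column(bases: dict[str, str], ref: str = "H", pos: int = 1) -> SiteColumn:
    return SiteColumn(chrom="chr1", pos=pos, reference_taxon=ref, residues=bases)


def brute_force_parsimony(tree: TimeTree, column: SiteColumn) -> int:
    """Independent small-parsimony oracle: exhaustive minimum over all
    internal-node base assignments of the number of edges whose endpoints
    disagree.  Exponential; only for tiny trees."""
    internals = [n for n in tree.preorder() if not n.is_leaf]
    leaves = tree.leaves()
    for leaf in leaves:
        assert column.residues[leaf.label] in BASES
    best = math.inf
    for labeling in itertools.product("ACGT", repeat=len(internals)):
        state = {id(n): b for n, b in zip(internals, labeling)}
        for leaf in leaves:
            state[id(leaf)] = column.residues[leaf.label]
        cost = 0
        for node in tree.preorder():
            if node is tree.root:
                continue
            if state[id(node)] != state[id(node.parent)]:
                cost += 1
        best = min(best, cost)
    return int(best)
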