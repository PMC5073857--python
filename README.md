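# evorank

Evolutionary context for GWAS variants, and an evolutionarily adjusted
ranking of their association P-values.

Genome-wide association studies report millions of SNP–phenotype
associations, most of which are not causal. Variants sitting at genomic
positions that evolve slowly across species, and that have existed for a
long stretch of evolutionary time, are more likely to be functionally
important. `evorank` quantifies both properties per position from a
multi-species alignment on a time-calibrated phylogeny and folds them,
together with the minor allele frequency, into a rank-based adjustment of
the association P-value. It is a library plus a `evorank` command-line
tool for analysts who want to prioritise GWAS hits with cross-species
conservation without depending on any hosted service.

## What it computes

For each human genomic position with residues across N species on a tree
with branch lengths in millions of years (My):

* **Evol_Rate** — the minimum number of nucleotide substitutions
  explaining the observed bases (Fitch–Hartigan small parsimony), divided
  by the total time of the subtree of species in which the position
  exists, in substitutions/site/**Gy**. Classes: `ultra` (rate = 0),
  `well` (0 < rate ≤ 1), `less` (rate > 1).
* **Evol_Span** — the fraction of the full tree's total branch time
  covered by the minimal spanning subtree of the species that carry a
  base at the position (also reported in absolute My).

For a set of association records (one study or query result), with
K_r = within-set rank of Evol_Rate (descending: most conserved = N) and
K_t = within-set rank of Evol_Span (ascending: longest span = N):

    e_score = (P / MAF) · 1 / (K_r · K_t)

Sorting by `e_score` gives the **E-rank** ordering; comparing it with the
raw **P-rank** ordering (and plotting E-rank vs P-rank, or the E−P
difference per SNP) shows which SNPs the evolutionary adjustment
promotes. See `docs/methods.md` for assumptions, parameter choices and
limitations.

## Worked example

```python
import evorank as ev

tree = ev.parse_newick("((human:100,chimp:100):400,(mouse:100,rat:100):400);")
col = ev.SiteColumn("chr6", 31540784, "human",
                    {"human": "A", "chimp": "A", "mouse": "G", "rat": "G"})
print(ev.site_evolution(tree, col))
```

```
SiteEvolution(evol_rate=0.8333333333333334, evol_span_fraction=1.0,
              evol_span_my=1200.0, n_substitutions=1, n_present_taxa=4,
              conservation_class='well')
```

One substitution (the A↔G split between primates and rodents) over the
1200 My summed across all branches gives 1/1.2 ≈ 0.83 substitutions per
site per billion years — a well-conserved site present in all four
species (span fraction 1.0).

Ranking three SNPs of one study:

```python
records = [
    {"rsid": "rs1", "p_value": 1e-8, "maf": 0.3, "evol_rate": 0.0, "evol_span": 1.0},
    {"rsid": "rs2", "p_value": 1e-8, "maf": 0.3, "evol_rate": 2.0, "evol_span": 0.2},
    {"rsid": "rs3", "p_value": 1e-3, "maf": 0.3, "evol_rate": 0.0, "evol_span": 1.0},
]
ranked, excluded = ev.compute_rankings(records)
print(ev.rankings_frame(ranked).to_string(index=False))
```

```
rsid      p_value  maf  evol_rate  evol_span  k_r  k_t      e_score  p_rank  e_rank_ordinal  rank_diff
 rs1 1.000000e-08  0.3        0.0        1.0  2.5  2.5 5.333333e-09       1               1          0
 rs2 1.000000e-08  0.3        2.0        0.2  1.0  1.0 3.333333e-08       2               2          0
 rs3 1.000000e-03  0.3        0.0        1.0  2.5  2.5 5.333333e-04       3               3          0
```

rs1 and rs2 tie on P, but rs1 sits at an ultra-conserved, full-span site
(K_r·K_t = 6.25) while rs2 is fast-evolving and short-span
(K_r·K_t = 1), so rs1's `e_score` is ~6× smaller and it leads the E-rank
ordering.

## Command line

```sh
evorank simulate --what columns --seed 1 --out sim/     # tree + columns + truth
evorank site-metrics --tree sim/tree.nwk --alignment sim/columns.tsv \
        --format tsv --reference t1 --out metrics.tsv
evorank erank --associations study.tsv --site-metrics metrics.tsv --out rankings.tsv
evorank plot-data --rankings rankings.tsv --kind scatter --out scatter.tsv
evorank plot --rankings rankings.tsv --kind diff --out bars.png
evorank filter --associations study.tsv --max-p 1e-5 --gene LTA --out hits.tsv
evorank summarize --associations study.tsv --by snp --sort-key min_p --out by_snp.tsv
```

Alignment columns are read from UCSC-style MAF, aligned FASTA, or a
per-position species×base TSV; trees from Newick with branch lengths in
My. Association tables are TSV/CSV with at least
`rsid, pmid, phenotype, p_value, maf` (rows with P > 0.05 are rejected
and reported, matching the source catalogue's inclusion rule).

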