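# Methods

## Scope and model

`evorank` computes per-position evolutionary context from a multi-species
alignment on a time-calibrated phylogeny and uses it to re-rank GWAS
association records. The phylogeny is a rooted tree whose branch lengths
are durations in millions of years (My); the alignment is consumed one
column at a time, keyed to 1-based reference (human) coordinates.

### Evolutionary rate

For one position, the substitution count is the small-parsimony score of
the observed leaf bases: the minimum number of state changes over all
assignments of bases to internal nodes. We use the Fitch–Hartigan
downpass, which returns the exact minimum on multifurcating trees as well
(binary Fitch is the special case). Parsimony was chosen over
likelihood-based counting because it is deterministic, assumption-light
and exactly testable against a brute-force enumeration oracle; the
trade-off is the usual one — parsimony cannot see multiple hits on a
single branch, so it *underestimates* at high rates. The test suite and
acceptance script therefore assert *monotone* recovery of the true rate
(recovered means at simulated true rates 0–4 substitutions/site/Gy are
strictly increasing, and exactly 0 at true rate 0), not unbiasedness.

The rate is the count divided by elapsed time, reported in substitutions
per site per **billion** years (branch lengths in My are divided by 1000
at the last step). The denominator is the total time of the subtree
**pruned to the species in which the position exists**, not the full
tree: substitutions are only observable where the position exists, and a
full-tree denominator would systematically deflate rates at short-span
positions. This is a genuine design choice — the definition "total time
elapsed on the tree" does not pin down which tree — and the pruned-tree
reading was adopted as the self-consistent one.

### Evolutionary timespan

The timespan of a position is the total branch time of the minimal
spanning subtree connecting the species that carry a base there
(degree-2 nodes collapsed with durations summed, re-rooted at the MRCA of
the present leaves). The reported fraction divides by the **full** tree's
total time so values are comparable across positions; the absolute span
in My is also reported. An alternative reading (time from human to the
most distant present species) was considered and not used; the
spanning-subtree time is the one consistent with "fraction of
evolutionary time among species for which the position has existed".

Residue semantics: `-` (gap) means the position does not exist in that
lineage; `N` (missing) means no information. Both are excluded from
substitution counting and from "presence" in the span. Treating missing
as absent is the conservative choice — it never credits a lineage with
presence that the data do not show — but it means poorly sequenced
species shorten spans.

A position carried only by the reference lineage admits no cross-species
comparison: its rate is **undefined** (not 0, which would assert perfect
conservation), its span is 0, its class is `unclassified`, and the
ranking step excludes it with an explicit reason.

### Conservation classes

From the rate: `ultra` (rate = 0), `well` (0 < rate ≤ 1), `less`
(rate > 1). The boundary at exactly 1.0 is closed on the `well` side:
"greater than one" is the unambiguous half of the definition, and its
complement is taken literally.

### E-rank

Within one record set (one study or one query result — never pooled
across studies), each SNP gets

    e_score = (P / MAF) · 1 / (K_r · K_t)

with K_r the midrank of its Evol_Rate ranked **descending** (fastest
evolving = 1, most conserved = N) and K_t the midrank of its Evol_Span
ranked **ascending** (longest span = N). These directions are the single
most consequential interpretation made in this package: they are chosen
so that conserved positions (low rate, long span) receive a large
K_r·K_t, shrinking the score and promoting the SNP — the behaviour the
adjustment exists to produce. Midranks keep the rank sum at N(N+1)/2
under ties; ordinal P-rank and E-rank orderings break ties by rsid so
output is reproducible. Useful identities that the tests assert: both
orderings are permutations of 1..N, their differences sum to zero,
scaling every P by a common factor leaves the E ordering unchanged, and
when all SNPs share identical rate/span/MAF the E ordering equals the P
ordering exactly.

A P-value of exactly 0 is clamped to the smallest positive float (with a
warning); a missing or zero MAF makes the record unrankable and excluded.

## Association store

A flat TSV/CSV table with in-memory hash indexes replaces a database
backend; the query semantics are the contract. At ingest, rows are
rejected (and itemised, never silently dropped) when the P-value is
unparsable or outside (0, 0.05] — the source catalogue's inclusion rule —
or when the (rsid, pmid, phenotype) key repeats, or when the region label
is outside the controlled vocabulary {intron, missense, synonymous,
3'UTR, 5'UTR, intergenic, other} (extensible via an argument). Filters
are conjunctive; phenotype/gene match exactly but case-insensitively;
the E-score cutoff requires rankings to have been merged first and errors
otherwise. Sorting uses a controlled key list, is stable, breaks ties by
rsid, and places missing values last regardless of direction. Keyword
search is a case-insensitive substring match over phenotype, phenotype
category, gene and study title.

## Rank-comparison outputs

Two plot products per ranked set: an E-rank vs P-rank scatter (adjusted
rank on x, raw rank on y, identity line as reference) and an
E-rank − P-rank bar series (negative bars = promoted SNPs). The contract
is the plot-ready TSV, which is byte-identical for identical input;
PNG/SVG rendering is presentation only and not byte-tested. Tabulated and
plotted views are capped at 1000 SNPs for interpretability, keeping the
caller's sort order so pre-sorting chooses what survives the cap; bulk
CSV export is never capped.

## Synthetic data

The generators define the conditions under which everything above is
exercised, with known ground truth:

* **Tree** — Yule-type pure-birth topology with exponential waiting
  times, node heights scaled so all leaves sit exactly `depth_my` below
  the root (ultrametric). Defaults: 8 taxa, 100 My depth — a desk-scale
  stand-in for a mammalian timetree.
* **Columns** — root base uniform on {A,C,G,T}; per branch a
  Poisson(rate × branch time in Gy) number of substitutions, each a
  uniform change to a different base (Jukes–Cantor-like; no
  transition/transversion bias, which a counting estimator does not see).
  Independently each internal edge deletes its subtending clade with
  probability `gap_prob` (default 0.05), the root-to-reference path being
  exempt so the reference always has a base; this clade-level gap model
  matches the lineage-level reading of timespan. The returned truth
  includes the event list and the count of events on the spanning subtree
  of surviving taxa (the observable ones), which Monte-Carlo tests check
  against the Poisson mean.
* **Association tables** — per SNP: MAF ~ Uniform(0.01, 0.5); a fraction
  `signal_fraction` (default 0.1) of SNPs draw P = 10^−U with
  U ~ Uniform(5, 10), the rest draw P ~ Uniform(10^−5, 0.05]; rsid, PMID,
  phenotype, region and gene labels are drawn from small pools. Every
  generated row satisfies the store's ingest invariants.

All generators are deterministic per seed; substreams derive from the
single seed through `numpy.random.SeedSequence` so each fixture is
reproducible in isolation.

What the synthetic data does *not* emulate: linkage disequilibrium,
realistic allele-frequency spectra, demography, alignment error,
genotype-level data, or the size and composition of a real GWAS
catalogue. Passing tests therefore demonstrate the correctness of the
computations and their invariants, not calibration of the adjustment on
real human data.

## Numerical and degenerate-input choices

* Branch lengths must be present on every non-root edge (an unlengthed
  edge is an error, never a silent default) and non-negative; leaf labels
  unique.
* Site-metric TSV output carries 6 significant digits and round-trips at
  that precision; undefined rates are written as `NA`.
* Alignment columns where the reference has a gap have no reference
  coordinate and are skipped; a reference `N` consumes a coordinate but
  yields no column (logged).
* Problem sizes in the test suite and acceptance script (8-taxon trees,
  200 columns per rate level, 500 random labelings per 5–6-leaf topology,
  1000–1500-SNP studies) were chosen as the smallest sizes at which the
  asserted properties are sharp — the parsimony oracle is exhaustive up to
  4 leaves, and the Monte-Carlo checks use 3-standard-error bounds.

## Known limitations

* Parsimony counting saturates: above ~2 substitutions/site/Gy on the
  default tree the recovered mean rate compresses (still monotone).
* The rate denominator and rank-direction choices above are this
  package's documented interpretations of underdetermined definitions.
* MAF reading is desk-scale streaming via Biopython; there is no indexing
  for genome-scale alignments, no liftover, and no strand logic (inputs
  are assumed reference-oriented).
* Functional scores (PolyPhen2, SIFT, EvoD) are pass-through annotation
  strings; the package never computes them.
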