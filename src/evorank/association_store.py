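"""GWAS association records: ingest, filter, aggregate, sort, search.

A flat-file, in-memory stand-in for a GWAS catalogue backend.  Records are
one SNP × study × phenotype association each; the catalogue's inclusion
rule — association P-value ≤ 0.05 — is enforced at ingest, with every
rejected row reported (never silently dropped).  Queries are conjunctive
filters, per-SNP and per-study aggregation, a controlled-key sort with
missing values last, and case-insensitive keyword search.
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass, field
from typing import IO, Mapping, Sequence, Union

import numpy as np
import pandas as pd

P_INCLUSION_THRESHOLD = 0.05

REQUIRED_COLUMNS = ["rsid", "pmid", "phenotype", "p_value", "maf"]
#: numeric annotation columns passed through when the source carries them
NUMERIC_PASSTHROUGH = ["evol_rate", "evol_span"]
OPTIONAL_COLUMNS = [
    "study_title",
    "phenotype_category",
    "allele",
    "chrom",
    "pos",
    "region_type",
    "gene",
    "aa_change",
    "polyphen2",
    "sift",
    "evod",
]

#: Closed vocabulary of genomic-region categories; extensible via the
#: ``extra_region_types`` argument of :func:`load_associations`.
REGION_TYPES = {
    "intron",
    "missense",
    "synonymous",
    "3'UTR",
    "5'UTR",
    "intergenic",
    "other",
}

SORT_KEYS = {
    "rsid",
    "chrom",
    "pos",
    "p_value",
    "log10_p",
    "maf",
    "allele",
    "gene",
    "region_type",
    "phenotype",
    "pmid",
    "evol_rate",
    "evol_span",
    "n_studies",
    "n_phenotypes",
    "min_p",
    "max_p",
    "aa_change",
    "polyphen2",
    "sift",
}

KEYWORD_FIELDS = ["phenotype", "phenotype_category", "gene", "study_title"]


class StoreError(ValueError):
    pass


@dataclass
class RejectionReport:
    """Rows dropped at ingest, each with its reason."""

    rows: list[tuple[int, str]] = field(default_factory=list)

    def add(self, row_index: int, reason: str) -> None:
        self.rows.append((row_index, reason))

    @property
    def n_rejected(self) -> int:
        return len(self.rows)

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        if not self.rows:
            return "0 rows rejected"
        lines = [f"{self.n_rejected} rows rejected:"]
        lines += [f"  row {i}: {reason}" for i, reason in self.rows]
        return "\n".join(lines)


def _normalise_header(columns: Sequence[str]) -> dict[str, str]:
    """Map actual header names to canonical ones, case-insensitively."""
    canon = {
        c.lower(): c
        for c in REQUIRED_COLUMNS + OPTIONAL_COLUMNS + NUMERIC_PASSTHROUGH
    }
    return {c: canon[c.strip().lower()] for c in columns if c.strip().lower() in canon}


def load_associations(
    source: Union[str, IO[str], pd.DataFrame],
    sep: str | None = None,
    extra_region_types: set[str] | None = None,
) -> tuple["AssociationStore", RejectionReport]:
    """Load a TSV/CSV association table into an :class:`AssociationStore`.

    Enforced per row: parsable P-value in (0, 0.05] (the catalogue's
    inclusion rule) and a unique (rsid, pmid, phenotype) key; violators go
    to the :class:`RejectionReport`.  A missing required column is fatal.
    ``sep`` is sniffed from the first line when not given.
    """
    if isinstance(source, pd.DataFrame):
        df = source.copy()
    else:
        if sep is None:
            if hasattr(source, "read"):
                text = source.read()
                sep = "\t" if "\t" in text.split("\n", 1)[0] else ","
                source = io.StringIO(text)
            else:
                with open(source) as fh:
                    sep = "\t" if "\t" in fh.readline() else ","
        df = pd.read_csv(source, sep=sep, dtype=str)

    rename = _normalise_header(list(df.columns))
    df = df.rename(columns=rename)
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise StoreError(f"missing required column(s): {missing}")
    for c in OPTIONAL_COLUMNS:
        if c not in df.columns:
            df[c] = ""
    df = df.fillna("")

    vocab = REGION_TYPES | (extra_region_types or set())
    report = RejectionReport()
    seen: set[tuple[str, str, str]] = set()
    kept: list[dict] = []
    for idx, row in df.iterrows():
        try:
            p = float(row["p_value"])
        except (TypeError, ValueError):
            report.add(idx, f"unparsable P-value {row['p_value']!r}")
            continue
        if not (0 < p <= P_INCLUSION_THRESHOLD):
            report.add(
                idx,
                f"P-value {p:g} exceeds {P_INCLUSION_THRESHOLD} inclusion threshold"
                if p > P_INCLUSION_THRESHOLD
                else f"P-value {p:g} not in (0, {P_INCLUSION_THRESHOLD}]",
            )
            continue
        key = (str(row["rsid"]), str(row["pmid"]), str(row["phenotype"]))
        if key in seen:
            report.add(idx, f"duplicate (rsid, pmid, phenotype) key {key}")
            continue
        seen.add(key)
        try:
            maf = float(row["maf"]) if str(row["maf"]) != "" else math.nan
        except (TypeError, ValueError):
            report.add(idx, f"unparsable MAF {row['maf']!r}")
            continue
        region = str(row["region_type"])
        if region and region not in vocab:
            report.add(
                idx,
                f"unknown region_type {region!r}; valid: {sorted(vocab)}",
            )
            continue
        rec = {c: str(row[c]) for c in REQUIRED_COLUMNS + OPTIONAL_COLUMNS}
        rec["p_value"] = p
        rec["log10_p"] = float(f"{math.log10(p):.6g}")
        rec["maf"] = maf
        rec["pos"] = int(row["pos"]) if str(row["pos"]).strip() else np.nan
        for c in NUMERIC_PASSTHROUGH:
            if c in df.columns:
                try:
                    rec[c] = float(row[c]) if str(row[c]).strip() else math.nan
                except (TypeError, ValueError):
                    rec[c] = math.nan
        kept.append(rec)

    passthrough = [c for c in NUMERIC_PASSTHROUGH if c in df.columns]
    frame = pd.DataFrame(
        kept,
        columns=REQUIRED_COLUMNS + ["log10_p"] + OPTIONAL_COLUMNS + passthrough,
    )
    return AssociationStore(frame, region_vocab=vocab), report


class AssociationStore:
    """In-memory association table with the catalogue's query semantics.

    Wraps a DataFrame (one row per SNP × study × phenotype record) plus
    hash indexes by rsid, pmid, phenotype and gene.  All query methods
    return new objects; the store is never mutated by a query.
    """

    def __init__(
        self,
        records: pd.DataFrame,
        region_vocab: set[str] | None = None,
    ):
        self.records = records.reset_index(drop=True)
        self.region_vocab = region_vocab or set(REGION_TYPES)
        self._index = {
            key: self._build_index(key)
            for key in ("rsid", "pmid", "phenotype", "gene")
        }

    def _build_index(self, column: str) -> dict[str, list[int]]:
        idx: dict[str, list[int]] = {}
        if column not in self.records.columns:
            return idx
        for i, v in enumerate(self.records[column]):
            idx.setdefault(str(v).lower(), []).append(i)
        return idx

    def __len__(self) -> int:
        return len(self.records)

    def lookup(self, column: str, value: str) -> pd.DataFrame:
        """Exact (case-insensitive) indexed lookup by rsid/pmid/phenotype/gene."""
        rows = self._index.get(column, {}).get(str(value).lower(), [])
        return self.records.iloc[rows]

    def _subset(self, frame: pd.DataFrame) -> "AssociationStore":
        return AssociationStore(frame, region_vocab=self.region_vocab)

    # -- filtering ---------------------------------------------------------

    def filter_records(
        self,
        max_p: float | None = None,
        max_e_score: float | None = None,
        region_type: str | None = None,
        phenotype: str | None = None,
        gene: str | None = None,
    ) -> "AssociationStore":
        """Conjunctive (AND) filter; omitted criteria are no-ops.

        ``max_e_score`` requires an ``e_score`` column from a prior ranking
        merge (:meth:`with_rankings`); phenotype/gene match exactly but
        case-insensitively; region_type must come from the controlled
        vocabulary.
        """
        df = self.records
        mask = pd.Series(True, index=df.index)
        if max_p is not None:
            mask &= df["p_value"] <= max_p
        if max_e_score is not None:
            if "e_score" not in df.columns:
                raise StoreError(
                    "max_e_score filter requires rankings: call with_rankings() "
                    "(or the erank pipeline) before filtering on E-rank score"
                )
            mask &= df["e_score"] <= max_e_score
        if region_type is not None:
            if region_type not in self.region_vocab:
                raise StoreError(
                    f"unknown region_type {region_type!r}; "
                    f"valid: {sorted(self.region_vocab)}"
                )
            mask &= df["region_type"] == region_type
        if phenotype is not None:
            mask &= df["phenotype"].str.lower() == phenotype.lower()
        if gene is not None:
            mask &= df["gene"].str.lower() == gene.lower()
        return self._subset(df[mask])

    def with_rankings(self, rankings: pd.DataFrame) -> "AssociationStore":
        """Merge per-rsid ranking output (``e_score`` etc.) onto the records."""
        cols = ["rsid"] + [
            c
            for c in ("e_score", "p_rank", "e_rank_ordinal", "rank_diff")
            if c in rankings.columns
        ]
        merged = self.records.merge(rankings[cols], on="rsid", how="left")
        return self._subset(merged)

    # -- aggregation -------------------------------------------------------

    def summarize_by_snp(
        self, site_metrics: pd.DataFrame | None = None
    ) -> pd.DataFrame:
        """One summary row per distinct rsid.

        ``n_studies``/``n_phenotypes`` count distinct PMIDs/phenotypes;
        ``min_p``/``max_p`` span all of the SNP's records.  Optional
        *site_metrics* (rsid, evol_rate, evol_span) are joined through.
        """
        if len(self.records) == 0:
            return pd.DataFrame(
                columns=[
                    "rsid", "chrom", "pos", "gene", "region_type",
                    "n_studies", "n_phenotypes", "min_p", "max_p",
                    "allele", "maf", "aa_change", "polyphen2", "sift",
                ]
            )
        g = self.records.groupby("rsid", sort=True)
        summary = g.agg(
            chrom=("chrom", "first"),
            pos=("pos", "first"),
            gene=("gene", "first"),
            region_type=("region_type", "first"),
            n_studies=("pmid", "nunique"),
            n_phenotypes=("phenotype", "nunique"),
            min_p=("p_value", "min"),
            max_p=("p_value", "max"),
            allele=("allele", "first"),
            maf=("maf", "first"),
            aa_change=("aa_change", "first"),
            polyphen2=("polyphen2", "first"),
            sift=("sift", "first"),
        ).reset_index()
        if site_metrics is not None:
            cols = ["rsid"] + [
                c for c in ("evol_rate", "evol_span") if c in site_metrics.columns
            ]
            summary = summary.merge(site_metrics[cols], on="rsid", how="left")
        return summary

    def summarize_by_study(self) -> pd.DataFrame:
        """Per-PMID counts: distinct SNPs, phenotypes and (non-empty) genes."""
        if len(self.records) == 0:
            return pd.DataFrame(
                columns=["pmid", "n_snps", "n_phenotypes", "n_genes"]
            )
        g = self.records.groupby("pmid", sort=True)
        return g.agg(
            n_snps=("rsid", "nunique"),
            n_phenotypes=("phenotype", "nunique"),
            n_genes=("gene", lambda s: s[s != ""].nunique()),
        ).reset_index()

    # -- sorting / search --------------------------------------------------

    @staticmethod
    def sort_table(
        table: pd.DataFrame, key: str, ascending: bool = True
    ) -> pd.DataFrame:
        """Stable sort of any records/summary table by a controlled key.

        Missing values (NaN or empty string) order last regardless of
        direction; ties break by rsid.
        """
        if key not in SORT_KEYS:
            raise StoreError(
                f"unknown sort key {key!r}; valid: {sorted(SORT_KEYS)}"
            )
        if key not in table.columns:
            raise StoreError(f"sort key {key!r} not present in this table")
        col = table[key]
        if col.dtype == object:
            col = col.replace("", np.nan)
        missing = col.isna()
        present = table[~missing]
        pcol = col[~missing]
        order = np.lexsort(
            (present["rsid"].to_numpy() if "rsid" in present else np.zeros(len(present)),
             pcol.to_numpy() if ascending else _invert_for_sort(pcol))
        )
        return pd.concat([present.iloc[order], table[missing]]).reset_index(
            drop=True
        )

    def sort_records(self, key: str, ascending: bool = True) -> "AssociationStore":
        return self._subset(self.sort_table(self.records, key, ascending))

    def keyword_search(self, query: str) -> "AssociationStore":
        """Case-insensitive substring search over phenotype, phenotype
        category, gene and study title."""
        q = query.strip().lower()
        if not q:
            raise StoreError("empty search query")
        df = self.records
        mask = pd.Series(False, index=df.index)
        for fld in KEYWORD_FIELDS:
            if fld in df.columns:
                mask |= df[fld].str.lower().str.contains(q, regex=False)
        return self._subset(df[mask])


def _invert_for_sort(col: pd.Series) -> np.ndarray:
    """Sortable array representing the descending order of *col*."""
    arr = col.to_numpy()
    if np.issubdtype(arr.dtype, np.number):
        return -arr
    # strings: rank ascending, negate ranks
    from scipy.stats import rankdata

    codes = rankdata(arr.astype(str), method="dense")
    return -codes
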