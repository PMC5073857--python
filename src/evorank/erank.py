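"""Evolutionary rank adjustment (E-rank) of GWAS association P-values.

For a set of N SNPs (one study's records, or one query result), each with
an association P-value P, minor allele frequency MAF, and per-site
evolutionary context (Evol_Rate, Evol_Span), the E-rank score is

    e_score = (P / MAF) * 1 / (K_r * K_t)

where K_r is the within-set rank of Evol_Rate and K_t the within-set rank
of Evol_Span (midranks; ties get the mean of the tied positions).  Rank
directions are chosen so that conserved positions — low rate, long span —
receive *large* K_r·K_t, shrinking the score and promoting the SNP:

* K_r ranks Evol_Rate **descending**: the fastest-evolving site gets rank 1,
  the most conserved gets rank N.
* K_t ranks Evol_Span **ascending**: the longest-spanning site gets rank N.

SNPs are then ordered twice: P-rank (ascending P) and E-rank (ascending
e_score), with a deterministic rsid tie-break; the difference
E-rank − P-rank is the per-SNP effect of the evolutionary adjustment.

Records that cannot be ranked (MAF missing or 0, undefined rate/span) are
excluded with a reason rather than silently assigned extreme ranks, which
would distort every other SNP's K values.
"""

from __future__ import annotations

import logging
import math
import sys
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata

logger = logging.getLogger(__name__)

RANKING_COLUMNS = [
    "rsid",
    "p_value",
    "maf",
    "evol_rate",
    "evol_span",
    "k_r",
    "k_t",
    "e_score",
    "p_rank",
    "e_rank_ordinal",
    "rank_diff",
]


@dataclass(frozen=True)
class RankedSNP:
    """One SNP's ranking state within a ranked set of size N."""

    rsid: str
    p_value: float
    maf: float
    evol_rate: float
    evol_span: float
    k_r: float
    k_t: float
    e_score: float
    p_rank: int
    e_rank_ordinal: int

    @property
    def rank_diff(self) -> int:
        """E-rank − P-rank; negative = promoted by the adjustment."""
        return self.e_rank_ordinal - self.p_rank


class RankingError(ValueError):
    """Raised when a record set contains nothing rankable."""


def rank_values(values: Sequence[float], direction: str = "ascending") -> np.ndarray:
    """Midranks 1..N of *values*; ties share the mean of their positions.

    ``direction="descending"`` gives the largest value rank 1.  The rank sum
    is always N(N+1)/2.
    """
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        raise RankingError("cannot rank an empty sequence")
    if not np.all(np.isfinite(arr)):
        raise RankingError("cannot rank non-finite values")
    if direction == "ascending":
        return rankdata(arr, method="average")
    if direction == "descending":
        return rankdata(-arr, method="average")
    raise ValueError(f"direction must be ascending/descending, got {direction!r}")


class Unrankable(Exception):
    """Signals a record that must be excluded from ranking (with reason)."""

    def __init__(self, reason: str):
        super().__init__(reason)
        self.reason = reason


def e_score(p: float, maf: float, k_r: float, k_t: float) -> float:
    """(p/maf) · 1/(k_r·k_t).  Strictly increasing in p; decreasing in the rest.

    A missing/zero MAF makes the record unrankable (raises
    :class:`Unrankable`); p = 0 is clamped to the smallest positive float
    with a warning — it would otherwise claim infinite significance.
    """
    if maf is None or (isinstance(maf, float) and math.isnan(maf)) or maf <= 0:
        raise Unrankable(f"MAF missing or non-positive ({maf!r})")
    if k_r < 1 or k_t < 1:
        raise ValueError(f"ranks must be ≥ 1, got k_r={k_r}, k_t={k_t}")
    if p == 0:
        logger.warning("P-value of 0 clamped to smallest positive float")
        p = sys.float_info.min
    if p < 0 or p > 1:
        raise ValueError(f"P-value {p} outside (0, 1]")
    return (p / maf) / (k_r * k_t)


def _ordinal_ranks(values: Sequence[float], rsids: Sequence[str]) -> np.ndarray:
    """Ordinal 1..N by ascending value, ties broken by rsid lexicographic."""
    order = sorted(range(len(values)), key=lambda i: (values[i], rsids[i]))
    ranks = np.empty(len(values), dtype=int)
    for rank, i in enumerate(order, start=1):
        ranks[i] = rank
    return ranks


def compute_rankings(
    records: Iterable[Mapping] | pd.DataFrame,
) -> tuple[list[RankedSNP], list[tuple[Mapping, str]]]:
    """Rank a record set; returns ``(ranked, excluded)``.

    *records* need fields ``rsid, p_value, maf, evol_rate, evol_span``.
    The ranking scope is exactly the supplied set (one study / one query).
    Records lacking evolutionary context or a positive MAF land in
    *excluded* with a reason; an all-excluded input raises
    :class:`RankingError` listing every reason.
    """
    if isinstance(records, pd.DataFrame):
        records = records.to_dict("records")
    records = list(records)

    def _bad(rec: Mapping) -> str | None:
        for f in ("evol_rate", "evol_span"):
            v = rec.get(f)
            if v is None or (isinstance(v, float) and math.isnan(v)):
                return f"undefined {f}"
        maf = rec.get("maf")
        if maf is None or (isinstance(maf, float) and math.isnan(maf)) or maf <= 0:
            return f"MAF missing or non-positive ({maf!r})"
        return None

    rankable: list[Mapping] = []
    excluded: list[tuple[Mapping, str]] = []
    for rec in records:
        reason = _bad(rec)
        if reason is None:
            rankable.append(rec)
        else:
            logger.warning("excluding %s: %s", rec.get("rsid"), reason)
            excluded.append((rec, reason))
    if not rankable:
        reasons = "; ".join(
            f"{r.get('rsid')}: {why}" for r, why in excluded
        ) or "empty input"
        raise RankingError(f"no rankable records ({reasons})")

    rsids = [str(r["rsid"]) for r in rankable]
    rates = [float(r["evol_rate"]) for r in rankable]
    spans = [float(r["evol_span"]) for r in rankable]
    pvals = [float(r["p_value"]) for r in rankable]
    mafs = [float(r["maf"]) for r in rankable]

    k_r = rank_values(rates, "descending")  # most conserved → rank N
    k_t = rank_values(spans, "ascending")  # longest span → rank N
    scores = [
        e_score(p, m, kr, kt) for p, m, kr, kt in zip(pvals, mafs, k_r, k_t)
    ]
    p_rank = _ordinal_ranks(pvals, rsids)
    e_rank = _ordinal_ranks(scores, rsids)

    ranked = [
        RankedSNP(
            rsid=rsids[i],
            p_value=pvals[i],
            maf=mafs[i],
            evol_rate=rates[i],
            evol_span=spans[i],
            k_r=float(k_r[i]),
            k_t=float(k_t[i]),
            e_score=scores[i],
            p_rank=int(p_rank[i]),
            e_rank_ordinal=int(e_rank[i]),
        )
        for i in range(len(rankable))
    ]
    return ranked, excluded


def rankings_frame(ranked: Sequence[RankedSNP]) -> pd.DataFrame:
    """Ranked set as a DataFrame (columns in :data:`RANKING_COLUMNS`)."""
    return pd.DataFrame(
        [
            {
                "rsid": r.rsid,
                "p_value": r.p_value,
                "maf": r.maf,
                "evol_rate": r.evol_rate,
                "evol_span": r.evol_span,
                "k_r": r.k_r,
                "k_t": r.k_t,
                "e_score": r.e_score,
                "p_rank": r.p_rank,
                "e_rank_ordinal": r.e_rank_ordinal,
                "rank_diff": r.rank_diff,
            }
            for r in ranked
        ],
        columns=RANKING_COLUMNS,
    )
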