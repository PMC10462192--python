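"""2x2 odds-ratio enrichment machinery.

All over-representation questions in the pipeline reduce to a 2x2 table
(foreground vs background, in-set vs out-of-set) tested with Fisher's exact
test and summarised by the cross-product odds ratio with a Woolf (log-normal)
95% confidence interval.  When a table has a zero cell the Haldane-Anscombe
correction (add 0.5 to every cell) is applied before the OR/CI; the policy is
configurable (``"on-zero"`` default, ``"always"``, ``"never"``).

The two-sided Fisher p-value is the sum of hypergeometric point
probabilities, over the feasible range at fixed margins, that do not exceed
the observed table's probability within a relative tolerance of 1e-7 (the
tolerance makes floating-point ties stable and is part of the documented
contract).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from .events import GeneSetCollection
from .psi import bh_fdr

logger = logging.getLogger(__name__)

Z95 = 1.96  # Woolf CI normal quantile


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Counts (a, b, c, d): a = fg in set, b = fg out, c = bg in set, d = bg out."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        cells = (self.a, self.b, self.c, self.d)
        if any(x < 0 for x in cells):
            raise ValueError("contingency cells must be non-negative")
        if sum(cells) < 1:
            raise ValueError("contingency table must contain at least one count")

    def as_tuple(self) -> tuple[int, int, int, int]:
        return (self.a, self.b, self.c, self.d)

    @property
    def has_zero_cell(self) -> bool:
        return 0 in self.as_tuple()


@dataclass
class EnrichmentResult:
    """Named 2x2 enrichment test result."""

    name: str
    table: ContingencyTable2x2
    odds_ratio: float
    ci_low: float
    ci_high: float
    p_value: float
    fdr: float | None = None
    degenerate: bool = False


@dataclass
class ConcordanceResult:
    """Direction agreement of shared DPSI estimates between two datasets."""

    n_shared: int
    n_classified: int
    frac_concordant: float
    frac_concordant_negative: float


def fisher_exact_2x2(table: ContingencyTable2x2, tie_tol: float = 1e-7) -> float:
    """Two-sided Fisher exact p by direct enumeration over the feasible range."""
    a, b, c, d = table.as_tuple()
    n = a + b + c + d
    row1 = a + b
    col1 = a + c
    lo = max(0, row1 + col1 - n)
    hi = min(row1, col1)
    support = np.arange(lo, hi + 1)
    pmf = hypergeom.pmf(support, n, col1, row1)
    p_obs = pmf[a - lo]
    p = pmf[pmf <= p_obs * (1.0 + tie_tol)].sum()
    return float(min(1.0, p))


def odds_ratio_ci(
    table: ContingencyTable2x2,
    correction: str = "on-zero",
    z: float = Z95,
) -> tuple[float, tuple[float, float]]:
    """Cross-product odds ratio with a Woolf log-method confidence interval.

    ``correction`` controls the Haldane-Anscombe 0.5 addition: ``"on-zero"``
    (only when a zero cell exists), ``"always"`` or ``"never"``.  With
    ``"never"`` and a zero cell the OR may be 0, inf or nan and the CI is nan.
    """
    a, b, c, d = (float(x) for x in table.as_tuple())
    if correction not in ("on-zero", "always", "never"):
        raise ValueError(f"unknown correction policy {correction!r}")
    if correction == "always" or (correction == "on-zero" and table.has_zero_cell):
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    with np.errstate(divide="ignore", invalid="ignore"):
        if b * c == 0:
            or_ = np.inf if a * d > 0 else np.nan
        else:
            or_ = (a * d) / (b * c)
        if min(a, b, c, d) > 0 and np.isfinite(or_) and or_ > 0:
            se = np.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
            lo = float(np.exp(np.log(or_) - z * se))
            hi = float(np.exp(np.log(or_) + z * se))
        else:
            lo = hi = np.nan
    return float(or_), (lo, hi)


def _result(
    name: str,
    table: ContingencyTable2x2,
    correction: str = "on-zero",
    degenerate: bool = False,
) -> EnrichmentResult:
    or_, (lo, hi) = odds_ratio_ci(table, correction=correction)
    p = fisher_exact_2x2(table)
    return EnrichmentResult(name, table, or_, lo, hi, p, degenerate=degenerate)


def gene_set_enrichment(
    mis_spliced: Iterable[str],
    universe: Iterable[str],
    gene_sets: GeneSetCollection | Mapping[str, Iterable[str]],
    correction: str = "on-zero",
) -> pd.DataFrame:
    """Per-set over-representation of mis-spliced genes within a detected universe.

    For each set S (intersected with the universe):
    a = mis in S, b = mis not in S, c = (universe - mis) in S, d = remainder.
    BH FDR is computed across the whole batch of sets tested together.
    Rows are ordered by descending odds ratio (forest-plot ready).
    """
    uni = {g.upper() for g in universe}
    if not uni:
        raise ValueError("empty universe")
    mis = {g.upper() for g in mis_spliced}
    if not mis <= uni:
        raise ValueError("mis-spliced genes must be a subset of the universe")
    items = gene_sets.items() if hasattr(gene_sets, "items") else gene_sets
    rows = []
    for name, members in items:
        s = {g.upper() for g in members} & uni
        a = len(mis & s)
        b = len(mis) - a
        c = len(s) - a
        d = len(uni) - len(mis) - c
        table = ContingencyTable2x2(a, b, c, d)
        degenerate = len(s) == 0 or len(s) == len(uni) or not mis
        res = _result(name, table, correction=correction, degenerate=degenerate)
        rows.append((name, a, b, c, d, res.odds_ratio, res.ci_low, res.ci_high,
                     res.p_value, degenerate))
    out = pd.DataFrame(
        rows,
        columns=["set", "a", "b", "c", "d", "odds_ratio", "ci_low", "ci_high",
                 "p_value", "degenerate"],
    ).set_index("set")
    out["fdr"] = bh_fdr(out["p_value"].to_numpy())
    return out.sort_values("odds_ratio", ascending=False)


def microexon_enrichment(
    results: pd.DataFrame,
    gene_set: Iterable[str] | None = None,
    name: str = "microexon",
    correction: str = "on-zero",
) -> EnrichmentResult:
    """Disproportion of microexons among mis-spliced SE events.

    Foreground: mis-spliced SE events (optionally restricted to ``gene_set``).
    Background: ALL FDR-evaluable SE events.  Rows: microexon vs not.
    """
    need = {"event_type", "is_microexon", "is_mis_spliced", "fdr"}
    if not need <= set(results.columns):
        raise ValueError(f"results must carry columns {sorted(need)}")
    se = results[(results["event_type"] == "SE") & results["fdr"].notna()]
    fg = se[se["is_mis_spliced"].fillna(False)]
    if gene_set is not None:
        members = {g.upper() for g in gene_set}
        fg = fg[fg["gene_symbol"].str.upper().isin(members)]
    a = int(fg["is_microexon"].sum())
    b = len(fg) - a
    c = int(se["is_microexon"].sum())
    d = len(se) - c
    degenerate = len(fg) == 0
    if degenerate:
        logger.warning("no mis-spliced SE events in scope for %s", name)
    return _result(name, ContingencyTable2x2(a, b, c, d),
                   correction=correction, degenerate=degenerate)


def overlap_test(
    items_a: Iterable[str],
    items_b: Iterable[str],
    universe: Iterable[str],
    name: str = "overlap",
    correction: str = "on-zero",
) -> EnrichmentResult:
    """Fisher overlap of two item sets within a common universe."""
    uni = set(universe)
    A = set(items_a)
    B = set(items_b)
    if not (A <= uni and B <= uni):
        raise ValueError("items must be subsets of the universe")
    a = len(A & B)
    b = len(A - B)
    c = len(B - A)
    d = len(uni) - len(A | B)
    return _result(name, ContingencyTable2x2(a, b, c, d), correction=correction,
                   degenerate=(not A or not B))


def concordance(
    dpsi_a: Mapping[str, float] | pd.Series,
    dpsi_b: Mapping[str, float] | pd.Series,
    shared_ids: Sequence[str] | None = None,
) -> ConcordanceResult:
    """Sign agreement of DPSI between two datasets over shared events.

    Pairs where either DPSI is exactly 0 are excluded from sign
    classification.  Among concordant pairs, the fraction with both signs
    negative (exclusion in both) is also reported.
    """
    sa = pd.Series(dpsi_a, dtype=float)
    sb = pd.Series(dpsi_b, dtype=float)
    ids = list(shared_ids) if shared_ids is not None else sorted(set(sa.index) & set(sb.index))
    n_shared = len(ids)
    if n_shared == 0:
        return ConcordanceResult(0, 0, np.nan, np.nan)
    va = sa.loc[ids].to_numpy()
    vb = sb.loc[ids].to_numpy()
    ok = np.isfinite(va) & np.isfinite(vb) & (va != 0) & (vb != 0)
    n_classified = int(ok.sum())
    if n_classified == 0:
        return ConcordanceResult(n_shared, 0, np.nan, np.nan)
    same = np.sign(va[ok]) == np.sign(vb[ok])
    frac_conc = float(same.mean())
    if same.sum():
        both_neg = (va[ok][same] < 0).mean()
    else:
        both_neg = np.nan
    return ConcordanceResult(n_shared, n_classified, frac_conc, float(both_neg))


def enrichment_frame(results: Sequence[EnrichmentResult], fdr: bool = True) -> pd.DataFrame:
    """Tabulate EnrichmentResults (with batch BH FDR) sorted by descending OR."""
    out = pd.DataFrame(
        [
            (r.name, *r.table.as_tuple(), r.odds_ratio, r.ci_low, r.ci_high,
             r.p_value, r.degenerate)
            for r in results
        ],
        columns=["set", "a", "b", "c", "d", "odds_ratio", "ci_low", "ci_high",
                 "p_value", "degenerate"],
    ).set_index("set")
    if fdr:
        out["fdr"] = bh_fdr(out["p_value"].to_numpy())
    return out.sort_values("odds_ratio", ascending=False)
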