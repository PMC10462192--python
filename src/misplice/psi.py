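"""PSI estimation, replicate-aware differential splicing and mis-splicing calls.

PSI (percent spliced in) is estimated from length-normalised junction counts,

    PSI = (I / lI) / (I / lI + S / lS),

where I and S are inclusion and skipping junction reads and lI, lS the
effective lengths of the two junction sets.  A sample is uninformative for an
event when I + S falls below a coverage floor (default 10 reads) and its PSI
is reported missing.

Group differences are tested with a two-sided label-permutation test on
per-sample PSI: exhaustive over all label assignments when their number is
small (<= ``max_exact``), otherwise Monte-Carlo with add-one smoothing,
p = (1 + #{|T*| >= |T|}) / (n_perm + 1).  The permutation test is
distribution-free and exact at small sample sizes; it deliberately tests the
same decision rule (|DPSI| > 0.1, FDR < 0.05, strict inequalities) that
count-model likelihood tests feed in production pipelines.

FDR control is Benjamini-Hochberg, by default within each event type
separately (SE, MXE, A5SS, A3SS, RI), mirroring the per-type output of
upstream event callers; a joint mode is available.
"""

from __future__ import annotations

import logging
import warnings
from itertools import combinations
from math import comb

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .events import EventCountsTable, SampleTable, SplicingEvent

logger = logging.getLogger(__name__)

#: inclusive microexon length bounds (nt) for SE events
MICROEXON_MIN = 3
MICROEXON_MAX = 33

_TIE_EPS = 1e-12  # |T*| >= |T| up to floating-point ties


def compute_psi(inclusion, skipping, inc_len, skip_len, min_reads: int = 10):
    """Length-normalised PSI; NaN where I + S < ``min_reads``.

    Accepts scalars or broadcastable arrays.  Raises ``ValueError`` for
    negative counts or non-positive effective lengths.
    """
    I = np.asarray(inclusion, dtype=float)
    S = np.asarray(skipping, dtype=float)
    lI = np.asarray(inc_len, dtype=float)
    lS = np.asarray(skip_len, dtype=float)
    if (I[np.isfinite(I)] < 0).any() or (S[np.isfinite(S)] < 0).any():
        raise ValueError("junction counts must be non-negative")
    if (lI < 1).any() or (lS < 1).any():
        raise ValueError("effective lengths must be >= 1")
    with np.errstate(invalid="ignore", divide="ignore"):
        num = I / lI
        den = num + S / lS
        psi = np.where(den > 0, num / den, np.nan)
        psi = np.where(I + S < min_reads, np.nan, psi)
    if psi.ndim == 0:
        return float(psi)
    return psi


def psi_matrix(counts: EventCountsTable, min_reads: int = 10) -> pd.DataFrame:
    """Events x samples PSI DataFrame; attrs record the coverage floor used."""
    psi = compute_psi(
        counts.inclusion, counts.skipping,
        counts.inc_len[:, None], counts.skip_len[:, None],
        min_reads=min_reads,
    )
    out = pd.DataFrame(psi, index=pd.Index(counts.event_ids, name="event_id"),
                       columns=counts.sample_ids)
    out.attrs["min_reads"] = min_reads
    return out


def _exhaustive_assignments(m: int, m_case: int) -> np.ndarray:
    """All case-label assignments as a (n_assign, m) boolean matrix."""
    combs = list(combinations(range(m), m_case))
    A = np.zeros((len(combs), m), dtype=bool)
    for i, idx in enumerate(combs):
        A[i, list(idx)] = True
    return A


def _mc_assignments(m: int, m_case: int, n_perm: int, rng: np.random.Generator) -> np.ndarray:
    order = np.argsort(rng.random((n_perm, m)), axis=1)
    A = np.zeros((n_perm, m), dtype=bool)
    np.put_along_axis(A, order[:, :m_case], True, axis=1)
    return A


def _perm_pvalues(
    P: np.ndarray,
    is_case: np.ndarray,
    obs: np.ndarray,
    n_perm: int,
    rng: np.random.Generator | None,
    max_exact: int,
    chunk: int = 512,
) -> np.ndarray:
    """Permutation p-values for a block of events sharing one informative-sample mask.

    ``P`` is (m_samples, k_events) PSI over informative samples, ``is_case``
    the observed labelling, ``obs`` the observed mean differences.
    """
    m = P.shape[0]
    m_case = int(is_case.sum())
    m_ctrl = m - m_case
    exact = comb(m, m_case) <= max_exact
    if exact:
        A = _exhaustive_assignments(m, m_case)
    else:
        if rng is None:
            raise ValueError("a seed is required for Monte-Carlo permutation")
        A = _mc_assignments(m, m_case, n_perm, rng)
    W = np.where(A, 1.0 / m_case, -1.0 / m_ctrl)
    k = P.shape[1]
    p = np.empty(k)
    thresh = np.abs(obs) - _TIE_EPS
    for lo in range(0, k, chunk):
        hi = min(lo + chunk, k)
        stats = W @ P[:, lo:hi]
        hits = (np.abs(stats) >= thresh[lo:hi]).sum(axis=0)
        if exact:
            p[lo:hi] = hits / A.shape[0]
        else:
            p[lo:hi] = (1.0 + hits) / (n_perm + 1.0)
    return p


def differential_splicing(
    counts: EventCountsTable,
    samples: SampleTable,
    case: str,
    control: str,
    *,
    min_reads: int = 10,
    n_perm: int = 9999,
    seed: int | None = None,
    max_exact: int = 10_000,
) -> pd.DataFrame:
    """Per-event DPSI and two-sided permutation p-value.

    DPSI = mean PSI(case) - mean PSI(control) over informative samples.
    Events with one uninformative group keep a row with missing DPSI/p;
    events with no informative samples at all are dropped with a warning.
    Monte-Carlo permutations share one seeded generator, so results are
    reproducible for a given seed and input order.
    """
    case_ids = samples.group(case)
    ctrl_ids = samples.group(control)
    if not case_ids or not ctrl_ids:
        raise ValueError(f"empty group: case={len(case_ids)}, control={len(ctrl_ids)} samples")
    cols = case_ids + ctrl_ids
    idx = counts.sample_index(cols)
    psi = psi_matrix(counts, min_reads=min_reads)
    P = psi.to_numpy()[:, idx]
    is_case = np.array([True] * len(case_ids) + [False] * len(ctrl_ids))
    inf = np.isfinite(P)
    n_case_inf = inf[:, is_case].sum(axis=1)
    n_ctrl_inf = inf[:, ~is_case].sum(axis=1)

    keep = (n_case_inf + n_ctrl_inf) > 0
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.warning("dropping %d events with no informative samples", n_dropped)

    event_ids = np.asarray(counts.event_ids)[keep]
    P = P[keep]
    inf = inf[keep]
    n_case_inf = n_case_inf[keep]
    n_ctrl_inf = n_ctrl_inf[keep]
    n = P.shape[0]

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        mean_case = np.nanmean(np.where(is_case, P, np.nan), axis=1)
        mean_ctrl = np.nanmean(np.where(~is_case, P, np.nan), axis=1)
    testable = (n_case_inf >= 1) & (n_ctrl_inf >= 1)
    dpsi = np.where(testable, mean_case - mean_ctrl, np.nan)

    rng = np.random.default_rng(seed) if seed is not None else None
    pvals = np.full(n, np.nan)
    if testable.any():
        masks = np.ascontiguousarray(inf[testable])
        tidx = np.flatnonzero(testable)
        keys = masks.view([("", masks.dtype)] * masks.shape[1]).ravel()
        order = np.argsort(keys, kind="stable")
        sorted_idx = tidx[order]
        sorted_keys = keys[order]
        start = 0
        for end in range(1, len(sorted_idx) + 1):
            if end == len(sorted_idx) or sorted_keys[end] != sorted_keys[start]:
                grp = sorted_idx[start:end]
                mask = inf[grp[0]]
                sub = P[np.ix_(grp, np.flatnonzero(mask))].T  # (m, k)
                pvals[grp] = _perm_pvalues(
                    sub, is_case[mask], dpsi[grp], n_perm, rng, max_exact
                )
                start = end

    out = pd.DataFrame(
        {
            "n_case": n_case_inf,
            "n_ctrl": n_ctrl_inf,
            "psi_case": mean_case,
            "psi_ctrl": mean_ctrl,
            "dpsi": dpsi,
            "p_value": pvals,
        },
        index=pd.Index(event_ids, name="event_id"),
    )
    out.attrs.update({"case": case, "control": control, "min_reads": min_reads,
                      "n_perm": n_perm, "seed": seed})
    return out


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values; NaNs are excluded and returned NaN."""
    p = np.asarray(p_values, dtype=float)
    ok = np.isfinite(p)
    if ((p[ok] < 0) | (p[ok] > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    q = np.full(p.shape, np.nan)
    if ok.sum():
        q[ok] = multipletests(p[ok], method="fdr_bh")[1]
    return np.clip(q, 0.0, 1.0, out=q)


def add_fdr(results: pd.DataFrame, scope: str = "per-type") -> pd.DataFrame:
    """Attach an ``fdr`` column; scope ``"per-type"`` (needs ``event_type``) or ``"joint"``."""
    out = results.copy()
    if scope == "joint":
        out["fdr"] = bh_fdr(out["p_value"].to_numpy())
    elif scope == "per-type":
        if "event_type" not in out.columns:
            raise ValueError("per-type FDR needs an 'event_type' column (annotate first)")
        out["fdr"] = np.nan
        for _, grp in out.groupby("event_type"):
            out.loc[grp.index, "fdr"] = bh_fdr(grp["p_value"].to_numpy())
    else:
        raise ValueError(f"unknown FDR scope {scope!r}")
    return out


def classify_microexon(event: SplicingEvent) -> bool:
    """True for SE events whose alternative exon is 3-33 nt long (inclusive)."""
    return (
        event.event_type == "SE"
        and MICROEXON_MIN <= event.alt_exon_length <= MICROEXON_MAX
    )


def annotate_events(results: pd.DataFrame, events) -> pd.DataFrame:
    """Join event metadata (type, gene, exon length, microexon flag) onto results."""
    meta = pd.DataFrame(
        {
            "event_type": [e.event_type for e in events],
            "gene_id": [e.gene_id for e in events],
            "gene_symbol": [e.gene_symbol for e in events],
            "alt_exon_length": [e.alt_exon_length for e in events],
            "is_microexon": [classify_microexon(e) for e in events],
        },
        index=pd.Index([e.event_id for e in events], name="event_id"),
    )
    return results.join(meta.loc[results.index.intersection(meta.index)], how="left")


def classify_mis_spliced(
    results: pd.DataFrame, dpsi_thresh: float = 0.1, fdr_thresh: float = 0.05
) -> pd.DataFrame:
    """Flag events with |DPSI| strictly > ``dpsi_thresh`` and FDR strictly < ``fdr_thresh``.

    Missing DPSI or FDR never flags.
    """
    out = results.copy()
    dpsi = out["dpsi"].to_numpy()
    fdr = out["fdr"].to_numpy()
    with np.errstate(invalid="ignore"):
        flag = (np.abs(dpsi) > dpsi_thresh) & (fdr < fdr_thresh)
    out["is_mis_spliced"] = np.where(np.isfinite(dpsi) & np.isfinite(fdr), flag, False)
    out.attrs.update(results.attrs)
    out.attrs.update({"dpsi_thresh": dpsi_thresh, "fdr_thresh": fdr_thresh})
    return out


def mis_spliced_genes(results: pd.DataFrame) -> tuple[set[str], set[str]]:
    """(mis-spliced genes, universe of FDR-evaluable genes) from annotated results.

    A gene is mis-spliced when >= 1 of its events is flagged; the universe is
    every gene with >= 1 FDR-evaluable event.  Events without a gene symbol
    are excluded with a warning.
    """
    if "gene_symbol" not in results.columns or "fdr" not in results.columns:
        raise ValueError("results must carry gene_symbol and fdr columns")
    sym = results["gene_symbol"].fillna("")
    blank = sym.str.len() == 0
    if blank.any():
        logger.warning("excluding %d events without a gene symbol", int(blank.sum()))
    ok = results.loc[~blank]
    evaluable = ok.loc[ok["fdr"].notna()]
    universe = set(evaluable["gene_symbol"].str.upper())
    flagged = ok.loc[ok.get("is_mis_spliced", pd.Series(False, index=ok.index)).fillna(False)]
    mis = set(flagged["gene_symbol"].str.upper()) & universe
    return mis, universe


def run_differential(
    events,
    counts: EventCountsTable,
    samples: SampleTable,
    case: str,
    control: str,
    *,
    min_reads: int = 10,
    n_perm: int = 9999,
    seed: int | None = None,
    dpsi_thresh: float = 0.1,
    fdr_thresh: float = 0.05,
    fdr_scope: str = "per-type",
) -> pd.DataFrame:
    """Full differential-splicing pass: test, annotate, FDR, mis-splicing flags."""
    res = differential_splicing(
        counts, samples, case, control,
        min_reads=min_reads, n_perm=n_perm, seed=seed,
    )
    res = annotate_events(res, events)
    res = add_fdr(res, scope=fdr_scope)
    res = classify_mis_spliced(res, dpsi_thresh=dpsi_thresh, fdr_thresh=fdr_thresh)
    res.attrs["fdr_scope"] = fdr_scope
    return res
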