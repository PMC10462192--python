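"""Per-sample mis-splicing burden and its correlation with numeric covariates.

The per-sample burden of a case individual is the mean, over an event subset
(typically the mis-spliced events of a gene panel), of |PSI_sample - mean
PSI_control|; events uninformative in that sample are skipped.  The
developmental variant replaces the control mean with a reference time point
(default: the earliest, embryonic, sample) so the burden tracks maturation.
Burdens are then correlated with covariates such as CTG repeat length or
MBNL expression using Pearson's r with a two-sided t-test p-value
(t = r * sqrt((n - 2) / (1 - r^2))).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .events import SampleTable


@dataclass
class CorrelationResult:
    r: float
    p_value: float
    n: int
    degenerate: bool = False


def pearson_corr(x, y) -> CorrelationResult:
    """Pearson correlation over pairwise-complete observations.

    Zero variance in either vector yields a degenerate result (r, p = NaN);
    a p-value needs n >= 3.
    """
    xa = np.asarray(x, dtype=float)
    ya = np.asarray(y, dtype=float)
    if xa.shape != ya.shape:
        raise ValueError("x and y must have equal length")
    ok = np.isfinite(xa) & np.isfinite(ya)
    xa, ya = xa[ok], ya[ok]
    n = xa.size
    if n < 2 or np.ptp(xa) == 0 or np.ptp(ya) == 0:
        return CorrelationResult(np.nan, np.nan, n, degenerate=True)
    if n < 3:
        r = float(stats.pearsonr(xa, ya).statistic)
        return CorrelationResult(r, np.nan, n)
    res = stats.pearsonr(xa, ya)
    return CorrelationResult(float(res.statistic), float(res.pvalue), n)


def per_sample_burden(
    psi: pd.DataFrame,
    control_mean: pd.Series,
    event_ids: Sequence[str],
    sample_ids: Sequence[str] | None = None,
) -> pd.Series:
    """Mean |PSI_sample - control mean| over ``event_ids`` for each sample.

    Events missing in a sample are skipped for that sample; a sample with no
    informative event in the subset gets a missing burden.
    """
    ids = [e for e in event_ids if e in psi.index and e in control_mean.index]
    if not ids:
        raise ValueError("event subset is empty or absent from the PSI matrix")
    sub = psi.loc[ids]
    if sample_ids is not None:
        sub = sub[list(sample_ids)]
    dev = sub.sub(control_mean.loc[ids], axis=0).abs()
    burden = dev.mean(axis=0, skipna=True)
    burden[dev.notna().sum(axis=0) == 0] = np.nan
    burden.name = "burden"
    return burden


def developmental_burden(
    psi_by_timepoint: pd.DataFrame,
    event_ids: Sequence[str],
    reference: str | None = None,
) -> pd.Series:
    """Mean |PSI_t - PSI_reference| per time point over an event subset.

    ``psi_by_timepoint`` is events x ordered time points.  The reference
    defaults to the first (earliest) column; events missing at the reference
    are excluded from every time point.
    """
    if psi_by_timepoint.shape[1] < 2:
        raise ValueError("need at least two time points")
    ref = reference if reference is not None else psi_by_timepoint.columns[0]
    if ref not in psi_by_timepoint.columns:
        raise ValueError(f"reference {ref!r} is not a time point")
    ids = [e for e in event_ids if e in psi_by_timepoint.index]
    if not ids:
        raise ValueError("event subset is empty or absent from the PSI matrix")
    sub = psi_by_timepoint.loc[ids]
    sub = sub[sub[ref].notna()]
    burden = sub.sub(sub[ref], axis=0).abs().mean(axis=0, skipna=True)
    burden.name = "burden"
    return burden


def burden_covariate_correlation(
    burden: pd.Series, covariate: pd.Series
) -> CorrelationResult:
    """Pearson correlation between per-sample burden and a covariate, by sample id."""
    ids = burden.index.intersection(covariate.index)
    return pearson_corr(covariate.loc[ids].to_numpy(), burden.loc[ids].to_numpy())


def case_burden_from_results(
    psi: pd.DataFrame,
    results: pd.DataFrame,
    samples: SampleTable,
    case: str,
    control: str,
    event_ids: Sequence[str] | None = None,
) -> pd.Series:
    """Convenience: burden of each case sample against the control-group mean PSI.

    ``event_ids`` defaults to the mis-spliced events in ``results``.
    """
    if event_ids is None:
        event_ids = list(results.index[results["is_mis_spliced"].fillna(False)])
    ctrl_mean = psi[samples.group(control)].mean(axis=1, skipna=True)
    return per_sample_burden(psi, ctrl_mean, event_ids, sample_ids=samples.group(case))
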