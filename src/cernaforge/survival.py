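"""Survival screening of network mRNAs.

The bespoke statistic here is the two-group log-rank test, implemented from
the observed-minus-expected formulation: over the distinct event times t_j,

    chi2 = (sum_j (O1j - E1j))^2 / sum_j V_j,

with E1j = d_j * n1j / n_j and the hypergeometric variance
V_j = d_j (n1j/n_j)(1 - n1j/n_j)(n_j - d_j)/(n_j - 1), which handles tied
event times; p comes from chi-square with 1 df. Each network mRNA is
screened by splitting the cohort at its median expression (the convention
of the survival portals used in this field; the quantile is configurable)
and kept when the log-rank p < alpha.

Multivariate Cox regression of clinical covariates is exposed as a thin
convenience wrapper around lifelines' proportional-hazards fitter — it is
routine plumbing, not re-derived here.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .cerna import CeRNAPair
from .errors import InputError
from .io_formats import ClinicalTable, ExpressionMatrix

log = logging.getLogger(__name__)

SURVIVAL_COLUMNS = ("feature_id", "cut", "chi2", "p_logrank", "direction", "passes")


def _logrank_detail(times_a, events_a, times_b, events_b) -> tuple[float, float, float]:
    """(chi2, p, O1 - E1) for two arms; degenerate arms give (0, 1, 0)."""
    ta = np.asarray(times_a, dtype=float)
    ea = np.asarray(events_a, dtype=int)
    tb = np.asarray(times_b, dtype=float)
    eb = np.asarray(events_b, dtype=int)
    if ta.shape != ea.shape or tb.shape != eb.shape:
        raise InputError("times and events must have matching shapes")
    if ea.sum() == 0 or eb.sum() == 0:
        warnings.warn("log-rank test degenerate: an arm has no events", stacklevel=2)
        return 0.0, 1.0, 0.0

    times = np.concatenate([ta, tb])
    events = np.concatenate([ea, eb])
    arm_a = np.zeros(times.size, dtype=bool)
    arm_a[: ta.size] = True

    event_times = np.unique(times[events == 1])
    ta_sorted = np.sort(ta)
    tb_sorted = np.sort(tb)
    n1 = ta.size - np.searchsorted(ta_sorted, event_times, side="left")
    n2 = tb.size - np.searchsorted(tb_sorted, event_times, side="left")
    n_tot = n1 + n2

    # events per distinct event time, per arm
    et_index = {t: i for i, t in enumerate(event_times)}
    d1 = np.zeros(event_times.size)
    d2 = np.zeros(event_times.size)
    for t, e, a in zip(times, events, arm_a):
        if e:
            if a:
                d1[et_index[t]] += 1
            else:
                d2[et_index[t]] += 1
    d = d1 + d2

    with np.errstate(divide="ignore", invalid="ignore"):
        e1 = d * n1 / n_tot
        frac = n1 / n_tot
        v = d * frac * (1 - frac) * (n_tot - d) / np.maximum(n_tot - 1, 1)
    o_minus_e = float((d1 - e1).sum())
    v_sum = float(v.sum())
    if v_sum <= 0:
        return 0.0, 1.0, o_minus_e
    chi2 = o_minus_e**2 / v_sum
    p = float(stats.chi2.sf(chi2, df=1))
    return float(chi2), p, o_minus_e


def logrank_test(times_a, events_a, times_b, events_b) -> tuple[float, float]:
    """Two-group log-rank test; returns (chi2, p)."""
    chi2, p, _ = _logrank_detail(times_a, events_a, times_b, events_b)
    return chi2, p


def km_median_split_screen(
    expr: ExpressionMatrix,
    clinical: ClinicalTable,
    features=None,
    alpha: float = 0.05,
    cut_quantile: float = 0.5,
) -> pd.DataFrame:
    """Screen features by expression split at the given quantile.

    The high-expression arm is samples strictly above the cut. Features for
    which the split leaves an arm empty (constant expression) are skipped
    and logged. ``direction`` is ``high_risk`` when the high arm shows more
    events than expected, else ``low_risk``.
    """
    samples = expr.sample_ids
    if set(samples) - set(clinical.sample_ids):
        raise InputError("expression samples absent from clinical table")
    cl = clinical.data.loc[samples]
    time = cl["time"].to_numpy(float)
    event = cl["event"].to_numpy(int)

    if features is None:
        features = expr.feature_ids
    rows = []
    n_skipped = 0
    for f in features:
        x = expr.data.loc[f].to_numpy(float)
        cut = float(np.quantile(x, cut_quantile))
        high = x > cut
        if high.sum() == 0 or (~high).sum() == 0:
            n_skipped += 1
            log.info("km_median_split_screen: skipped %s (degenerate split)", f)
            continue
        chi2, p, o_minus_e = _logrank_detail(time[high], event[high], time[~high], event[~high])
        rows.append(
            dict(
                feature_id=f,
                cut=cut,
                chi2=chi2,
                p_logrank=p,
                direction="high_risk" if o_minus_e > 0 else "low_risk",
                passes=p < alpha,
            )
        )
    if n_skipped:
        log.info("km_median_split_screen: %d features skipped", n_skipped)
    return pd.DataFrame(rows, columns=list(SURVIVAL_COLUMNS))


def prune_network(
    pairs: list[CeRNAPair], survival_results: pd.DataFrame, alpha: float = 0.05
) -> tuple[list[CeRNAPair], dict]:
    """Retain pairs whose mRNA passes the survival screen."""
    passing = set(
        survival_results.loc[
            (survival_results["p_logrank"] < alpha), "feature_id"
        ]
    )
    kept = [p for p in pairs if p.mrna_id in passing]
    if not kept:
        warnings.warn("survival pruning removed every pair", stacklevel=2)
    report = {
        "n_pairs_in": len(pairs),
        "n_pairs_retained": len(kept),
        "n_mrnas_passing": len(passing),
    }
    return kept, report


def cox_regression(clinical: ClinicalTable, covariates: list[str]):
    """Multivariate Cox proportional-hazards fit of clinical covariates.

    Returns the fitted lifelines ``CoxPHFitter`` (summary under
    ``.summary``). Categorical covariates are one-hot encoded against their
    first level.
    """
    from lifelines import CoxPHFitter

    df = clinical.data[["time", "event", *covariates]].copy()
    df = pd.get_dummies(df, columns=[c for c in covariates if df[c].dtype == object],
                        drop_first=True, dtype=float)
    cph = CoxPHFitter()
    cph.fit(df, duration_col="time", event_col="event")
    return cph
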