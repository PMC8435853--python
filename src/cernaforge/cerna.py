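"""Competing-endogenous-RNA pair construction.

A lncRNA and an mRNA form a ceRNA pair when they compete for the same
miRNAs: the miRNA is negatively correlated with both transcripts, the two
transcripts are positively correlated with each other, they share
significantly more miRNAs than chance (one-sided hypergeometric test on the
shared-miRNA count), and their miRNA-correlation profiles agree (regulation
similarity >= 0.5).

Statistics
----------
Hypergeometric sharing test
    p = P(X >= k), X ~ Hypergeom(M = |universe|, K = |lncRNA's miRNAs|,
    N = |mRNA's miRNAs|), k the observed overlap; upper tail, inclusive.
    The universe is the set of differential miRNAs surviving evidence
    filtering (the smallest defensible reference set).
Regulation similarity (normalized-difference form, default)
    reg_sim = 1 - (1/k) * sum_i |cL_i - cM_i| / (|cL_i| + |cM_i|)
    over the k shared miRNAs, where cL_i = corr(miRNA_i, lncRNA) and
    cM_i = corr(miRNA_i, mRNA); a term with cL_i = cM_i = 0 contributes 0
    to the sum (continuity choice). Ranges over [0, 1], is 1 iff the two
    profiles are elementwise identical, and is defined from k = 1 up.
    An alternative form — the Pearson correlation between the two profiles,
    requiring k >= 3 — is available as ``reg_sim_formula="vector_corr"``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import InputError
from .io_formats import ExpressionMatrix

log = logging.getLogger(__name__)


@dataclass
class CeRNAPair:
    """A candidate lncRNA-mRNA sponge pair with all its statistics."""

    lncrna_id: str
    mrna_id: str
    shared_mirnas: tuple[str, ...]
    r_lnc_mrna: float
    p_corr: float
    p_hyper: float
    reg_sim: float
    passes_all: bool


# ---------------------------------------------------------------------------
# correlation


def correlation_matrix(
    x: np.ndarray, y: np.ndarray, method: str = "pearson"
) -> tuple[np.ndarray, np.ndarray]:
    """Row-by-row correlations between two (features x samples) arrays.

    Returns (R, P): R[i, j] = corr(x[i], y[j]) and the two-sided p-value
    from the t distribution with n - 2 df. Spearman is Pearson on ranks
    (large-sample approximation for p). Zero-variance rows give NaN.
    """
    if x.shape[1] != y.shape[1]:
        raise InputError("correlation inputs must share the sample axis")
    n = x.shape[1]
    if n < 3:
        raise InputError("need at least 3 samples for a correlation p-value")
    if method == "spearman":
        x = stats.rankdata(x, axis=1)
        y = stats.rankdata(y, axis=1)
    elif method != "pearson":
        raise InputError(f"unknown correlation method {method!r}")
    xc = x - x.mean(axis=1, keepdims=True)
    yc = y - y.mean(axis=1, keepdims=True)
    sx = np.sqrt((xc**2).sum(axis=1))
    sy = np.sqrt((yc**2).sum(axis=1))
    with np.errstate(divide="ignore", invalid="ignore"):
        r = (xc @ yc.T) / np.outer(sx, sy)
    r = np.clip(r, -1.0, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt((n - 2) / np.maximum(1.0 - r**2, np.finfo(float).tiny))
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    p[np.abs(r) >= 1.0] = 0.0
    p[np.isnan(r)] = np.nan
    return r, p


def negative_correlation_filter(
    edges: pd.DataFrame,
    expr_mirna: ExpressionMatrix,
    expr_target: ExpressionMatrix,
    alpha: float = 0.05,
    method: str = "pearson",
) -> pd.DataFrame:
    """Keep miRNA->target edges with r < 0 and two-sided p < alpha.

    ``edges`` needs columns source_id (miRNA) and target_id; the returned
    frame adds ``r`` and ``p_r``. Edges touching a zero-variance feature are
    dropped and logged. Requires >= 10 aligned samples.
    """
    if expr_mirna.sample_ids != expr_target.sample_ids:
        raise InputError("expression matrices are not sample-aligned")
    if len(expr_mirna.sample_ids) < 10:
        raise InputError("need >= 10 samples for the correlation filter")
    out = edges.copy()
    mirs = sorted(set(out["source_id"]) & set(expr_mirna.feature_ids))
    tgts = sorted(set(out["target_id"]) & set(expr_target.feature_ids))
    n_missing = len(out) - int(
        (out["source_id"].isin(mirs) & out["target_id"].isin(tgts)).sum()
    )
    if n_missing:
        log.info("negative_correlation_filter: %d edges reference absent features", n_missing)
    out = out[out["source_id"].isin(mirs) & out["target_id"].isin(tgts)]
    if out.empty:
        out = out.copy()
        out["r"] = pd.Series(dtype=float)
        out["p_r"] = pd.Series(dtype=float)
        return out.reset_index(drop=True)
    r, p = correlation_matrix(
        expr_mirna.data.loc[mirs].to_numpy(float),
        expr_target.data.loc[tgts].to_numpy(float),
        method=method,
    )
    mi = {m: i for i, m in enumerate(mirs)}
    ti = {t: i for i, t in enumerate(tgts)}
    rows = out["source_id"].map(mi).to_numpy()
    cols = out["target_id"].map(ti).to_numpy()
    out["r"] = r[rows, cols]
    out["p_r"] = p[rows, cols]
    n_zero_var = int(out["r"].isna().sum())
    if n_zero_var:
        log.info("negative_correlation_filter: dropped %d zero-variance edges", n_zero_var)
    keep = (out["r"] < 0) & (out["p_r"] < alpha)
    return out[keep.fillna(False)].reset_index(drop=True)


# ---------------------------------------------------------------------------
# hypergeometric sharing test


def shared_mirna_hypergeometric(
    lnc_targets: set[str], mrna_targets: set[str], universe: set[str]
) -> float:
    """Upper-tail (inclusive) probability of the observed miRNA sharing."""
    if not universe:
        raise InputError("empty miRNA universe")
    if not lnc_targets <= universe or not mrna_targets <= universe:
        raise InputError("target sets must be subsets of the universe")
    m = len(universe)
    big_k = len(lnc_targets)
    n = len(mrna_targets)
    k = len(lnc_targets & mrna_targets)
    # P(X >= k) = survival function at k - 1
    return float(stats.hypergeom.sf(k - 1, m, big_k, n))


# ---------------------------------------------------------------------------
# regulation similarity


def regulation_similarity(
    corr_lnc: np.ndarray, corr_mrna: np.ndarray, formula: str = "normdiff"
) -> float:
    """Similarity of the two miRNA-correlation profiles over shared miRNAs."""
    cl = np.asarray(corr_lnc, dtype=float)
    cm = np.asarray(corr_mrna, dtype=float)
    if cl.shape != cm.shape:
        raise InputError("correlation profiles must have equal length")
    if cl.ndim != 1 or cl.size < 1:
        raise InputError("correlation profiles must be 1-d with length >= 1")
    if formula == "normdiff":
        denom = np.abs(cl) + np.abs(cm)
        terms = np.zeros_like(denom)
        nz = denom > 0
        terms[nz] = np.abs(cl[nz] - cm[nz]) / denom[nz]
        return float(1.0 - terms.mean())
    if formula == "vector_corr":
        if cl.size < 3:
            raise InputError("vector_corr regulation similarity needs >= 3 shared miRNAs")
        return float(stats.pearsonr(cl, cm).statistic)
    raise InputError(f"unknown regulation-similarity formula {formula!r}")


# ---------------------------------------------------------------------------
# pair construction


def build_pairs(
    lnc_edges: pd.DataFrame,
    mrna_edges: pd.DataFrame,
    expr_lncrna: ExpressionMatrix,
    expr_mrna: ExpressionMatrix,
    expr_mirna: ExpressionMatrix,
    alpha: float = 0.05,
    reg_sim_min: float = 0.5,
    method: str = "pearson",
    reg_sim_formula: str = "normdiff",
) -> tuple[list[CeRNAPair], list[CeRNAPair]]:
    """Enumerate lncRNA-mRNA pairs with >= 1 shared miRNA and score them.

    A pair passes when r(lncRNA, mRNA) >= 0 with p < alpha, the
    hypergeometric sharing p < alpha, and regulation similarity >=
    ``reg_sim_min``. Returns (all candidate pairs, passing subset); ties are
    never broken — every candidate is reported.
    """
    lnc_by_mir = {m: set(s["target_id"]) for m, s in lnc_edges.groupby("source_id")}
    mrna_by_mir = {m: set(s["target_id"]) for m, s in mrna_edges.groupby("source_id")}
    universe = set(lnc_by_mir) | set(mrna_by_mir)

    shared: dict[tuple[str, str], set[str]] = {}
    for mir in set(lnc_by_mir) & set(mrna_by_mir):
        for l in lnc_by_mir[mir]:
            for r_ in mrna_by_mir[mir]:
                shared.setdefault((l, r_), set()).add(mir)
    if not shared:
        return [], []

    mirs_of_lnc: dict[str, set[str]] = {}
    for mir, ls in lnc_by_mir.items():
        for l in ls:
            mirs_of_lnc.setdefault(l, set()).add(mir)
    mirs_of_mrna: dict[str, set[str]] = {}
    for mir, rs in mrna_by_mir.items():
        for r_ in rs:
            mirs_of_mrna.setdefault(r_, set()).add(mir)

    lncs = sorted({l for l, _ in shared})
    mrnas = sorted({r_ for _, r_ in shared})
    mirs = sorted(universe & set(expr_mirna.feature_ids))
    xl = expr_lncrna.data.loc[lncs].to_numpy(float)
    xr = expr_mrna.data.loc[mrnas].to_numpy(float)
    xm = expr_mirna.data.loc[mirs].to_numpy(float)
    r_lr, p_lr = correlation_matrix(xl, xr, method=method)
    r_ml, _ = correlation_matrix(xm, xl, method=method)
    r_mr, _ = correlation_matrix(xm, xr, method=method)
    li = {l: i for i, l in enumerate(lncs)}
    ri = {r_: i for i, r_ in enumerate(mrnas)}
    mi = {m: i for i, m in enumerate(mirs)}

    pairs: list[CeRNAPair] = []
    for (l, r_), mset in sorted(shared.items()):
        smirs = tuple(sorted(mset))
        rv = float(r_lr[li[l], ri[r_]])
        pv = float(p_lr[li[l], ri[r_]])
        p_hyper = shared_mirna_hypergeometric(mirs_of_lnc[l], mirs_of_mrna[r_], universe)
        idx = [mi[m] for m in smirs]
        cl = r_ml[idx, li[l]]
        cm = r_mr[idx, ri[r_]]
        try:
            rs = regulation_similarity(cl, cm, formula=reg_sim_formula)
        except InputError:
            rs = float("nan")  # vector_corr with < 3 shared miRNAs
        passes = bool(
            np.isfinite(rv)
            and rv >= 0
            and pv < alpha
            and p_hyper < alpha
            and np.isfinite(rs)
            and rs >= reg_sim_min
        )
        pairs.append(CeRNAPair(l, r_, smirs, rv, pv, p_hyper, rs, passes))
    passing = [p for p in pairs if p.passes_all]
    return pairs, passing


def pairs_to_frame(pairs: list[CeRNAPair]) -> pd.DataFrame:
    """Tabular view of a pair list (shared miRNAs joined with ';')."""
    return pd.DataFrame(
        {
            "lncrna_id": [p.lncrna_id for p in pairs],
            "mrna_id": [p.mrna_id for p in pairs],
            "shared_mirnas": [";".join(p.shared_mirnas) for p in pairs],
            "n_shared": [len(p.shared_mirnas) for p in pairs],
            "r_lnc_mrna": [p.r_lnc_mrna for p in pairs],
            "p_corr": [p.p_corr for p in pairs],
            "p_hyper": [p.p_hyper for p in pairs],
            "reg_sim": [p.reg_sim for p in pairs],
            "passes_all": [p.passes_all for p in pairs],
        }
    )
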