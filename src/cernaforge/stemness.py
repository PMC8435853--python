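"""One-class logistic regression (OCLR) stemness index.

A weight vector w over features is fitted on pluripotent reference profiles
only (ESC/iPSC, PCBC-style), minimizing the strictly convex objective

    L(w) = (1/n) sum_i log(1 + exp(-w . x_i)) + (lambda / 2) ||w||^2 ,

so the optimum is unique for lambda > 0; the per-sample normalization makes
lambda comparable across reference sizes (and duplicating the reference
leaves the fit unchanged). A tumor sample's raw stemness is
the Spearman correlation between w and the sample's expression over the
model's features (the mRNAsi convention; Pearson switchable), and scores
are min-max scaled to [0, 1] within the cohort. Because the raw score is
rank-based it is invariant to any strictly monotone transform of a sample's
expression.

The reference matrix is taken as given; centering (typically against the
feature means of a pooled stem + tumor background, so that stem-elevated
features are positive) is the caller's preprocessing step — the synthetic
generator ships profiles already centered that way.
"""

from __future__ import annotations

import io
import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import yaml
from scipy import optimize, stats

from .errors import InputError
from .io_formats import ExpressionMatrix

log = logging.getLogger(__name__)


@dataclass
class StemnessModel:
    feature_ids: list[str]
    weights: np.ndarray
    lam: float
    n_iter: int
    objective: float
    converged: bool


def _objective(w: np.ndarray, x: np.ndarray, lam: float) -> tuple[float, np.ndarray]:
    n = x.shape[1]
    z = w @ x  # per-sample margin
    f = np.logaddexp(0.0, -z).mean() + 0.5 * lam * (w @ w)
    with np.errstate(over="ignore"):
        sig = 1.0 / (1.0 + np.exp(z))  # sigmoid(-z)
    grad = -(x @ sig) / n + lam * w
    return f, grad


def fit_oclr(
    reference: ExpressionMatrix,
    lam: float = 1.0,
    tol: float = 1e-10,
    max_iter: int = 1000,
    x0: np.ndarray | None = None,
) -> StemnessModel:
    """Fit the one-class weight vector on stem reference profiles.

    Quasi-Newton (L-BFGS) with the analytic gradient; converged when the
    relative objective change falls below ``tol`` (gradient tolerance 1e-9).
    The default tolerance is tight: the objective is strongly convex, so
    the extra iterations are cheap and refits from any starting point agree
    to high precision. Non-convergence at ``max_iter`` warns and returns
    the best iterate.
    """
    if lam <= 0:
        raise InputError("lambda must be > 0")
    x = reference.data.to_numpy(float)
    n_feat = x.shape[0]
    w0 = np.zeros(n_feat) if x0 is None else np.asarray(x0, dtype=float)
    if w0.shape != (n_feat,):
        raise InputError("x0 has the wrong dimension")
    res = optimize.minimize(
        _objective,
        w0,
        args=(x, lam),
        jac=True,
        method="L-BFGS-B",
        options={"maxiter": max_iter, "ftol": tol, "gtol": 1e-9},
    )
    if not res.success and res.status == 1:  # hit the iteration cap
        warnings.warn("OCLR did not converge within max_iter; returning best iterate",
                      stacklevel=2)
    return StemnessModel(
        feature_ids=reference.feature_ids,
        weights=np.asarray(res.x),
        lam=lam,
        n_iter=int(res.nit),
        objective=float(res.fun),
        converged=bool(res.success),
    )


def score_samples(
    model: StemnessModel,
    tumor: ExpressionMatrix,
    method: str = "spearman",
    min_overlap: float = 0.5,
) -> pd.DataFrame:
    """Stemness scores per tumor sample: raw rank correlation + cohort min-max.

    Model features missing from the tumor matrix are dropped (logged); fewer
    than ``min_overlap`` of them present is an error.
    """
    common = [f for f in model.feature_ids if f in set(tumor.feature_ids)]
    frac = len(common) / len(model.feature_ids)
    if frac < min_overlap:
        raise InputError(
            f"only {frac:.0%} of model features present in the tumor matrix "
            f"(minimum {min_overlap:.0%})"
        )
    if frac < 1.0:
        log.info("score_samples: %d model features absent from tumor matrix dropped",
                 len(model.feature_ids) - len(common))
    widx = {f: i for i, f in enumerate(model.feature_ids)}
    w = model.weights[[widx[f] for f in common]]
    x = tumor.data.loc[common].to_numpy(float)

    if method == "spearman":
        wr = stats.rankdata(w)
        xr = stats.rankdata(x, axis=0)
    elif method == "pearson":
        wr, xr = w, x
    else:
        raise InputError(f"unknown scoring method {method!r}")
    wc = wr - wr.mean()
    xc = xr - xr.mean(axis=0)
    denom = np.sqrt((wc**2).sum()) * np.sqrt((xc**2).sum(axis=0))
    with np.errstate(divide="ignore", invalid="ignore"):
        raw = (wc @ xc) / denom
    raw = np.clip(raw, -1.0, 1.0)

    lo, hi = np.nanmin(raw), np.nanmax(raw)
    scaled = np.full_like(raw, 0.5) if hi == lo else (raw - lo) / (hi - lo)
    return pd.DataFrame({"sample_id": tumor.sample_ids, "raw": raw, "scaled": scaled})


def score_gene_correlation(
    scores: pd.DataFrame,
    expr: ExpressionMatrix,
    gene_ids,
    method: str = "spearman",
) -> pd.DataFrame:
    """Correlation of each gene's expression with the scaled stemness score."""
    s = scores.set_index("sample_id")["scaled"]
    samples = [c for c in expr.sample_ids if c in s.index]
    if not samples:
        raise InputError("no overlap between scored samples and expression columns")
    sv = s.loc[samples].to_numpy(float)
    rows = []
    for g in gene_ids:
        x = expr.data.loc[g, samples].to_numpy(float)
        if np.var(x) == 0 or np.var(sv) == 0:
            rows.append(dict(gene_id=g, r=np.nan, p=np.nan, note="constant"))
            continue
        if method == "spearman":
            res = stats.spearmanr(x, sv)
            r, p = float(res.statistic), float(res.pvalue)
        else:
            res = stats.pearsonr(x, sv)
            r, p = float(res.statistic), float(res.pvalue)
        rows.append(dict(gene_id=g, r=r, p=p, note=""))
    return pd.DataFrame(rows, columns=["gene_id", "r", "p", "note"])


def write_model(model: StemnessModel, path) -> None:
    """Persist a model as a TSV (feature, weight) with a YAML comment header."""
    meta = yaml.safe_dump(
        dict(lam=model.lam, n_iter=model.n_iter, objective=model.objective,
             converged=model.converged),
        sort_keys=True,
    )
    with open(path, "w", encoding="utf-8") as fh:
        for line in meta.strip().splitlines():
            fh.write(f"# {line}\n")
        fh.write("feature_id\tweight\n")
        for f, w in zip(model.feature_ids, model.weights):
            fh.write(f"{f}\t{w:.10g}\n")


def read_model(path) -> StemnessModel:
    meta_lines = []
    with open(path, encoding="utf-8") as fh:
        body = []
        for line in fh:
            if line.startswith("# "):
                meta_lines.append(line[2:])
            else:
                body.append(line)
    meta = yaml.safe_load("".join(meta_lines)) or {}
    df = pd.read_csv(io.StringIO("".join(body)), sep="\t")
    return StemnessModel(
        feature_ids=list(df["feature_id"]),
        weights=df["weight"].to_numpy(float),
        lam=float(meta.get("lam", float("nan"))),
        n_iter=int(meta.get("n_iter", -1)),
        objective=float(meta.get("objective", float("nan"))),
        converged=bool(meta.get("converged", True)),
    )
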