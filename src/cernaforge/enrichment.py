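"""Signal-to-noise ranking and weighted-KS gene-set enrichment.

Genes are ranked between two phenotype groups by the signal-to-noise ratio
snr = (mu1 - mu2) / (sigma1 + sigma2), with each group's sigma floored at
max(0.2 * |mu|, 0.2) (the classic GSEA convention). The enrichment score is
the signed maximum deviation of a weighted Kolmogorov-Smirnov running sum:
walking down the ranking, a gene in the set increments by |snr| / sum of
|snr| over set members, a gene outside decrements by 1 / (N - N_hits).
Significance comes from phenotype-label permutation:

    p = (1 + #{|ES_perm| >= |ES_obs|}) / (1 + n_perm).

Nominal p only — no normalized ES or multi-set FDR machinery.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import InputError
from .io_formats import ExpressionMatrix

SIGMA_FLOOR_FRAC = 0.2
SIGMA_FLOOR_ABS = 0.2


@dataclass
class EnrichmentResult:
    set_name: str
    es: float
    p_perm: float
    n_perm: int


def _snr(x: np.ndarray, g1: np.ndarray) -> np.ndarray:
    """Signal-to-noise per row of x (features x samples) for mask g1."""
    x1, x2 = x[:, g1], x[:, ~g1]
    m1, m2 = x1.mean(axis=1), x2.mean(axis=1)
    s1 = np.std(x1, axis=1, ddof=1)
    s2 = np.std(x2, axis=1, ddof=1)
    s1 = np.maximum(s1, np.maximum(SIGMA_FLOOR_FRAC * np.abs(m1), SIGMA_FLOOR_ABS))
    s2 = np.maximum(s2, np.maximum(SIGMA_FLOOR_FRAC * np.abs(m2), SIGMA_FLOOR_ABS))
    return (m1 - m2) / (s1 + s2)


def signal_to_noise(matrix: ExpressionMatrix, groups) -> pd.DataFrame:
    """Ranked list: feature_id and snr, sorted by descending snr.

    ``groups`` is a boolean mask over the matrix's samples (True = group 1).
    Both groups need >= 3 samples. Ties are ordered by feature id so the
    ranking is deterministic.
    """
    g1 = np.asarray(groups, dtype=bool)
    if g1.size != len(matrix.sample_ids):
        raise InputError("group mask length does not match the sample count")
    if g1.sum() < 3 or (~g1).sum() < 3:
        raise InputError("each group needs >= 3 samples for the signal-to-noise ranking")
    snr = _snr(matrix.data.to_numpy(float), g1)
    out = pd.DataFrame({"feature_id": matrix.feature_ids, "snr": snr})
    return out.sort_values(["snr", "feature_id"], ascending=[False, True], kind="stable").reset_index(
        drop=True
    )


def _es_from_order(snr_ordered: np.ndarray, hits: np.ndarray) -> float:
    """ES given snr values in rank order and the boolean hit mask."""
    n = snr_ordered.size
    n_hits = int(hits.sum())
    w = np.abs(snr_ordered)
    hit_mass = w[hits].sum()
    steps = np.empty(n)
    if hit_mass > 0:
        steps[hits] = w[hits] / hit_mass
    else:  # all-zero weights: fall back to equal hit increments
        steps[hits] = 1.0 / n_hits
    if n_hits < n:
        steps[~hits] = -1.0 / (n - n_hits)
    running = np.cumsum(steps)
    return float(running[np.argmax(np.abs(running))])


def enrichment_score(ranked: pd.DataFrame, gene_set) -> float:
    """Weighted-KS enrichment score of ``gene_set`` on a ranked list.

    ``ranked`` is the output of :func:`signal_to_noise` (descending snr).
    """
    ids = ranked["feature_id"].to_numpy()
    hits = np.isin(ids, list(gene_set))
    if not hits.any():
        raise InputError("gene set does not intersect the ranked list")
    return _es_from_order(ranked["snr"].to_numpy(float), hits)


def permutation_p(
    matrix: ExpressionMatrix,
    groups,
    gene_set,
    n_perm: int = 1000,
    seed: int | None = None,
    set_name: str = "gene_set",
) -> EnrichmentResult:
    """Phenotype-permutation significance of the enrichment score."""
    if n_perm < 100:
        raise InputError("n_perm must be >= 100")
    g1 = np.asarray(groups, dtype=bool)
    x = matrix.data.to_numpy(float)
    ids = np.asarray(matrix.feature_ids)
    member = np.isin(ids, list(gene_set))
    if not member.any():
        raise InputError("gene set does not intersect the expression matrix")

    def es_for(mask: np.ndarray) -> float:
        snr = _snr(x, mask)
        order = np.lexsort((ids, -snr))
        return _es_from_order(snr[order], member[order])

    es_obs = es_for(g1)
    rng = np.random.default_rng(seed)
    n_exceed = 0
    for _ in range(n_perm):
        perm = rng.permutation(g1)
        if abs(es_for(perm)) >= abs(es_obs):
            n_exceed += 1
    p = (1 + n_exceed) / (1 + n_perm)
    return EnrichmentResult(set_name=set_name, es=es_obs, p_perm=p, n_perm=n_perm)


def read_gmt(path) -> dict[str, list[str]]:
    """GMT gene-set file: name <tab> description <tab> member ids..."""
    sets: dict[str, list[str]] = {}
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                continue
            sets[parts[0]] = [g for g in parts[2:] if g]
    return sets


def write_gmt(sets: dict[str, list[str]], path, description: str = "na") -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for name, members in sets.items():
            fh.write("\t".join([name, description, *members]) + "\n")
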