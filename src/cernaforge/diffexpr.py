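"""Two-group differential screening of one expression layer.

Patients are grouped by vascular-invasion status; every feature is tested
for a location shift between groups. The default test is the Wilcoxon
rank-sum (distribution-free on log expression, consistent with the
rank-based statistics used downstream), with Welch's t available. The
effect size is the difference of group means on the log2 scale. No
multiplicity correction is applied by default (screens at raw P < 0.05);
Benjamini-Hochberg can be switched on.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .errors import InputError
from .io_formats import ClinicalTable, ExpressionMatrix

DE_COLUMNS = ("feature_id", "layer", "log2fc", "p", "passes", "note")


def differential_screen(
    matrix: ExpressionMatrix,
    clinical: ClinicalTable,
    alpha: float = 0.05,
    test: str = "wilcoxon",
    adjust: str | None = None,
) -> pd.DataFrame:
    """Screen every feature of one layer; returns one row per feature.

    ``log2fc`` is mean(invasion) - mean(no_invasion). Features with zero
    pooled variance get p = 1, log2fc = 0 and note ``zero_variance``.
    ``adjust="bh"`` applies Benjamini-Hochberg before thresholding.
    """
    samples = matrix.sample_ids
    missing = set(samples) - set(clinical.sample_ids)
    if missing:
        raise InputError(f"{len(missing)} matrix samples absent from clinical table")
    g1 = clinical.group_mask(samples)
    g2 = ~g1
    if g1.sum() < 3 or g2.sum() < 3:
        raise InputError(
            f"need >= 3 samples per group, got {int(g1.sum())} invasion / {int(g2.sum())} control"
        )

    x = matrix.data.to_numpy(dtype=float)
    lfc = x[:, g1].mean(axis=1) - x[:, g2].mean(axis=1)
    constant = x.var(axis=1) == 0.0

    p = np.ones(x.shape[0])
    live = ~constant
    if live.any():
        if test == "wilcoxon":
            res = stats.mannwhitneyu(
                x[live][:, g1], x[live][:, g2], axis=-1, alternative="two-sided",
                method="asymptotic",
            )
            p[live] = res.pvalue
        elif test == "welch":
            res = stats.ttest_ind(x[live][:, g1], x[live][:, g2], axis=-1, equal_var=False)
            p[live] = res.pvalue
        else:
            raise InputError(f"unknown test {test!r}; expected 'wilcoxon' or 'welch'")
    lfc[constant] = 0.0

    p_thr = p
    if adjust == "bh":
        p_thr = stats.false_discovery_control(p, method="bh")
    elif adjust is not None:
        raise InputError(f"unknown adjustment {adjust!r}")

    return pd.DataFrame(
        {
            "feature_id": matrix.feature_ids,
            "layer": matrix.layer,
            "log2fc": lfc,
            "p": p,
            "passes": p_thr < alpha,
            "note": np.where(constant, "zero_variance", ""),
        },
        columns=list(DE_COLUMNS),
    )


def passing_set(de_result: pd.DataFrame) -> set[str]:
    """Ids of features that pass the screen."""
    return set(de_result.loc[de_result["passes"], "feature_id"])
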