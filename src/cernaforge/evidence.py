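"""Interaction-evidence filtering by per-source score thresholds.

lncRNA-miRNA records come from miRcode/LncBase-style flags; miRNA-mRNA
records carry miRDB scores, TargetScan context percentiles and miRanda
energies. An lncRNA edge is kept when flagged by miRcode OR
LncBase-experimental (union rule; intersection switchable). An mRNA edge is
kept when at least ``min_mrna_sources`` of {miRDB > 75, TargetScan
percentile > 50, miRanda energy < -15} pass — the printed thresholds, with
strict inequalities. Records referencing features outside the
differential-expression passing sets are dropped first.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import InputError
from .io_formats import validate_interactions

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class EvidenceThresholds:
    mirdb_min: float = 75.0
    targetscan_min_percentile: float = 50.0
    miranda_max_energy: float = -15.0
    min_mrna_sources: int = 2
    lncrna_rule: str = "union"  # or "intersection"

    def validate(self) -> None:
        for v in (self.mirdb_min, self.targetscan_min_percentile, self.miranda_max_energy):
            if not np.isfinite(v):
                raise InputError("evidence thresholds must be finite")
        if self.min_mrna_sources not in (1, 2, 3):
            raise InputError("min_mrna_sources must be 1, 2 or 3")
        if self.lncrna_rule not in ("union", "intersection"):
            raise InputError("lncrna_rule must be 'union' or 'intersection'")


def filter_evidence(
    records: pd.DataFrame,
    thresholds: EvidenceThresholds | None = None,
    de_sets: dict[str, set[str]] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Apply the per-source thresholds; returns (lnc_edges, mrna_edges, report).

    ``de_sets`` maps layer -> passing feature ids ({"mRNA", "lncRNA",
    "miRNA"}); when given, records whose miRNA or target is not in the
    corresponding set are dropped (count logged). Edge frames keep the score
    columns plus boolean per-source pass flags (provenance) and, for mRNA
    edges, the number of passing sources.
    """
    thresholds = thresholds or EvidenceThresholds()
    thresholds.validate()
    df = validate_interactions(records.copy())

    n_in = len(df)
    if de_sets is not None:
        mir_ok = df["source_id"].isin(de_sets.get("miRNA", set())).to_numpy()
        tgt_ok = np.zeros(len(df), dtype=bool)
        for layer in ("mRNA", "lncRNA"):
            m = (df["target_layer"] == layer).to_numpy()
            tgt_ok[m] = df.loc[m, "target_id"].isin(de_sets.get(layer, set())).to_numpy()
        df = df[mir_ok & tgt_ok]
    n_dropped_de = n_in - len(df)
    if n_dropped_de:
        log.info("filter_evidence: dropped %d records outside the DE-passing sets", n_dropped_de)

    def col(frame: pd.DataFrame, name: str) -> pd.Series:
        return frame[name] if name in frame.columns else pd.Series(np.nan, index=frame.index)

    lnc = df[df["target_layer"] == "lncRNA"].copy()
    mircode = col(lnc, "mircode").fillna(0).astype(bool)
    lncbase = col(lnc, "lncbase_experimental").fillna(0).astype(bool)
    lnc["pass_mircode"] = mircode
    lnc["pass_lncbase"] = lncbase
    if thresholds.lncrna_rule == "union":
        lnc_keep = mircode | lncbase
    else:
        lnc_keep = mircode & lncbase
    lnc_edges = lnc[lnc_keep].reset_index(drop=True)

    mrna = df[df["target_layer"] == "mRNA"].copy()
    p_mirdb = col(mrna, "mirdb_score") > thresholds.mirdb_min
    p_ts = col(mrna, "targetscan_percentile") > thresholds.targetscan_min_percentile
    p_mira = col(mrna, "miranda_energy") < thresholds.miranda_max_energy
    mrna["pass_mirdb"] = p_mirdb.fillna(False)
    mrna["pass_targetscan"] = p_ts.fillna(False)
    mrna["pass_miranda"] = p_mira.fillna(False)
    mrna["n_sources"] = (
        mrna["pass_mirdb"].astype(int)
        + mrna["pass_targetscan"].astype(int)
        + mrna["pass_miranda"].astype(int)
    )
    mrna_edges = mrna[mrna["n_sources"] >= thresholds.min_mrna_sources].reset_index(drop=True)

    report = {
        "n_records": n_in,
        "n_dropped_not_de": n_dropped_de,
        "n_lnc_candidates": int(len(lnc)),
        "n_lnc_edges": int(len(lnc_edges)),
        "n_mrna_candidates": int(len(mrna)),
        "n_mrna_edges": int(len(mrna_edges)),
    }
    return lnc_edges, mrna_edges, report


def targets_by_mirna(edges: pd.DataFrame) -> dict[str, set[str]]:
    """miRNA id -> set of its retained targets."""
    return {m: set(sub["target_id"]) for m, sub in edges.groupby("source_id")}


def mirnas_by_target(edges: pd.DataFrame) -> dict[str, set[str]]:
    """Target id -> set of miRNAs with retained evidence against it."""
    return {t: set(sub["source_id"]) for t, sub in edges.groupby("target_id")}
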