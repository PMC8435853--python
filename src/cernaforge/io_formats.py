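"""Tables and graph exports.

Every table the pipeline touches is a UTF-8 tab-separated file with a header
row and "." as the decimal mark; floats are written with 6 significant
digits so that write-then-read round-trips are stable. Networks are exported
as SIF and GraphML (Cytoscape-compatible) via networkx.

In-memory containers
--------------------
ExpressionMatrix
    One molecular layer (mRNA / lncRNA / miRNA): a features x samples
    DataFrame of log-scale values plus the layer tag.
ClinicalTable
    Per-sample invasion-group label, survival time (days) and event flag,
    with optional extra covariates.
Interaction evidence
    A plain DataFrame, one row per candidate miRNA->target record with
    per-source score columns (miRDB score, TargetScan context percentile,
    miRanda energy, miRcode / LncBase-experimental flags).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .errors import AlignmentError, ExportError, FormatError, InputError

log = logging.getLogger(__name__)

LAYERS = ("mRNA", "lncRNA", "miRNA")
GROUPS = ("invasion", "no_invasion")

#: score columns recognized in interaction-evidence tables
SCORE_COLUMNS = (
    "mirdb_score",
    "targetscan_percentile",
    "miranda_energy",
    "mircode",
    "lncbase_experimental",
)

FLOAT_FORMAT = "%.6g"


@dataclass
class ExpressionMatrix:
    """One expression layer: features x samples, log scale."""

    layer: str
    data: pd.DataFrame

    def __post_init__(self) -> None:
        if self.layer not in LAYERS:
            raise FormatError(f"unknown layer {self.layer!r}; expected one of {LAYERS}")
        if self.data.index.has_duplicates:
            dup = self.data.index[self.data.index.duplicated()][0]
            raise FormatError(f"duplicate feature id {dup!r} in {self.layer} matrix")
        if self.data.columns.has_duplicates:
            dup = self.data.columns[self.data.columns.duplicated()][0]
            raise FormatError(f"duplicate sample id {dup!r} in {self.layer} matrix")
        if self.data.isna().any().any():
            raise FormatError(f"{self.layer} matrix contains missing values after load")

    @property
    def feature_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    def restrict(self, samples: Sequence[str]) -> "ExpressionMatrix":
        return ExpressionMatrix(self.layer, self.data.loc[:, list(samples)].copy())


@dataclass
class ClinicalTable:
    """Per-sample clinical annotations, indexed by sample id."""

    data: pd.DataFrame

    REQUIRED = ("group", "time", "event")

    def __post_init__(self) -> None:
        df = self.data
        for col in self.REQUIRED:
            if col not in df.columns:
                raise FormatError(f"clinical table missing column {col!r}")
        if df.index.has_duplicates:
            dup = df.index[df.index.duplicated()][0]
            raise FormatError(f"duplicate sample id {dup!r} in clinical table")
        bad_group = set(df["group"]) - set(GROUPS)
        if bad_group:
            raise FormatError(f"unknown group labels {sorted(bad_group)}; expected {GROUPS}")
        if (df["time"] < 0).any():
            raise FormatError("negative survival time in clinical table")
        if not df["event"].isin((0, 1)).all():
            raise FormatError("event indicator must be 0 or 1")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    def restrict(self, samples: Sequence[str]) -> "ClinicalTable":
        return ClinicalTable(self.data.loc[list(samples)].copy())

    def group_mask(self, samples: Sequence[str] | None = None, group: str = "invasion") -> np.ndarray:
        """Boolean mask (aligned to *samples* order) for membership in *group*."""
        df = self.data if samples is None else self.data.loc[list(samples)]
        return (df["group"] == group).to_numpy()


# ---------------------------------------------------------------------------
# expression tables


def read_expression(path, layer: str, max_missing_frac: float = 0.2) -> ExpressionMatrix:
    """Load a features x samples TSV for one layer.

    Features with a missing fraction strictly above ``max_missing_frac`` are
    dropped; remaining missing cells are imputed with the feature's median of
    observed values. The number of dropped features is logged.
    """
    raw = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    if raw.index.has_duplicates:
        dup = raw.index[raw.index.duplicated()][0]
        raise FormatError(f"duplicated feature row {dup!r} in {path}")
    values = raw.apply(lambda c: pd.to_numeric(c, errors="coerce")).astype(float)
    bad = values.isna() & raw.notna()
    if bad.any().any():
        r, c = np.argwhere(bad.to_numpy())[0]
        raise FormatError(
            f"non-numeric cell at feature {raw.index[r]!r}, sample {raw.columns[c]!r} in {path}"
        )
    missing_frac = values.isna().mean(axis=1)
    keep = missing_frac <= max_missing_frac
    n_dropped = int((~keep).sum())
    if n_dropped:
        log.info("read_expression(%s): dropped %d features with >%.0f%% missing",
                 path, n_dropped, 100 * max_missing_frac)
    values = values.loc[keep]
    if values.isna().any().any():
        medians = values.median(axis=1)
        values = values.apply(lambda row: row.fillna(medians[row.name]), axis=1)
    return ExpressionMatrix(layer, values)


def write_expression(matrix: ExpressionMatrix, path) -> None:
    matrix.data.to_csv(path, sep="\t", float_format=FLOAT_FORMAT, index_label="feature_id")


# ---------------------------------------------------------------------------
# clinical tables


def read_clinical(path) -> ClinicalTable:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return ClinicalTable(df)


def write_clinical(table: ClinicalTable, path) -> None:
    table.data.to_csv(path, sep="\t", float_format=FLOAT_FORMAT, index_label="sample_id")


# ---------------------------------------------------------------------------
# interaction evidence


def validate_interactions(df: pd.DataFrame) -> pd.DataFrame:
    """Check an interaction-evidence table: required keys and >=1 score field."""
    for col in ("source_id", "target_id", "target_layer"):
        if col not in df.columns:
            raise FormatError(f"interaction table missing column {col!r}")
    present = [c for c in SCORE_COLUMNS if c in df.columns]
    if not present:
        raise FormatError(f"interaction table has no recognized score column among {SCORE_COLUMNS}")
    bad_layer = set(df["target_layer"]) - {"mRNA", "lncRNA"}
    if bad_layer:
        raise FormatError(f"unknown target layers {sorted(bad_layer)}")
    if df[present].isna().all(axis=1).any():
        idx = df.index[df[present].isna().all(axis=1)][0]
        raise FormatError(f"interaction record {idx} carries no score in any recognized field")
    return df


def read_interactions(path) -> pd.DataFrame:
    return validate_interactions(pd.read_csv(path, sep="\t"))


def write_interactions(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", float_format=FLOAT_FORMAT, index=False)


# ---------------------------------------------------------------------------
# sample alignment


def align_samples(*matrices: ExpressionMatrix, clinical: ClinicalTable | None = None):
    """Restrict all inputs to their common samples, in sorted order.

    Returns the matrices (and the clinical table, if given) in input order.
    Raises :class:`AlignmentError` when the intersection is empty.
    """
    if len(matrices) + (clinical is not None) < 2:
        raise InputError("align_samples needs at least two inputs")
    common: set[str] | None = None
    for m in matrices:
        common = set(m.sample_ids) if common is None else common & set(m.sample_ids)
    if clinical is not None:
        cset = set(clinical.sample_ids)
        common = cset if common is None else common & cset
    if not common:
        raise AlignmentError("no common samples across inputs")
    order = sorted(common)
    n_dropped = sum(len(m.sample_ids) - len(order) for m in matrices)
    if clinical is not None:
        n_dropped += len(clinical.sample_ids) - len(order)
    if n_dropped:
        log.info("align_samples: %d sample columns dropped outside the common set", n_dropped)
    out = [m.restrict(order) for m in matrices]
    if clinical is not None:
        out.append(clinical.restrict(order))
    return tuple(out)


# ---------------------------------------------------------------------------
# network export


def network_graph(pairs: Iterable, tf_ids: Iterable[str] = (), survival_p: dict | None = None) -> nx.Graph:
    """Build the undirected ceRNA graph: lncRNA -"sponges"- miRNA -"targets"- mRNA.

    Node attributes: ``layer``, ``is_tf`` and (when known) ``survival_p``.
    Edge attributes carry the parent pair's statistics (shared-miRNA count,
    hypergeometric p, regulation similarity); when an edge supports several
    pairs the smallest hypergeometric p wins.
    """
    pairs = list(pairs)
    if not pairs:
        raise ExportError("cannot export an empty network")
    tf_set = set(tf_ids)
    survival_p = survival_p or {}
    g = nx.Graph()
    for p in pairs:
        if not p.shared_mirnas:
            raise ExportError(
                f"pair ({p.lncrna_id}, {p.mrna_id}) has no shared miRNA (dangling reference)"
            )
        for node, layer in ((p.lncrna_id, "lncRNA"), (p.mrna_id, "mRNA")):
            g.add_node(node, layer=layer, is_tf=bool(node in tf_set))
            if node in survival_p:
                g.nodes[node]["survival_p"] = float(survival_p[node])
        attrs = dict(
            shared_mirna_count=len(p.shared_mirnas),
            p_hyper=float(p.p_hyper),
            reg_sim=float(p.reg_sim),
        )
        for mir in p.shared_mirnas:
            g.add_node(mir, layer="miRNA", is_tf=False)
            for u, v, rel in ((p.lncrna_id, mir, "sponges"), (mir, p.mrna_id, "targets")):
                if g.has_edge(u, v) and g.edges[u, v].get("p_hyper", 1.0) <= attrs["p_hyper"]:
                    continue
                g.add_edge(u, v, relation=rel, **attrs)
    return g


def export_network(pairs, sif_path, graphml_path, tf_ids=(), survival_p=None) -> nx.Graph:
    """Write the ceRNA network as SIF and GraphML; returns the graph."""
    g = network_graph(pairs, tf_ids=tf_ids, survival_p=survival_p)
    lines = sorted(f"{u}\t{d['relation']}\t{v}" for u, v, d in g.edges(data=True))
    with open(sif_path, "w", encoding="utf-8") as fh:
        fh.write("\n".join(lines) + "\n")
    nx.write_graphml(g, graphml_path)
    return g


def read_graphml(path) -> nx.Graph:
    return nx.read_graphml(path)
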