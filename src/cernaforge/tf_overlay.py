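"""Transcription-factor overlay and hub-lncRNA extraction.

The knockdown-derived TF analysis reduces, on the network side, to set
membership plus degree counting: annotate each surviving network mRNA as a
transcription factor from a user-supplied identifier list, keep the pairs
whose mRNA is a TF, and rank lncRNAs by the number of distinct TFs they
reach through shared miRNAs. The headline pattern is one hub lncRNA
sponging the miRNAs of several surviving TFs simultaneously.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import pandas as pd

from .cerna import CeRNAPair


@dataclass
class TFSubnetwork:
    """TF-restricted pairs plus the hub ranking."""

    pairs: list[CeRNAPair]
    hub_table: pd.DataFrame  # lncrna_id, n_tfs, tfs
    top_hubs: list[str]

    @property
    def triplets(self) -> list[tuple[str, str, str]]:
        """Every (lncRNA, miRNA, TF) triplet in the subnetwork."""
        out = []
        for p in self.pairs:
            out.extend((p.lncrna_id, m, p.mrna_id) for m in p.shared_mirnas)
        return sorted(out)


def annotate_tfs(mrna_ids, tf_ids, source: str = "tf_list") -> pd.DataFrame:
    """Per-mRNA TF annotation table."""
    tf_set = set(tf_ids)
    return pd.DataFrame(
        {
            "mrna_id": list(mrna_ids),
            "is_tf": [m in tf_set for m in mrna_ids],
            "source": source,
        }
    )


def extract_tf_subnetwork(pairs: list[CeRNAPair], tf_ids) -> TFSubnetwork:
    """Restrict to TF mRNAs and rank lncRNAs by distinct TFs reached.

    Hubs tied at the maximum degree are all reported, in lexicographic
    order; nothing is dropped by tie-breaking. An empty result (no TF in
    the network) yields an empty subnetwork with a warning.
    """
    tf_set = set(tf_ids)
    kept = [p for p in pairs if p.mrna_id in tf_set]
    if not kept:
        warnings.warn("no transcription factor found in the network", stacklevel=2)
        empty = pd.DataFrame(columns=["lncrna_id", "n_tfs", "tfs"])
        return TFSubnetwork(pairs=[], hub_table=empty, top_hubs=[])

    reach: dict[str, set[str]] = {}
    for p in kept:
        reach.setdefault(p.lncrna_id, set()).add(p.mrna_id)
    hub_table = (
        pd.DataFrame(
            {
                "lncrna_id": list(reach),
                "n_tfs": [len(v) for v in reach.values()],
                "tfs": [";".join(sorted(v)) for v in reach.values()],
            }
        )
        .sort_values(["n_tfs", "lncrna_id"], ascending=[False, True])
        .reset_index(drop=True)
    )
    max_deg = int(hub_table["n_tfs"].max())
    top_hubs = sorted(hub_table.loc[hub_table["n_tfs"] == max_deg, "lncrna_id"])
    return TFSubnetwork(pairs=kept, hub_table=hub_table, top_hubs=top_hubs)
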