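"""End-to-end pipeline: simulate -> de -> evidence -> cerna -> survival -> tf
-> enrich -> stemness, with one config, a JSON-lines audit log and a
deterministic run manifest.

Every threshold of the analysis is surfaced in :class:`PipelineConfig` with
the published defaults (alpha = 0.05 at every screen, miRDB > 75,
TargetScan percentile > 50, miRanda energy < -15, regulation similarity >=
0.5); nothing is hard-coded inside the stages. Each stage appends a JSON
line with its input/output counts, producing the candidate -> filtered ->
survival-retained funnel as the audit trail. The manifest records the
package version, seed, full config, funnel counts and SHA-256 of every
output file; reruns with the same config hash to the same manifest.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .cerna import build_pairs, negative_correlation_filter, pairs_to_frame
from .diffexpr import differential_screen, passing_set
from .enrichment import permutation_p, signal_to_noise
from .errors import ConfigurationError
from .evidence import EvidenceThresholds, filter_evidence
from .io_formats import align_samples, export_network, write_interactions
from .stemness import fit_oclr, score_gene_correlation, score_samples, write_model
from .survival import km_median_split_screen, prune_network
from .synthetic import SimulationConfig, simulate_cohort, simulate_stemness
from .tf_overlay import extract_tf_subnetwork

STAGES = ("simulate", "de", "evidence", "cerna", "survival", "tf", "enrich", "stemness")


@dataclass(frozen=True)
class PipelineConfig:
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    thresholds: EvidenceThresholds = field(default_factory=EvidenceThresholds)
    alpha_de: float = 0.05
    de_test: str = "wilcoxon"
    alpha_corr: float = 0.05
    alpha_pairs: float = 0.05  # correlation + hypergeometric screens in build_pairs
    reg_sim_min: float = 0.5
    corr_method: str = "pearson"
    reg_sim_formula: str = "normdiff"
    alpha_survival: float = 0.05
    cut_quantile: float = 0.5
    n_perm: int = 500
    stemness_lambda: float = 1.0
    outdir: str = "cernaforge_run"

    def validate(self) -> None:
        self.simulation.validate()
        self.thresholds.validate()
        for a in (self.alpha_de, self.alpha_corr, self.alpha_pairs, self.alpha_survival):
            if not (0 < a <= 1):
                raise ConfigurationError("alpha thresholds must lie in (0, 1]")
        if not (0 <= self.reg_sim_min <= 1):
            raise ConfigurationError("reg_sim_min must lie in [0, 1]")
        if not (0 < self.cut_quantile < 1):
            raise ConfigurationError("cut_quantile must lie in (0, 1)")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if "simulation" in d and isinstance(d["simulation"], dict):
            d["simulation"] = SimulationConfig(**d["simulation"])
        if "thresholds" in d and isinstance(d["thresholds"], dict):
            d["thresholds"] = EvidenceThresholds(**d["thresholds"])
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path, encoding="utf-8") as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})


@dataclass
class CohortAnalysis:
    """In-memory results of the core inference chain on one cohort."""

    de_sets: dict[str, set[str]]
    lnc_edges: pd.DataFrame
    mrna_edges: pd.DataFrame
    all_pairs: list
    passing_pairs: list
    survival: pd.DataFrame
    pruned_pairs: list
    tf_subnetwork: object | None


def analyze_cohort(cohort, config: PipelineConfig | None = None) -> CohortAnalysis:
    """Run de -> evidence -> correlation -> pairs -> survival -> tf in memory.

    The file-writing pipeline (:func:`run_all`) follows the same chain; this
    entry point serves programmatic experiments on a simulated cohort.
    """
    config = config or PipelineConfig()
    mrna, lncrna, mirna, clinical = align_samples(
        cohort.mrna, cohort.lncrna, cohort.mirna, clinical=cohort.clinical
    )
    de_sets = {
        layer: passing_set(differential_screen(m, clinical, config.alpha_de, config.de_test))
        for layer, m in (("mRNA", mrna), ("lncRNA", lncrna), ("miRNA", mirna))
    }
    lnc_edges, mrna_edges, _ = filter_evidence(cohort.interactions, config.thresholds, de_sets)
    lnc_edges = negative_correlation_filter(
        lnc_edges, mirna, lncrna, config.alpha_corr, config.corr_method
    )
    mrna_edges = negative_correlation_filter(
        mrna_edges, mirna, mrna, config.alpha_corr, config.corr_method
    )
    all_pairs, passing = build_pairs(
        lnc_edges, mrna_edges, lncrna, mrna, mirna,
        alpha=config.alpha_pairs, reg_sim_min=config.reg_sim_min,
        method=config.corr_method, reg_sim_formula=config.reg_sim_formula,
    )
    net_mrnas = sorted({p.mrna_id for p in passing})
    surv = km_median_split_screen(
        mrna, clinical, features=net_mrnas,
        alpha=config.alpha_survival, cut_quantile=config.cut_quantile,
    )
    pruned = []
    if passing:
        pruned, _ = prune_network(passing, surv, config.alpha_survival)
    sub = extract_tf_subnetwork(pruned, cohort.tf_ids) if pruned else None
    return CohortAnalysis(
        de_sets=de_sets, lnc_edges=lnc_edges, mrna_edges=mrna_edges,
        all_pairs=all_pairs, passing_pairs=passing, survival=surv,
        pruned_pairs=pruned, tf_subnetwork=sub,
    )


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_all(config: PipelineConfig) -> dict:
    """Run all eight stages; returns (and writes) the run manifest."""
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    log_path = outdir / "log.jsonl"
    log_fh = open(log_path, "w", encoding="utf-8")
    stages_done: list[str] = []
    funnel: dict[str, int] = {}

    def stage_log(stage: str, **counts) -> None:
        rec = {"stage": stage, **counts}
        log_fh.write(json.dumps(rec, sort_keys=True) + "\n")
        stages_done.append(stage)

    try:
        # 1. simulate ------------------------------------------------------
        cohort = simulate_cohort(config.simulation)
        cohort.write(outdir / "inputs")
        stage_log(
            "simulate",
            n_samples=config.simulation.n_samples,
            n_planted_triplets=config.simulation.n_planted_triplets,
            n_interactions=len(cohort.interactions),
        )

        mrna, lncrna, mirna, clinical = align_samples(
            cohort.mrna, cohort.lncrna, cohort.mirna, clinical=cohort.clinical
        )

        # 2. differential screening ---------------------------------------
        de = {
            "mRNA": differential_screen(mrna, clinical, config.alpha_de, config.de_test),
            "lncRNA": differential_screen(lncrna, clinical, config.alpha_de, config.de_test),
            "miRNA": differential_screen(mirna, clinical, config.alpha_de, config.de_test),
        }
        de_sets = {layer: passing_set(tab) for layer, tab in de.items()}
        for layer, tab in de.items():
            tab.to_csv(outdir / f"de_{layer.lower()}.tsv", sep="\t", index=False,
                       float_format="%.6g")
        funnel.update(
            de_mrna=len(de_sets["mRNA"]), de_lncrna=len(de_sets["lncRNA"]),
            de_mirna=len(de_sets["miRNA"]),
        )
        stage_log("de", **{k: funnel[k] for k in ("de_mrna", "de_lncrna", "de_mirna")})

        # 3. evidence thresholds ------------------------------------------
        lnc_edges, mrna_edges, ev_report = filter_evidence(
            cohort.interactions, config.thresholds, de_sets
        )
        # criterion (A): miRNA-target expression must be negatively correlated
        lnc_edges = negative_correlation_filter(
            lnc_edges, mirna, lncrna, config.alpha_corr, config.corr_method
        )
        mrna_edges = negative_correlation_filter(
            mrna_edges, mirna, mrna, config.alpha_corr, config.corr_method
        )
        write_interactions(lnc_edges, outdir / "edges_lncrna.tsv")
        write_interactions(mrna_edges, outdir / "edges_mrna.tsv")
        funnel.update(lnc_edges=len(lnc_edges), mrna_edges=len(mrna_edges))
        stage_log("evidence", **ev_report, lnc_edges_kept=len(lnc_edges),
                  mrna_edges_kept=len(mrna_edges))

        # 4. ceRNA pairs ---------------------------------------------------
        all_pairs, passing = build_pairs(
            lnc_edges, mrna_edges, lncrna, mrna, mirna,
            alpha=config.alpha_pairs, reg_sim_min=config.reg_sim_min,
            method=config.corr_method, reg_sim_formula=config.reg_sim_formula,
        )
        pairs_to_frame(all_pairs).to_csv(outdir / "pairs_candidates.tsv", sep="\t",
                                         index=False, float_format="%.6g")
        pairs_to_frame(passing).to_csv(outdir / "pairs_passing.tsv", sep="\t",
                                       index=False, float_format="%.6g")
        funnel.update(candidate_pairs=len(all_pairs), passing_pairs=len(passing))
        stage_log("cerna", candidate_pairs=len(all_pairs), passing_pairs=len(passing))

        # 5. survival pruning ---------------------------------------------
        net_mrnas = sorted({p.mrna_id for p in passing})
        surv = km_median_split_screen(
            mrna, clinical, features=net_mrnas,
            alpha=config.alpha_survival, cut_quantile=config.cut_quantile,
        )
        surv.to_csv(outdir / "survival_screen.tsv", sep="\t", index=False,
                    float_format="%.6g")
        pruned, prune_report = ([], {"n_pairs_in": 0, "n_pairs_retained": 0,
                                     "n_mrnas_passing": 0})
        if passing:
            pruned, prune_report = prune_network(passing, surv, config.alpha_survival)
        pairs_to_frame(pruned).to_csv(outdir / "pairs_pruned.tsv", sep="\t",
                                      index=False, float_format="%.6g")
        funnel.update(retained_pairs=len(pruned))
        stage_log("survival", **prune_report)

        # 6. transcription-factor overlay ---------------------------------
        sub = extract_tf_subnetwork(pruned, cohort.tf_ids) if pruned else None
        if sub is not None and sub.pairs:
            sub.hub_table.to_csv(outdir / "hub_ranking.tsv", sep="\t", index=False)
            survival_p = dict(zip(surv["feature_id"], surv["p_logrank"]))
            export_network(
                sub.pairs, outdir / "network.sif", outdir / "network.graphml",
                tf_ids=cohort.tf_ids, survival_p=survival_p,
            )
            top_hubs, tf_pairs = sub.top_hubs, len(sub.pairs)
        else:
            top_hubs, tf_pairs = [], 0
        funnel.update(tf_pairs=tf_pairs)
        stage_log("tf", tf_pairs=tf_pairs, top_hubs=top_hubs)

        # 7. enrichment around the hub lncRNA ------------------------------
        if top_hubs:
            hub = top_hubs[0]
            hub_expr = lncrna.data.loc[hub].to_numpy(float)
            hub_high = hub_expr > np.median(hub_expr)
            gene_set = sorted({p.mrna_id for p in pruned})
        else:  # fall back to an invasion-group enrichment of DE mRNAs
            hub = None
            hub_high = clinical.group_mask(mrna.sample_ids)
            gene_set = sorted(de_sets["mRNA"]) or mrna.feature_ids[:5]
        ranked = signal_to_noise(mrna, hub_high)
        ranked.to_csv(outdir / "snr_ranking.tsv", sep="\t", index=False,
                      float_format="%.6g")
        enr = permutation_p(
            mrna, hub_high, gene_set, n_perm=config.n_perm,
            seed=config.simulation.seed + 1, set_name="network_mrnas",
        )
        stage_log("enrich", hub=hub, es=round(enr.es, 6), p_perm=enr.p_perm,
                  n_perm=enr.n_perm, set_size=len(gene_set))

        # 8. stemness ------------------------------------------------------
        reference, tumor, gradient = simulate_stemness(seed=config.simulation.seed + 2)
        model = fit_oclr(reference, lam=config.stemness_lambda)
        scores = score_samples(model, tumor)
        scores.to_csv(outdir / "stemness_scores.tsv", sep="\t", index=False,
                      float_format="%.6g")
        write_model(model, outdir / "stemness_model.tsv")
        from scipy import stats as _st

        grad_rho = float(_st.spearmanr(scores["scaled"], gradient.loc[scores["sample_id"]]).statistic)
        sig_corr = score_gene_correlation(scores, tumor, tumor.feature_ids[:3])
        sig_corr.to_csv(outdir / "stemness_gene_correlation.tsv", sep="\t", index=False,
                        float_format="%.6g")
        stage_log("stemness", n_scored=len(scores), gradient_spearman=round(grad_rho, 6),
                  converged=model.converged)
    except Exception as exc:
        log_fh.write(json.dumps({"stage": "error", "failed_after": stages_done,
                                 "error": str(exc)}) + "\n")
        log_fh.close()
        raise
    log_fh.close()

    files = {
        p.name: _sha256(p)
        for p in sorted(outdir.rglob("*"))
        if p.is_file() and p.name != "run_manifest.yaml"
    }
    manifest = {
        "package": "cernaforge",
        "version": __version__,
        "seed": config.simulation.seed,
        "config": config.to_dict(),
        "stages": stages_done,
        "funnel": funnel,
        "files": files,
    }
    hashed = {k: v for k, v in manifest.items()}
    hashed["config"] = {k: v for k, v in manifest["config"].items() if k != "outdir"}
    manifest["manifest_hash"] = hashlib.sha256(
        json.dumps(hashed, sort_keys=True).encode()
    ).hexdigest()
    with open(outdir / "run_manifest.yaml", "w", encoding="utf-8") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=True)
    return manifest
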