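import numpy as np
import pytest
from scipy import stats

from cernaforge.errors import ConfigurationError
from cernaforge.synthetic import (
    SimulationConfig,
    hub_experiment_config,
    simulate_cohort,
    simulate_stemness,
)


class TestConfigValidation:
    @pytest.mark.parametrize(
        "kw",
        [
            dict(frac_group1=0.0),
            dict(frac_group1=1.0),
            dict(noise_sd=0.0),
            dict(n_samples=0),
            dict(n_planted_triplets=-1),
            dict(sponge_strength=1.5),
            dict(n_planted_triplets=20, n_lncrna=10),
            dict(n_planted_triplets=20, mirnas_per_triplet=3, n_mirna=40),
        ],
    )
    def test_invalid_configs_rejected(self, kw):
        with pytest.raises(ConfigurationError):
            simulate_cohort(SimulationConfig(**kw))


class TestDeterminism:
    def test_identical_seed_gives_byte_identical_files(self, tmp_path):
        for d in ("a", "b"):
            simulate_cohort(SimulationConfig(seed=7)).write(tmp_path / d)
        for f in sorted((tmp_path / "a").iterdir()):
            assert f.read_bytes() == (tmp_path / "b" / f.name).read_bytes(), f.name

    def test_different_seeds_differ(self):
        a = simulate_cohort(SimulationConfig(seed=1))
        b = simulate_cohort(SimulationConfig(seed=2))
        assert not np.allclose(a.mrna.data.to_numpy(), b.mrna.data.to_numpy())


class TestGenerativeStructure:
    def test_no_signal_config_has_no_strong_cross_layer_correlation(self):
        cfg = SimulationConfig(
            seed=5, n_planted_triplets=0, sponge_strength=0.0,
            n_mrna=30, n_lncrna=10, n_mirna=10, n_decoy_interactions=0,
        )
        co = simulate_cohort(cfg)
        for x, y in [(co.mirna, co.lncrna), (co.mirna, co.mrna), (co.lncrna, co.mrna)]:
            r = np.corrcoef(x.data.to_numpy(), y.data.to_numpy())[: x.shape[0], x.shape[0]:]
            assert np.abs(r).max() < 0.3

    def test_planted_triplet_sign_pattern(self):
        """Sponge coupling forces miRNA down, lncRNA/mRNA up, together."""
        for seed in range(30):
            co = simulate_cohort(SimulationConfig(seed=seed, n_samples=200))
            for l, m, r in co.truth.planted_triplets:
                xm = co.mirna.data.loc[m].to_numpy()
                xl = co.lncrna.data.loc[l].to_numpy()
                xr = co.mrna.data.loc[r].to_numpy()
                assert np.corrcoef(xm, xl)[0, 1] < 0
                assert np.corrcoef(xm, xr)[0, 1] < 0
                assert np.corrcoef(xl, xr)[0, 1] > 0

    def test_group_fraction_within_binomial_ci(self):
        fracs = []
        for seed in range(20):
            co = simulate_cohort(SimulationConfig(seed=seed))
            fracs.append((co.clinical.data["group"] == "invasion").mean())
        n, p = 200, 0.35
        lo, hi = stats.binom.ppf([0.005, 0.995], n, p) / n
        assert sum(lo <= f <= hi for f in fracs) >= 18  # 99% CI, 20 draws

    def test_truth_ids_exist_in_matrices(self, default_cohort):
        co = default_cohort
        for l, m, r in co.truth.planted_triplets:
            assert l in co.lncrna.feature_ids
            assert m in co.mirna.feature_ids
            assert r in co.mrna.feature_ids
        assert set(co.truth.true_survival_genes) <= set(co.mrna.feature_ids)

    def test_planted_edges_always_pass_default_thresholds(self, default_cohort):
        co = default_cohort
        planted = co.truth.planted_mrna_edges
        tab = co.mrna_interactions.set_index(["source_id", "target_id"])
        for edge in planted:
            row = tab.loc[edge]
            assert row["mirdb_score"] > 75
            assert row["targetscan_percentile"] > 50
            assert row["miranda_energy"] < -15
        lnc_tab = co.lnc_interactions.set_index(["source_id", "target_id"])
        for edge in co.truth.planted_lnc_edges:
            row = lnc_tab.loc[edge]
            assert row["mircode"] == 1 and row["lncbase_experimental"] == 1

    def test_decoy_scores_straddle_each_threshold(self):
        co = simulate_cohort(SimulationConfig(seed=3, n_decoy_interactions=2000))
        planted = co.truth.planted_mrna_edges
        keys = list(zip(co.mrna_interactions["source_id"], co.mrna_interactions["target_id"]))
        decoy = co.mrna_interactions[[k not in planted for k in keys]]
        n = len(decoy)
        ci = 3 * np.sqrt(0.25 / n)  # ~3 sigma binomial band around 0.5
        assert abs((decoy["mirdb_score"] > 75).mean() - 0.5) < ci
        assert abs((decoy["targetscan_percentile"] > 50).mean() - 0.5) < ci
        assert abs((decoy["miranda_energy"] < -15).mean() - 0.5) < ci

    def test_null_condition_removes_group_shift(self):
        """With the sponge off, planted features carry no invasion signal."""
        co = simulate_cohort(SimulationConfig(seed=4, sponge_strength=0.0))
        assert co.truth.planted_de_features == {"mRNA": [], "lncRNA": [], "miRNA": []}
        g1 = co.clinical.group_mask(co.mrna.sample_ids)
        x = co.mrna.data.iloc[0].to_numpy()
        assert abs(x[g1].mean() - x[~g1].mean()) < 1.0

    def test_hub_mode_shares_one_lncrna_over_three_triplets(self):
        co = simulate_cohort(hub_experiment_config(seed=0))
        lncs = [l for l, _, _ in co.truth.planted_triplets]
        counts = {l: lncs.count(l) for l in set(lncs)}
        assert counts["LNC0000"] == 3 * co.config.mirnas_per_triplet
        assert sum(1 for v in counts.values() if v > co.config.mirnas_per_triplet) == 1


class TestStemnessGenerator:
    def test_shapes_and_gradient_alignment(self):
        ref, tum, grad = simulate_stemness(seed=1)
        assert ref.shape == (200, 40)
        assert tum.shape == (200, 100)
        assert list(grad.index) == tum.sample_ids
        assert grad.between(0, 1).all()

    def test_reference_signature_positive_after_centering(self):
        ref, _, _ = simulate_stemness(seed=2)
        means = ref.data.mean(axis=1)
        assert means.iloc[:80].mean() > 0.5  # signature block elevated
        assert abs(means.iloc[80:].mean()) < 0.2
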