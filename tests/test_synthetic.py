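"""Generator contracts: determinism, calibration, inversion, recovery."""

import numpy as np
import pandas as pd
import pytest
from dataclasses import replace

from canopygrowth.errors import InversionError
from canopygrowth.inference import fit_lm
from canopygrowth.reconstruction import derive_traits
from canopygrowth.synthetic import (
    GeneratorConfig,
    generate_field_dataset,
    generate_trait_table,
    invert_to_field_measurements,
)

TABLE_TARGETS = {
    "agr": (105.43, 80.68), "height": (26.22, 3.03), "tla": (1339.73, 759.23),
    "sa": (0.172, 0.119), "sla": (105.65, 17.76), "n_leaf": (2.56, 0.43),
    "n_sapw": (0.25, 0.09), "ba": (0.331, 0.183),
    "sapwood_lifespan": (29.78, 21.77), "sapwood_growth": (101.37, 76.54),
}


class TestConfig:
    def test_species_counts(self, cfg):
        counts = [s.n_trees for s in cfg.species]
        assert sorted(counts, reverse=True) == [15, 11, 9, 8]
        assert sum(counts) == 43

    def test_growth_sa_coefficient_default(self, cfg):
        assert dict(cfg.growth_coef)["sa"] == 0.73
        assert dict(cfg.sa_coef)["sapwood_growth"] == 0.45

    def test_yaml_round_trip_lossless(self, cfg, tmp_path):
        p = tmp_path / "config.yaml"
        cfg.to_yaml(p)
        back = GeneratorConfig.from_yaml(p)
        assert back == cfg

    def test_invalid_configs_rejected(self, cfg):
        with pytest.raises(ValueError):
            replace(cfg, growth_resid_sd=-1.0)
        # a,b and b,c strongly positive but a,c strongly negative: not PSD
        bad = np.eye(8)
        bad[0, 1] = bad[1, 0] = 0.9
        bad[1, 2] = bad[2, 1] = 0.9
        bad[0, 2] = bad[2, 0] = -0.9
        with pytest.raises(ValueError, match="positive-definite"):
            replace(cfg, within_corr=tuple(map(tuple, bad)))


class TestGenerateTraitTable:
    def test_deterministic_under_seed(self, cfg):
        a, _ = generate_trait_table(cfg, seed=99)
        b, _ = generate_trait_table(cfg, seed=99)
        pd.testing.assert_frame_equal(a, b)
        c, _ = generate_trait_table(cfg, seed=100)
        assert not a["agr"].equals(c["agr"])

    def test_pooled_moments_match_calibration(self, cfg_unmasked):
        traits, truth = generate_trait_table(cfg_unmasked, seed=314,
                                             n_scale=500)
        full = truth.traits_full
        for col, (m, s) in TABLE_TARGETS.items():
            assert full[col].mean() == pytest.approx(m, rel=0.05), col
            assert full[col].std(ddof=1) == pytest.approx(s, rel=0.20), col

    def test_masking_hides_sapwood_of_unobservable_species(self, cfg):
        masked, truth = generate_trait_table(cfg, seed=6)
        hide = masked["species"].str.contains("Cariniana")
        assert masked.loc[hide, "sa"].isna().all()
        assert masked.loc[hide, "sapwood_lifespan"].isna().all()
        assert truth.traits_full.loc[hide.to_numpy(), "sa"].notna().all()

    def test_sa_never_exceeds_ba(self, traits430):
        _, truth = traits430
        f = truth.traits_full
        assert (f["sa"] <= f["ba"]).all()

    def test_structural_model_holds_in_large_sample(self, cfg_unmasked):
        """Regressing the generated response on the reference z-scores
        returns the configured ground-truth coefficients."""
        _, truth = generate_trait_table(cfg_unmasked, seed=11, n_scale=500)
        f = truth.traits_full
        smap = dict(cfg_unmasked.scales)
        z_sa = (np.log(f["sa"]) - smap["sa"].loc) / smap["sa"].scale
        X = pd.DataFrame({
            "g": smap["sapwood_growth"].natural_z(f["sapwood_growth"]),
            "l": smap["sapwood_lifespan"].natural_z(f["sapwood_lifespan"]),
            "ba": (np.log(f["ba"]) - smap["ba"].loc) / smap["ba"].scale,
        })
        for sp in f["species"].unique()[:-1]:
            X[sp] = (f["species"] == sp).astype(float)
        fit = fit_lm(X, z_sa)
        truth_coefs = dict(cfg_unmasked.sa_coef)
        assert fit.params["g"] == pytest.approx(truth_coefs["sapwood_growth"],
                                                abs=0.01)
        assert fit.params["l"] == pytest.approx(
            truth_coefs["sapwood_lifespan"], abs=0.01)
        assert fit.params["ba"] == pytest.approx(truth_coefs["ba"], abs=0.015)


class TestInversion:
    def _row(self, **kw):
        base = dict(tree_id="T1", species="Hura crepitans", agr=105.0,
                    height=26.0, tla=1300.0, sa=0.17, sla=105.0, n_leaf=2.5,
                    n_sapw=0.25, ba=0.33, sapwood_lifespan=30.0,
                    sapwood_growth=100.0, sa_imputed=False)
        base.update(kw)
        return pd.Series(base)

    def test_degenerate_zero_growth(self, cfg):
        tree = invert_to_field_measurements(
            self._row(agr=0.0, sapwood_growth=0.0), cfg, seed=1)
        for d in tree.discs:
            assert np.all(d.ring_widths_5yr_cm == 0.0)

    def test_sa_above_ba_rejected(self, cfg):
        with pytest.raises(InversionError, match="exceeds"):
            invert_to_field_measurements(self._row(sa=0.4, ba=0.33), cfg, 1)

    def test_unattainable_growth_combination_rejected(self, cfg):
        with pytest.raises(InversionError):
            invert_to_field_measurements(
                self._row(agr=360.0, sapwood_growth=13.0, height=22.0), cfg, 1)

    def test_positive_growth_with_zero_ring_growth_rejected(self, cfg):
        with pytest.raises(InversionError):
            invert_to_field_measurements(
                self._row(sapwood_growth=0.0), cfg, 1)

    def test_round_trip_on_single_record(self, cfg):
        row = self._row()
        tree = invert_to_field_measurements(row, cfg, seed=3)
        derived, _ = derive_traits([tree])
        got = derived.iloc[0]
        for col in ["agr", "ba", "sa", "tla", "sla", "sapwood_growth",
                    "sapwood_lifespan"]:
            assert got[col] == pytest.approx(row[col], rel=1e-9), col


class TestFieldDataset:
    def test_derivation_reproduces_ground_truth(self, cfg_unmasked):
        trees, traits, _ = generate_field_dataset(cfg_unmasked, seed=21,
                                                  n_scale=3)
        derived, _ = derive_traits(trees)
        m = traits.set_index("tree_id")
        d = derived.set_index("tree_id")
        for col in ["agr", "ba", "sa", "tla", "sla", "sapwood_growth",
                    "sapwood_lifespan"]:
            rel = ((m[col] - d[col]).abs() / m[col].abs()).dropna()
            assert (rel < 1e-6).all(), col

    def test_deterministic(self, cfg):
        t1, tr1, _ = generate_field_dataset(cfg, seed=8)
        t2, tr2, _ = generate_field_dataset(cfg, seed=8)
        pd.testing.assert_frame_equal(tr1, tr2)
        assert t1[0].discs[0].radii_cm == t2[0].discs[0].radii_cm

    def test_full_pipeline_recovers_growth_coefficients(self, cfg_unmasked):
        """generate -> invert -> derive -> fit recovers the ground-truth
        standardized growth coefficients (sampled replicates)."""
        from canopygrowth.inference import (GROWTH_DESIGN, average_models,
                                            enumerate_subsets,
                                            transform_and_scale)
        ests = []
        for s in range(8):
            trees, _, _ = generate_field_dataset(cfg_unmasked, seed=900 + s,
                                                 n_scale=10)
            derived, _ = derive_traits(trees)
            dm = transform_and_scale(derived, GROWTH_DESIGN)
            avg = average_models(enumerate_subsets(dm))
            ests.append(avg.coefficients["log(sa)"])
        mean = np.mean(ests)
        mc_se = np.std(ests, ddof=1) / np.sqrt(len(ests))
        truth = dict(cfg_unmasked.growth_coef)["sa"]
        assert abs(mean - truth) < max(2 * mc_se, 0.02)
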