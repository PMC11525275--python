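"""Generator: atlas invariants, closed-form loadings, calibration, connectomes."""

import numpy as np
import pandas as pd
import pytest

from wmhnet import synth
from wmhnet.synth import CalibrationError, SimConfig


class TestAtlas:
    def test_structure_and_counts(self, atlas):
        assert len(atlas) == 246
        assert (atlas["lobe"] == "Subcortical").sum() == 36
        assert ((atlas["network"] == "SUB") == (atlas["lobe"] == "Subcortical")).all()
        counts = atlas["lobe"].value_counts()
        assert counts["Frontal"] == 70 and counts["Occipital"] == 36
        # seven cortical networks get 30 nodes each
        cortical = atlas[atlas["network"] != "SUB"]
        assert set(cortical["network"].value_counts()) == {30}

    def test_deterministic_given_seed(self):
        pd.testing.assert_frame_equal(synth.make_atlas(3), synth.make_atlas(3))

    def test_volume_varies_with_seed(self):
        a, b = synth.make_atlas(1), synth.make_atlas(2)
        assert not np.allclose(a["volume_mm3"], b["volume_mm3"])


class TestLoadings:
    def test_domain_triad_closed_form(self):
        load = synth.solve_latent_loadings(SimConfig())
        r1, r2, r3 = 0.846, 0.604, 0.557
        assert load.a_ef == pytest.approx(np.sqrt(r1 * r2 / r3), abs=1e-12)
        assert load.a_ef * load.a_ps == pytest.approx(r1, abs=1e-12)
        assert load.a_ef * load.a_mem == pytest.approx(r2, abs=1e-12)
        assert load.a_ps * load.a_mem == pytest.approx(r3, abs=1e-12)
        assert load.a_ef == pytest.approx(0.958, abs=1e-3)

    def test_decoupled_system(self):
        cfg = SimConfig(rho_age_g=1e-9, rho_g_wmh=1e-9)
        load = synth.solve_latent_loadings(cfg)
        assert load.beta == pytest.approx(0.0, abs=1e-6)
        assert load.alpha == pytest.approx(cfg.rho_age_wmh, abs=1e-6)

    def test_wmh_exposure_unit_variance(self):
        load = synth.solve_latent_loadings(SimConfig())
        r = SimConfig().rho_age_g
        var = load.alpha**2 + load.beta**2 - 2 * load.alpha * load.beta * r + load.gamma**2
        assert var == pytest.approx(1.0, abs=1e-12)

    def test_non_positive_definite_targets_rejected(self):
        with pytest.raises(CalibrationError):
            SimConfig(rho_age_g=-0.99, rho_age_wmh=0.99, rho_g_wmh=0.9)
        with pytest.raises(CalibrationError):
            SimConfig(domain_pair_corrs=(0.99, 0.99, 0.2))


LARGE = (50_000, 25_000, 25_000)


class TestPhenotypeCalibration:
    @pytest.mark.parametrize(
        "overrides",
        [
            {},
            {"rho_age_g": -0.5, "rho_age_wmh": 0.4, "rho_g_wmh": -0.3},
            {"domain_pair_corrs": (0.5, 0.4, 0.3), "rho_age_wmh": 0.2, "rho_g_wmh": -0.2},
        ],
    )
    def test_large_sample_correlations_hit_targets(self, overrides):
        cfg = SimConfig(cohort_sizes=LARGE, seed=13, **overrides)
        p = synth.simulate_phenotypes(cfg)
        lw = np.log(p["wmh_global_k07"])
        assert np.corrcoef(p["age_years"], p["latent_g"])[0, 1] == pytest.approx(
            cfg.rho_age_g, abs=0.01
        )
        assert np.corrcoef(p["age_years"], lw)[0, 1] == pytest.approx(cfg.rho_age_wmh, abs=0.01)
        assert np.corrcoef(p["latent_g"], lw)[0, 1] == pytest.approx(cfg.rho_g_wmh, abs=0.01)
        pairs = [("ef", "ps"), ("ef", "mem"), ("ps", "mem")]
        for (d1, d2), target in zip(pairs, cfg.domain_pair_corrs):
            got = np.corrcoef(p[f"latent_{d1}"], p[f"latent_{d2}"])[0, 1]
            assert got == pytest.approx(target, abs=0.01)

    def test_wmh_series_structure(self):
        cfg = SimConfig(cohort_sizes=LARGE, seed=17)
        p = synth.simulate_phenotypes(cfg)
        lw = np.log(p["wmh_global_k07"])
        assert lw.mean() == pytest.approx(6.11, abs=0.02)
        assert lw.std() == pytest.approx(1.40, abs=0.02)
        assert np.corrcoef(lw, np.log(p["wmh_pv_k07"]))[0, 1] == pytest.approx(0.99, abs=0.01)
        assert np.corrcoef(lw, np.log(p["wmh_deep_k07"]))[0, 1] == pytest.approx(0.64, abs=0.01)
        assert np.corrcoef(lw, np.log(p["wmh_global_k05"]))[0, 1] == pytest.approx(0.99, abs=0.01)
        assert (p.filter(like="wmh_") > 0).all().all()
        # vocabulary independent of age
        assert abs(np.corrcoef(p["age_years"], p["vocabulary"])[0, 1]) < 0.01

    def test_null_targets_give_null_correlations(self):
        cfg = SimConfig(
            cohort_sizes=LARGE, seed=19, rho_age_g=1e-9, rho_age_wmh=1e-9, rho_g_wmh=1e-9
        )
        p = synth.simulate_phenotypes(cfg)
        lw = np.log(p["wmh_global_k07"])
        for a, b in [("age_years", "latent_g"), ("age_years", None), ("latent_g", None)]:
            y = lw if b is None else p[b]
            assert abs(np.corrcoef(p[a], y)[0, 1]) < 0.01

    def test_cohort_age_ranges_respected(self, phenotypes, config):
        ages = phenotypes["age_years"].to_numpy()
        start = 0
        for size, (lo, hi) in zip(config.cohort_sizes, config.cohort_age_ranges):
            chunk = ages[start : start + size]
            assert chunk.min() >= lo and chunk.max() <= hi
            start += size

    def test_tiny_cohort_rejected(self):
        with pytest.raises(ValueError, match="at least 2"):
            synth.simulate_phenotypes(SimConfig(cohort_sizes=(1, 2, 2)))

    def test_deterministic_given_seed(self):
        a = synth.simulate_phenotypes(SimConfig(seed=3))
        b = synth.simulate_phenotypes(SimConfig(seed=3))
        pd.testing.assert_frame_equal(a, b)


class TestConnectomes:
    def test_invariants(self, connectomes):
        connectomes.validate()  # symmetry, zero diagonal, >= 0, threshold gap
        W = connectomes.matrices
        nz = W[W > 0]
        assert nz.min() >= 3
        assert connectomes.signal_mask.any()

    def test_mean_density_matches_target(self, connectomes, config):
        iu = np.triu_indices(246, k=1)
        dens = np.array([(W[iu] > 0).mean() for W in connectomes.matrices])
        assert dens.mean() == pytest.approx(config.base_density_target, abs=0.05)

    def test_signal_edges_track_wmh_exposure(self, connectomes, phenotypes):
        iu = np.triu_indices(246, k=1)
        E = connectomes.matrices[:, iu[0], iu[1]]
        sig = connectomes.signal_mask[iu]
        w = phenotypes["latent_w"].to_numpy()
        b = (w - w.mean()) / w.std()
        sd = E.std(axis=0)
        ok = sd > 0

        def mean_corr(mask):
            m = mask & ok
            Ec = E[:, m] - E[:, m].mean(axis=0)
            return float(((Ec * b[:, None]).mean(0) / (E[:, m].std(0) * b.std())).mean())

        assert mean_corr(sig) < -0.2
        assert mean_corr(~sig) == pytest.approx(0.0, abs=0.05)

    def test_null_decay_gives_chance_level_edge_correlations(self):
        cfg = SimConfig(seed=23, signal_edge_decay=0.0)
        p = synth.simulate_phenotypes(cfg)
        a = synth.make_atlas(23)
        cs = synth.simulate_connectomes(p, a, cfg)
        iu = np.triu_indices(246, k=1)
        E = cs.matrices[:, iu[0], iu[1]]
        b = p["latent_w"].to_numpy()
        b = (b - b.mean()) / b.std()
        ok = E.std(axis=0) > 0
        Ec = E[:, ok] - E[:, ok].mean(axis=0)
        r = (Ec * b[:, None]).mean(0) / (E[:, ok].std(0) * b.std())
        n = len(p)
        crit = 1.96 / np.sqrt(n - 3)  # Fisher-z two-sided 5% critical value
        assert 0.03 < (np.abs(np.arctanh(r)) > crit).mean() < 0.07

    def test_deterministic_given_seed(self, config, phenotypes, atlas):
        a = synth.simulate_connectomes(phenotypes, atlas, config)
        b = synth.simulate_connectomes(phenotypes, atlas, config)
        assert np.array_equal(a.matrices, b.matrices)
        assert np.array_equal(a.signal_mask, b.signal_mask)

    def test_requires_generator_phenotypes(self, atlas, config, phenotypes):
        with pytest.raises(KeyError, match="latent_w"):
            synth.simulate_connectomes(phenotypes.drop(columns=["latent_w"]), atlas, config)


class TestStreamlineThreshold:
    def test_cells_below_three_zeroed(self):
        M = np.array([[0.0, 2.0, 3.0], [2.0, 0.0, 5.0], [3.0, 5.0, 0.0]])
        out = synth.apply_streamline_threshold(M)
        assert out[0, 1] == 0.0 and out[0, 2] == 3.0 and out[1, 2] == 5.0
        assert np.array_equal(out, out.T)

    def test_identity_on_zeros(self):
        Z = np.zeros((4, 4))
        assert np.array_equal(synth.apply_streamline_threshold(Z), Z)

    def test_non_square_rejected(self):
        with pytest.raises(ValueError, match="square"):
            synth.apply_streamline_threshold(np.zeros((3, 4)))
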