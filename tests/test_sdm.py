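"""TSS, thresholding, ensemble fitting, importance and projection."""

import warnings

import numpy as np
import pandas as pd
import pytest

import alpscape as alp
from alpscape import landuse as lu
from alpscape.sdm import (
    SDMFit,
    _prob_of,
    build_region_predictors,
    design_matrix,
    ensemble_predict,
    fit_species_models,
    max_tss_threshold,
    permutation_importance,
    project_region,
    tss,
)
from alpscape.synthetic import truth_map


class TestTSS:
    def test_perfect_prediction_scores_one(self):
        obs = np.array([0, 1, 0, 1, 1])
        assert tss(obs, obs) == pytest.approx(1.0)

    def test_constant_prediction_scores_zero(self):
        obs = np.array([0, 1, 0, 1])
        assert tss(obs, np.ones(4)) == pytest.approx(0.0)
        assert tss(obs, np.zeros(4)) == pytest.approx(0.0)

    def test_hand_confusion_table(self):
        # sensitivity 0.9 (90/100 presences hit), specificity 0.8 -> 0.7
        obs = np.r_[np.ones(100), np.zeros(100)]
        pred = np.r_[np.ones(90), np.zeros(10), np.zeros(80), np.ones(20)]
        assert tss(obs, pred) == pytest.approx(0.7)

    def test_single_class_observed_rejected(self):
        with pytest.raises(ValueError):
            tss(np.ones(5), np.ones(5))


class TestMaxTSSThreshold:
    def _brute(self, obs, probs):
        best_t, best_s = None, -np.inf
        for t in np.unique(probs):
            s = tss(obs, probs >= t)
            if s > best_s + 1e-12:
                best_t, best_s = t, s
        return best_t, best_s

    def test_matches_exhaustive_search(self, rng):
        for _ in range(50):
            n = int(rng.integers(10, 80))
            obs = rng.integers(0, 2, n)
            if obs.all() or not obs.any():
                continue
            probs = rng.random(n).round(2)  # duplicated values exercise ties
            t, s = max_tss_threshold(obs, probs)
            bt, bs = self._brute(obs, probs)
            assert s == pytest.approx(bs, abs=1e-12)
            assert t == pytest.approx(bt, abs=1e-12)

    def test_separated_probabilities(self):
        obs = np.array([0, 0, 1, 1])
        probs = np.array([0.1, 0.2, 0.8, 0.9])
        t, s = max_tss_threshold(obs, probs)
        assert s == pytest.approx(1.0)
        assert t == pytest.approx(0.8)  # smallest achieving threshold

    def test_monotone_transform_preserves_partition(self, rng):
        obs = rng.integers(0, 2, 50)
        obs[:2] = [0, 1]
        probs = rng.random(50)
        t1, s1 = max_tss_threshold(obs, probs)
        t2, s2 = max_tss_threshold(obs, probs**3)
        assert s1 == pytest.approx(s2)
        assert np.array_equal(probs >= t1, probs**3 >= t2)


class TestEnsemble:
    def _fit_with(self, weights, probs_by_model):
        class Stub:
            def __init__(self, p):
                self.p = np.asarray(p)
                self.classes_ = np.array([0, 1])

            def predict_proba(self, X):
                return np.column_stack([1 - self.p, self.p])

        return SDMFit(
            species_id="stub",
            models={m: Stub(p) for m, p in probs_by_model.items()},
            split_tss={m: [1.0] for m in probs_by_model},
            mean_tss={m: 1.0 for m in probs_by_model},
            weights=weights,
            threshold=0.5,
            ensemble_tss=1.0,
        )

    def _frame(self, n):
        return pd.DataFrame(
            {"landuse": [1] * n, "bio6": 0.0, "bio7": 0.0, "bio15": 0.0,
             "bio18": 0.0, "substrate": 0, "solar": 0.0}
        )

    def test_single_model_passthrough(self):
        fit = self._fit_with({"RF": 1.0}, {"RF": [0.2, 0.7]})
        assert np.allclose(ensemble_predict(fit, self._frame(2)), [0.2, 0.7])

    def test_equal_weights_average(self):
        fit = self._fit_with({"RF": 0.5, "GBM": 0.5}, {"RF": [0.2], "GBM": [0.8]})
        assert np.allclose(ensemble_predict(fit, self._frame(1)), [0.5])

    def test_exclusion_equals_zero_weight(self):
        kept = self._fit_with({"RF": 1.0}, {"RF": [0.3, 0.6]})
        both = self._fit_with({"RF": 1.0, "GBM": 0.0}, {"RF": [0.3, 0.6], "GBM": [0.9, 0.9]})
        assert np.allclose(
            ensemble_predict(kept, self._frame(2)), ensemble_predict(both, self._frame(2))
        )

    def test_no_models_rejected(self):
        fit = self._fit_with({}, {})
        with pytest.raises(ValueError):
            ensemble_predict(fit, self._frame(1))


class TestFitting:
    def test_probabilities_are_bounded(self, sdm_fits, plots):
        for fit in sdm_fits:
            p = ensemble_predict(fit, plots.predictors())
            assert (p >= 0).all() and (p <= 1).all()
            assert sum(fit.weights.values()) == pytest.approx(1.0)
            assert 0.0 < fit.threshold < 1.0

    def test_well_constructed_species_reach_tss_07(self, sdm_fits, plots):
        """Every retained ensemble clears the 0.5 skill cutoff comfortably;
        well-sampled species (>= 100 occurrences) reach evaluation TSS 0.7."""
        occ = plots.occurrences()
        assert all(f.ensemble_tss >= 0.55 for f in sdm_fits)
        well = [f for f in sdm_fits if occ[f.species_id] >= 100]
        assert well and all(f.ensemble_tss >= 0.7 for f in well)

    def test_sparse_species_rejected_by_filter(self, plots):
        sparse = plots.excluded[0] if plots.excluded else None
        if sparse is None:
            pytest.skip("fixture has no excluded species")
        with pytest.raises(ValueError):
            fit_species_models(plots, sparse, seed=0)

    def test_label_noise_species_retains_no_model(self, plots):
        """Shuffled labels carry no signal; every algorithm stays below the
        TSS cutoff and the species is flagged unusable."""
        rng = np.random.default_rng(4)
        sp = plots.usable_species()[0]
        noisy = plots.data.copy()
        noisy[sp] = rng.permutation(noisy[sp].to_numpy())
        shuffled = alp.PlotTable(
            data=noisy, species_ids=plots.species_ids,
            min_occurrences=plots.min_occurrences, excluded=plots.excluded,
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = fit_species_models(shuffled, sp, seed=0)
        assert not fit.usable
        assert fit.weights == {}


class TestImportance:
    def test_informative_predictor_outranks_ignored_one(self, plots, rng):
        """A purely climate-limited virtual species: permuting BIO6 destroys
        the predictions, permuting solar radiation does not."""
        data = plots.data.copy()
        p = 1.0 / (1.0 + np.exp((data["bio6"].to_numpy() + 8.0) / 0.5))
        data["onevar"] = (np.random.default_rng(0).random(len(data)) < p).astype(int)
        table = alp.PlotTable(
            data=data, species_ids=plots.species_ids + ["onevar"],
            min_occurrences=plots.min_occurrences, excluded=plots.excluded,
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = fit_species_models(table, "onevar", seed=0)
        imp_bio6 = permutation_importance(fit, table, "bio6", rng, n_perm=3)
        imp_solar = permutation_importance(fit, table, "solar", rng, n_perm=3)
        assert imp_bio6 > 0.5
        assert imp_solar < 0.15

    def test_unknown_predictor_rejected(self, sdm_fits, plots, rng):
        with pytest.raises(ValueError):
            permutation_importance(sdm_fits[0], plots, "elevation", rng)


class TestProjection:
    def test_broadcast_contract_within_coarse_cells(self, sdm_fits, landscape, climate):
        """Two 25 m cells sharing a 100 m parent and land-use class must get
        identical predictions."""
        fit = sdm_fits[0]
        suit = project_region(fit, landscape, climate, landscape.landuse).binary
        codes = landscape.landuse
        # within the first coarse block, compare equal-class cells
        block = codes[:4, :4]
        vals = suit[:4, :4]
        for c in np.unique(block):
            assert len(np.unique(vals[block == c])) == 1

    def test_unknown_class_code_rejected(self, sdm_fits, landscape, climate):
        bad = landscape.landuse.copy()
        bad[0, 0] = 44
        with pytest.raises(ValueError):
            build_region_predictors(landscape, climate, bad)

    def test_affinity_restricted_species_stays_in_its_classes(
        self, species_pool, landscape, climate, plots
    ):
        """A planted specialist's truth range lies inside its habitat group."""
        for niche in species_pool:
            if niche.planted_group is None:
                continue
            t = truth_map(niche, landscape, climate).astype(bool)
            group_cells = np.isin(
                landscape.landuse,
                [c for c in lu.ALL_CODES if lu.HABITAT_GROUP_LOOKUP[c] == niche.planted_group],
            )
            spill = t & ~group_cells
            assert spill.sum() <= 0.15 * max(t.sum(), 1)

    def test_well_sampled_species_recover_truth_maps(
        self, sdm_fits, species_pool, landscape, climate, plots
    ):
        """Widespread virtual species: projected current range overlaps the
        generator's truth map at Jaccard >= 0.8 (small-ranged species
        over-predict at low max-TSS thresholds and are excluded here)."""
        occ = plots.occurrences()
        niches = {n.species_id: n for n in species_pool}
        checked = 0
        for fit in sdm_fits:
            if occ[fit.species_id] < 0.15 * plots.n_plots:
                continue
            proj = project_region(fit, landscape, climate, landscape.landuse).binary.astype(bool)
            t = truth_map(niches[fit.species_id], landscape, climate).astype(bool)
            union = (proj | t).sum()
            jac = (proj & t).sum() / union if union else 1.0
            assert jac >= 0.8, fit.species_id
            checked += 1
        assert checked >= 1
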