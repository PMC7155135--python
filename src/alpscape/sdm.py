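"""Ensemble species distribution models.

Per species, three classifiers — random forest (RF), a single-hidden-layer
artificial neural network (ANN) and a gradient boosting machine (GBM) — are
fitted to presence/absence at vegetation plots with seven predictors: land
use (22 categories, one-hot encoded), four bioclimatic variables (BIO6,
BIO7, BIO15, BIO18), calcareous-substrate presence and solar radiation.
Models are evaluated by the true skill statistic (TSS) on three stratified
80/20 splits; models with mean TSS below 0.5 are excluded, the remainder
are refitted on all data and combined into a TSS-weighted ensemble whose
probabilities are binarized at the threshold maximizing TSS.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from sklearn.ensemble import GradientBoostingClassifier, RandomForestClassifier
from sklearn.model_selection import StratifiedShuffleSplit
from sklearn.neural_network import MLPClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler

from . import landuse as lu
from .climate import BIO_VARS, ClimateGrids
from .rasters import parent_coarse_index
from .synthetic import Landscape, PlotTable, PREDICTOR_COLUMNS

logger = logging.getLogger(__name__)

MODEL_NAMES = ("RF", "ANN", "GBM")
NUMERIC_PREDICTORS = ("bio6", "bio7", "bio15", "bio18", "substrate", "solar")

#: fixed, seedable hyperparameters standing in for the reference defaults
HYPERPARAMS = {
    "RF": {"n_estimators": 200, "min_samples_leaf": 2, "n_jobs": 1},
    "ANN": {"hidden_layer_sizes": (10,), "max_iter": 400, "alpha": 1e-3},
    "GBM": {"n_estimators": 100, "learning_rate": 0.1, "max_depth": 3},
}


def design_matrix(df: pd.DataFrame) -> np.ndarray:
    """Numeric design matrix: one-hot land use (22 fixed levels) + numerics."""
    codes = df["landuse"].to_numpy(int)
    onehot = np.zeros((len(df), lu.N_CLASSES))
    onehot[np.arange(len(df)), codes - 1] = 1.0
    numeric = df[list(NUMERIC_PREDICTORS)].to_numpy(float)
    return np.column_stack([onehot, numeric])


def make_models(seed: int):
    """Fresh unfitted RF/ANN/GBM instances with fixed hyperparameters."""
    return {
        "RF": RandomForestClassifier(random_state=seed, **HYPERPARAMS["RF"]),
        "ANN": Pipeline(
            [
                ("scale", StandardScaler()),
                ("mlp", MLPClassifier(random_state=seed, **HYPERPARAMS["ANN"])),
            ]
        ),
        "GBM": GradientBoostingClassifier(random_state=seed, **HYPERPARAMS["GBM"]),
    }


def tss(observed: np.ndarray, predicted: np.ndarray) -> float:
    """True skill statistic = sensitivity + specificity - 1."""
    obs = np.asarray(observed).astype(bool)
    pred = np.asarray(predicted).astype(bool)
    if obs.all() or not obs.any():
        raise ValueError("TSS undefined: observed vector has a single class")
    sens = (pred & obs).sum() / obs.sum()
    spec = (~pred & ~obs).sum() / (~obs).sum()
    return float(sens + spec - 1.0)


def max_tss_threshold(observed: np.ndarray, probabilities: np.ndarray) -> Tuple[float, float]:
    """Threshold (from the unique predicted probabilities) maximizing the TSS
    of ``prob >= t``; ties resolve to the smallest such threshold. Returns
    ``(threshold, tss_at_threshold)``."""
    obs = np.asarray(observed).astype(bool)
    if obs.all() or not obs.any():
        raise ValueError("threshold undefined: observed vector has a single class")
    probs = np.asarray(probabilities, float)
    cand = np.unique(probs)
    # descending threshold sweep via cumulative sums on sorted probabilities
    order = np.argsort(-probs, kind="stable")
    obs_sorted = obs[order]
    probs_sorted = probs[order]
    tp = np.cumsum(obs_sorted)
    fp = np.cumsum(~obs_sorted)
    n_pos, n_neg = obs.sum(), (~obs).sum()
    # last index where probs_sorted >= t for each candidate t
    idx = np.searchsorted(-probs_sorted, -cand, side="right") - 1
    sens = tp[idx] / n_pos
    spec = 1.0 - fp[idx] / n_neg
    scores = sens + spec - 1.0
    best = scores.max()
    t = float(cand[scores >= best - 1e-12].min())
    return t, float(best)


def _prob_of(model, X: np.ndarray) -> np.ndarray:
    proba = model.predict_proba(X)
    classes = list(model.classes_)
    if 1 not in classes:
        return np.zeros(len(X))
    return proba[:, classes.index(1)]


@dataclass
class SDMFit:
    species_id: str
    models: Dict[str, object]  # retained, refitted on all data
    split_tss: Dict[str, List[float]]  # per model, per split (all 3 models)
    mean_tss: Dict[str, float]
    weights: Dict[str, float]  # retained models only, sum to 1
    threshold: float
    ensemble_tss: float  # mean TSS of the weighted ensemble on the held-out splits
    importance: Dict[str, Dict[str, float]] = field(default_factory=dict)
    dropped_columns: List[str] = field(default_factory=list)

    @property
    def usable(self) -> bool:
        return len(self.models) > 0


def fit_species_models(
    plots: PlotTable,
    species_id: str,
    seed: int = 0,
    n_splits: int = 3,
    test_fraction: float = 0.2,
    tss_cutoff: float = 0.5,
) -> SDMFit:
    """Fit, evaluate and ensemble the three algorithms for one species.

    Evaluation: per algorithm, TSS at the max-TSS threshold on each of three
    stratified 80/20 splits, averaged. Algorithms under the cutoff are
    dropped; survivors are refitted on all plots and weighted by mean TSS.
    Species below the occurrence filter are rejected up front; a species
    retaining no model is returned flagged unusable.
    """
    y = plots.presence(species_id)
    if y.sum() < plots.min_occurrences:
        raise ValueError(
            f"{species_id}: {int(y.sum())} occurrences < filter of {plots.min_occurrences}"
        )
    df = plots.predictors()
    X = design_matrix(df)
    const = X.std(axis=0) == 0.0
    dropped: List[str] = []
    if const.any():
        names = [f"landuse_{c}" for c in lu.ALL_CODES] + list(NUMERIC_PREDICTORS)
        dropped = [names[i] for i in np.flatnonzero(const)]
        logger.warning("%s: dropping constant predictor columns %s", species_id, dropped)
        X = X[:, ~const]

    splitter = StratifiedShuffleSplit(
        n_splits=n_splits, test_size=test_fraction, random_state=seed
    )
    split_tss: Dict[str, List[float]] = {m: [] for m in MODEL_NAMES}
    heldout: List[Tuple[np.ndarray, Dict[str, np.ndarray]]] = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for k, (tr, te) in enumerate(splitter.split(X, y)):
            models = make_models(seed + 1000 * k)
            probs_te: Dict[str, np.ndarray] = {}
            for name, model in models.items():
                model.fit(X[tr], y[tr])
                probs = _prob_of(model, X[te])
                probs_te[name] = probs
                try:
                    _, score = max_tss_threshold(y[te], probs)
                except ValueError:
                    score = 0.0
                split_tss[name].append(score)
            heldout.append((y[te], probs_te))
        mean_tss = {m: float(np.mean(split_tss[m])) for m in MODEL_NAMES}
        retained = {m: s for m, s in mean_tss.items() if s >= tss_cutoff}
        final_models: Dict[str, object] = {}
        if retained:
            models = make_models(seed)
            for name in retained:
                models[name].fit(X, y)
                final_models[name] = models[name]
    if not retained:
        logger.warning("%s: no model reached TSS %.2f; species unusable", species_id, tss_cutoff)
        return SDMFit(
            species_id=species_id,
            models={},
            split_tss=split_tss,
            mean_tss=mean_tss,
            weights={},
            threshold=0.5,
            ensemble_tss=float("nan"),
            dropped_columns=dropped,
        )
    wsum = sum(retained.values())
    weights = {m: s / wsum for m, s in retained.items()}
    # evaluation TSS of the weighted ensemble: per held-out split, at that
    # split's max-TSS threshold, averaged over the three splits
    eval_scores = []
    for y_te, probs_te in heldout:
        ens_te = sum(weights[m] * probs_te[m] for m in weights)
        try:
            _, sc = max_tss_threshold(y_te, ens_te)
        except ValueError:
            sc = 0.0
        eval_scores.append(sc)
    fit = SDMFit(
        species_id=species_id,
        models=final_models,
        split_tss=split_tss,
        mean_tss=mean_tss,
        weights=weights,
        threshold=0.5,
        ensemble_tss=0.0,
        dropped_columns=dropped,
    )
    fit._column_mask = ~const  # type: ignore[attr-defined]
    fit.ensemble_tss = float(np.mean(eval_scores))
    ens = ensemble_predict(fit, df)
    fit.threshold, _ = max_tss_threshold(y, ens)
    return fit


def _design_for_fit(fit: SDMFit, df: pd.DataFrame) -> np.ndarray:
    X = design_matrix(df)
    mask = getattr(fit, "_column_mask", None)
    return X[:, mask] if mask is not None else X


def ensemble_predict(fit: SDMFit, df: pd.DataFrame) -> np.ndarray:
    """TSS-weighted mean of the retained models' probabilities."""
    if not fit.models:
        raise ValueError(f"{fit.species_id}: no retained model")
    X = _design_for_fit(fit, df)
    out = np.zeros(len(df))
    for name, model in fit.models.items():
        out += fit.weights[name] * _prob_of(model, X)
    return out


def permutation_importance(
    fit: SDMFit,
    plots: PlotTable,
    predictor: str,
    rng: np.random.Generator,
    n_perm: int = 3,
    model_name: Optional[str] = None,
) -> float:
    """1 - Pearson r between predictions on the original table and on the
    table with one predictor permuted, averaged over permutations, in [0,1].

    Land use is permuted as a single categorical column (the whole one-hot
    block moves together), so its importance is scored as one predictor.
    """
    if predictor not in PREDICTOR_COLUMNS:
        raise ValueError(f"unknown predictor {predictor!r}")
    df = plots.predictors()

    def predict(frame: pd.DataFrame) -> np.ndarray:
        if model_name is None:
            return ensemble_predict(fit, frame)
        X = _design_for_fit(fit, frame)
        return _prob_of(fit.models[model_name], X)

    base = predict(df)
    if base.std() == 0.0:
        return 0.0
    scores = []
    for _ in range(n_perm):
        perm = df.copy()
        perm[predictor] = rng.permutation(perm[predictor].to_numpy())
        shuffled = predict(perm)
        if shuffled.std() == 0.0:
            scores.append(1.0)
            continue
        r = np.corrcoef(base, shuffled)[0, 1]
        scores.append(1.0 - r)
    return float(np.clip(np.mean(scores), 0.0, 1.0))


def importance_table(
    fits: Sequence[SDMFit], plots: PlotTable, seed: int = 0, n_perm: int = 3
) -> pd.DataFrame:
    """Ensemble permutation importance of every predictor for every species."""
    import zlib

    rows = []
    for fit in fits:
        if not fit.usable:
            continue
        sub = zlib.crc32(fit.species_id.encode()) & 0x7FFFFFFF
        rng = np.random.default_rng(np.random.SeedSequence([seed, sub]))
        for pred in PREDICTOR_COLUMNS:
            rows.append(
                {
                    "species": fit.species_id,
                    "predictor": pred,
                    "importance": permutation_importance(fit, plots, pred, rng, n_perm),
                }
            )
    return pd.DataFrame(rows)


@dataclass
class SuitabilityMap:
    species_id: str
    climate_scenario: str
    landuse_scenario: str
    run: int
    binary: np.ndarray  # (rows, cols) of {0, 1} at 25 m


def build_region_predictors(
    landscape: Landscape, climate: ClimateGrids, landuse_map: np.ndarray
) -> pd.DataFrame:
    """Predictor table for every 25 m cell: land use at native grain, climate
    / substrate / solar broadcast as constants within their 100 m parent."""
    geom = landscape.geom
    if landuse_map.shape != geom.fine_shape:
        raise ValueError("land-use map does not match the landscape geometry")
    codes = np.asarray(landuse_map).ravel().astype(int)
    if codes.min() < 1 or codes.max() > lu.N_CLASSES:
        raise ValueError("unknown land-use class code in map")
    parent = parent_coarse_index(geom).ravel()
    bio = climate.bio()
    return pd.DataFrame(
        {
            "landuse": codes,
            "bio6": bio["bio6"].ravel()[parent],
            "bio7": bio["bio7"].ravel()[parent],
            "bio15": bio["bio15"].ravel()[parent],
            "bio18": bio["bio18"].ravel()[parent],
            "substrate": landscape.substrate.ravel()[parent].astype(int),
            "solar": landscape.solar.ravel()[parent],
        }
    )


def project_region(
    fit: SDMFit,
    landscape: Landscape,
    climate: ClimateGrids,
    landuse_map: np.ndarray,
    predictors: Optional[pd.DataFrame] = None,
    climate_scenario: str = "current",
    landuse_scenario: str = "current",
    run: int = 0,
) -> SuitabilityMap:
    """Binary suitability over the region at the fit's max-TSS threshold."""
    df = predictors if predictors is not None else build_region_predictors(
        landscape, climate, landuse_map
    )
    probs = ensemble_predict(fit, df)
    binary = (probs >= fit.threshold).astype(np.int8).reshape(landscape.geom.fine_shape)
    return SuitabilityMap(
        species_id=fit.species_id,
        climate_scenario=climate_scenario,
        landuse_scenario=landuse_scenario,
        run=run,
        binary=binary,
    )


def evaluation_table(fits: Sequence[SDMFit]) -> pd.DataFrame:
    rows = []
    for fit in fits:
        for m in MODEL_NAMES:
            for split, score in enumerate(fit.split_tss[m]):
                rows.append(
                    {
                        "species": fit.species_id,
                        "model": m,
                        "split": split,
                        "tss": score,
                        "mean_tss": fit.mean_tss[m],
                        "retained": m in fit.models,
                        "weight": fit.weights.get(m, 0.0),
                        "threshold": fit.threshold,
                        "ensemble_tss": fit.ensemble_tss,
                    }
                )
    return pd.DataFrame(rows)
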