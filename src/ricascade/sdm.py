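"""Species distribution modelling from presences and pseudo-absences.

A binomial GLM (logit link, linear terms only, no interactions) is fitted to
presence points against background pseudo-absence points sampled outside a
buffer around the known distribution, evaluated on a stratified held-out
split with AUC and the maximum true skill statistic (TSS), and projected
back onto the environmental grid as a probability surface.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree
from scipy.special import expit
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import train_test_split

from .grid import EnvGrid, OccurrenceSet, SuitabilitySurface


class SamplingError(RuntimeError):
    """Raised when pseudo-absence sampling cannot satisfy the request."""


class EvaluationError(ValueError):
    """Raised when a score set cannot be evaluated (e.g. one class only)."""


class FitError(RuntimeError):
    """Raised when the SDM cannot be fitted."""


@dataclass
class SDMFit:
    """A fitted per-species logistic SDM with held-out skill metrics.

    Coefficients are on the logit scale of the original (unstandardized)
    predictors, one slope per layer plus the intercept.
    """

    species: str
    intercept: float
    coefficients: dict[str, float]
    predictor_names: list[str] = field(default_factory=list)
    train_fraction: float = 0.7
    auc: float = float("nan")
    tss: float = float("nan")
    tss_threshold: float = float("nan")
    rng_seed: int = 0

    def linear_predictor(self, X: np.ndarray) -> np.ndarray:
        beta = np.array([self.coefficients[p] for p in self.predictor_names])
        return self.intercept + X @ beta


def _env_matrix(env: EnvGrid, points: np.ndarray, predictors: list[str]) -> np.ndarray:
    """Layer values at each point's containing cell, columns ordered as `predictors`."""
    rows_cols = [env.cell_of(lon, lat) for lon, lat in points]
    r = np.array([rc[0] for rc in rows_cols])
    c = np.array([rc[1] for rc in rows_cols])
    return np.column_stack([env.layers[p][r, c] for p in predictors])


def generate_pseudo_absences(
    presences: OccurrenceSet,
    env: EnvGrid,
    buffer_deg: float = 0.05,
    ratio: int = 4,
    rng_seed: int = 0,
) -> OccurrenceSet:
    """Sample background pseudo-absence points outside a buffer.

    Candidate cells are the valid cells whose center lies strictly farther
    than ``buffer_deg`` (planar degrees) from every presence point; ``ratio``
    times the number of presences are drawn uniformly without replacement and
    jittered within their cells (jitter kept small enough not to violate the
    buffer).
    """
    if len(presences) == 0:
        raise SamplingError("need at least one presence point")
    if buffer_deg < 0:
        raise ValueError("buffer_deg must be >= 0")
    n_abs = ratio * len(presences)
    lons, lats = env.cell_centers()
    centers = np.column_stack([lons[env.mask], lats[env.mask]])
    tree = cKDTree(presences.points)
    dist, _ = tree.query(centers, k=1)
    occupied = np.zeros(env.shape, dtype=bool)
    for lon, lat in presences.points:
        occupied[env.cell_of(lon, lat)] = True
    eligible = (dist > buffer_deg) & ~occupied[env.mask]
    n_eligible = int(eligible.sum())
    if n_eligible < n_abs:
        raise SamplingError(
            f"only {n_eligible} cells beyond the {buffer_deg} deg buffer; "
            f"{n_abs} pseudo-absences requested ({n_abs - n_eligible} short)"
        )
    rng = np.random.default_rng(rng_seed)
    pick = rng.choice(np.flatnonzero(eligible), size=n_abs, replace=False)
    chosen = centers[pick]
    # jitter within the cell, but never past the buffer boundary
    margin = np.minimum(env.resolution / 2.0, np.maximum(dist[pick] - buffer_deg, 0.0))
    jitter = rng.uniform(-1.0, 1.0, size=(n_abs, 2)) * (margin[:, None] / np.sqrt(2.0))
    return OccurrenceSet(
        species=presences.species, points=chosen + jitter, role="pseudo_absence"
    )


def evaluate_auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """Rank-based AUC: probability a random presence outscores a random
    absence, ties counting one half (Mann–Whitney convention)."""
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise EvaluationError("AUC needs both presence and absence labels")
    return float(roc_auc_score(labels, np.asarray(scores, dtype=float)))


def evaluate_tss(scores: np.ndarray, labels: np.ndarray) -> tuple[float, float]:
    """Maximum TSS = sensitivity + specificity - 1 over candidate thresholds.

    Candidates are midpoints of consecutive sorted unique scores; points
    scoring strictly above the threshold are predicted present.  Returns
    (max TSS, smallest maximizing threshold).
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise EvaluationError("TSS needs both presence and absence labels")
    uniq = np.unique(scores)
    if uniq.size < 2:
        return 0.0, float(uniq[0])
    cands = (uniq[:-1] + uniq[1:]) / 2.0
    pos = labels == 1
    n_pos, n_neg = pos.sum(), (~pos).sum()
    best_tss, best_t = -np.inf, cands[0]
    for t in cands:
        pred = scores > t
        sens = (pred & pos).sum() / n_pos
        spec = (~pred & ~pos).sum() / n_neg
        tss = sens + spec - 1.0
        if tss > best_tss + 1e-12:
            best_tss, best_t = tss, t
    return float(best_tss), float(best_t)


def fit_sdm(
    presences: OccurrenceSet,
    absences: OccurrenceSet,
    env: EnvGrid,
    train_fraction: float = 0.7,
    rng_seed: int = 0,
    predictors: list[str] | None = None,
) -> SDMFit:
    """Fit the presence/absence logistic SDM and score it on held-out data.

    The data are split into train/test stratified by class (default 70/30);
    AUC and max-TSS are computed on the held-out fraction only.  Predictors
    are standardized internally; reported coefficients are mapped back to the
    original layer units.
    """
    if len(presences) == 0 or len(absences) == 0:
        raise FitError("both presences and absences are required")
    predictors = list(predictors) if predictors is not None else list(env.layers)
    Xp = _env_matrix(env, presences.points, predictors)
    Xa = _env_matrix(env, absences.points, predictors)
    X = np.vstack([Xp, Xa])
    y = np.concatenate([np.ones(len(Xp)), np.zeros(len(Xa))])

    X_tr, X_te, y_tr, y_te = train_test_split(
        X, y, train_size=train_fraction, stratify=y, random_state=rng_seed
    )
    if len(np.unique(y_tr)) < 2 or len(np.unique(y_te)) < 2:
        raise FitError("a class is absent from the train or test split")
    mu, sd = X_tr.mean(axis=0), X_tr.std(axis=0)
    if np.any(sd == 0):
        flat = [p for p, s in zip(predictors, sd) if s == 0]
        raise FitError(f"predictors with zero variance in training data: {flat}")

    # unpenalized logistic GLM (C=inf disables regularization)
    model = LogisticRegression(C=np.inf, max_iter=2000, solver="lbfgs")
    with warnings.catch_warnings():
        # perfect separation drives |beta| -> inf; predictions still rank correctly
        warnings.simplefilter("ignore", ConvergenceWarning)
        model.fit((X_tr - mu) / sd, y_tr)

    beta_std = model.coef_.ravel()
    beta = beta_std / sd
    intercept = float(model.intercept_[0] - np.sum(beta_std * mu / sd))

    test_scores = expit(intercept + X_te @ beta)
    auc = evaluate_auc(test_scores, y_te)
    tss, thr = evaluate_tss(test_scores, y_te)
    return SDMFit(
        species=presences.species,
        intercept=intercept,
        coefficients=dict(zip(predictors, beta)),
        predictor_names=predictors,
        train_fraction=train_fraction,
        auc=auc,
        tss=tss,
        tss_threshold=thr,
        rng_seed=rng_seed,
    )


def predict_surface(fit: SDMFit, env: EnvGrid) -> SuitabilitySurface:
    """Project a fitted SDM onto the grid: inverse-logit of the linear
    predictor at every valid cell, NaN at NODATA cells."""
    missing = [p for p in fit.predictor_names if p not in env.layers]
    if missing:
        raise KeyError(f"environment lacks predictor layers {missing}")
    lp = np.full(env.shape, fit.intercept, dtype=float)
    for p in fit.predictor_names:
        lp += fit.coefficients[p] * env.layers[p]
    values = np.where(env.mask, expit(lp), np.nan)
    return SuitabilitySurface(species=fit.species, values=values, grid=env, normalized=False)


def relative_intensity(fit: SDMFit, env: EnvGrid) -> SuitabilitySurface:
    """Relative occurrence intensity: exp of the linear predictor, rescaled to
    max 1 over valid cells.

    In a presence/background logistic fit the intercept absorbs the arbitrary
    pseudo-absence ratio, so the predicted probability is flattened relative
    to the sampling intensity that generated the presences; the exponential
    of the linear predictor is proportional to that intensity and is the
    scale on which a normalized surface consistently estimates the species'
    distribution over sites.  Use this (normalized) for niche-overlap
    computation; use :func:`predict_surface` for probability maps.
    """
    missing = [p for p in fit.predictor_names if p not in env.layers]
    if missing:
        raise KeyError(f"environment lacks predictor layers {missing}")
    lp = np.full(env.shape, fit.intercept, dtype=float)
    for p in fit.predictor_names:
        lp += fit.coefficients[p] * env.layers[p]
    lp = lp - np.nanmax(np.where(env.mask, lp, -np.inf))
    values = np.where(env.mask, np.exp(lp), np.nan)
    return SuitabilitySurface(species=fit.species, values=values, grid=env, normalized=False)
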