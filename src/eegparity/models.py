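"""P300 trial classifiers with likelihood-ratio outputs.

Three model families operate on the filtered trial tensor:

* PRK — channel-wise principal component analysis, a regularized
  discriminant (class covariances shrunk toward the pooled covariance by
  ``lambda`` and toward a scaled identity by ``gamma``), and per-class
  Gaussian kernel density estimates of the 1-D discriminant score, whose
  ratio is the trial likelihood.
* LR — L2-penalized logistic regression on standardized flattened trials
  at a fixed inverse regularization C = 0.0183.
* RLDA — xDAWN-covariance super-trials mapped to the tangent space at
  their affine-invariant Riemannian mean, classified with a shrinkage
  (Ledoit-Wolf, eigen solver) linear discriminant.

All three expose a per-trial positive likelihood ratio so that the
online decision threshold of 1.0 is the natural boundary.
"""

from __future__ import annotations

import math
import pickle
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
from scipy import linalg
from scipy.special import logsumexp
from sklearn.decomposition import PCA
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler

from .filters import TrialDataset
from .metrics import ConfusionMatrix, MetricResult, balanced_accuracy, matthews_cc

__all__ = [
    "ModelHyperparams",
    "TrainedModel",
    "fit_prk",
    "fit_logistic",
    "fit_rlda",
    "fit_model",
    "predict_likelihoods",
    "cross_validate",
    "save_model",
    "load_model",
    "airm_mean",
    "tangent_vectors",
]

MODEL_KINDS = ("PRK", "LR", "RLDA")


# ---------------------------------------------------------------------------
# Hyperparameters
# ---------------------------------------------------------------------------

@dataclass
class LrParams:
    inverse_regularization_C: float = 0.0183
    max_iter: int = 1000
    tol: float = 1e-6


@dataclass
class PrkParams:
    # retention/shrinkage defaults favor stability of the class-covariance
    # estimates at ~100 target trials; see docs/methods.md
    pca_variance_kept: float = 0.6
    rda_lambda: float = 0.9
    rda_gamma: float = 0.5
    kde_bandwidth_rule: str = "silverman"


@dataclass
class RldaParams:
    xdawn_filters_per_class: int = 2
    shrinkage: str = "auto"
    mean_type: str = "affine_invariant"


@dataclass
class ModelHyperparams:
    lr: LrParams = field(default_factory=LrParams)
    prk: PrkParams = field(default_factory=PrkParams)
    rlda: RldaParams = field(default_factory=RldaParams)
    cv_folds: int = 10
    selection_metric: str = "mcc"

    def __post_init__(self) -> None:
        if not 0 < self.prk.pca_variance_kept <= 1:
            raise ValueError("pca_variance_kept must lie in (0, 1]")
        if not (0 <= self.prk.rda_lambda <= 1 and 0 <= self.prk.rda_gamma <= 1):
            raise ValueError("rda_lambda and rda_gamma must lie in [0, 1]")
        if self.cv_folds < 2:
            raise ValueError("cv_folds must be >= 2")


# ---------------------------------------------------------------------------
# Small numerical building blocks
# ---------------------------------------------------------------------------

class _GaussianKde1D:
    """1-D Gaussian KDE with Silverman bandwidth.

    Degenerate training scores (zero spread, e.g. a perfectly separable
    noise-free class) fall back to a tiny fixed bandwidth so densities
    stay finite and positive.
    """

    def __init__(self, points: np.ndarray):
        self.points = np.asarray(points, dtype=float).ravel()
        n = self.points.size
        if n == 0:
            raise ValueError("KDE needs at least one training score")
        sd = self.points.std(ddof=1) if n > 1 else 0.0
        factor = (3.0 * n / 4.0) ** (-0.2)  # Silverman, d = 1
        self.bandwidth = factor * sd if sd > 0 else 1e-6 * (1 + abs(self.points[0]))

    def log_density(self, x) -> np.ndarray:
        """Log density via logsumexp; immune to far-tail underflow."""
        x = np.atleast_1d(np.asarray(x, dtype=float))
        h = self.bandwidth
        z = (x[:, None] - self.points[None, :]) / h
        return (logsumexp(-0.5 * z * z, axis=1)
                - math.log(self.points.size * h * math.sqrt(2 * math.pi)))

    def __call__(self, x) -> np.ndarray:
        return np.exp(self.log_density(x))


def _logm_spd(mats: np.ndarray) -> np.ndarray:
    """Matrix logarithm of a stack of SPD matrices via batched eigh."""
    w, v = np.linalg.eigh(mats)
    w = np.clip(w, 1e-300, None)
    return np.einsum("...ij,...j,...kj->...ik", v, np.log(w), v)


def _powm_spd(mat: np.ndarray, power: float) -> np.ndarray:
    w, v = np.linalg.eigh(mat)
    w = np.clip(w, 1e-300, None)
    return (v * w ** power) @ v.T


def _expm_sym(mat: np.ndarray) -> np.ndarray:
    w, v = np.linalg.eigh(mat)
    return (v * np.exp(w)) @ v.T


def airm_mean(mats: np.ndarray, tol: float = 1e-8,
              max_iter: int = 150) -> np.ndarray:
    """Affine-invariant Riemannian mean of SPD matrices.

    Fixed-point iteration started from the log-Euclidean mean, with step
    halving whenever the gradient norm fails to decrease — the plain
    fixed point can oscillate on nearly singular inputs.
    """
    mats = np.asarray(mats, dtype=float)
    mean = _expm_sym(_logm_spd(mats).mean(axis=0))
    step = 1.0
    prev_norm, best_norm, stall = np.inf, np.inf, 0
    for _ in range(max_iter):
        half = _powm_spd(mean, 0.5)
        ihalf = _powm_spd(mean, -0.5)
        logs = _logm_spd(ihalf @ mats @ ihalf)
        delta = logs.mean(axis=0)
        norm = np.linalg.norm(delta)
        if norm < tol:
            return mean
        # ill-conditioned stacks bottom out above tol at the eigh
        # precision floor; accept the mean once progress has stalled there
        if norm < 1e-5 and norm > 0.5 * best_norm:
            stall += 1
            if stall >= 5:
                return mean
        else:
            stall = 0
        best_norm = min(best_norm, norm)
        if norm >= prev_norm:
            step = max(step / 2, 1e-3)
        prev_norm = norm
        # bound the update so near-singular stacks cannot drive the mean
        # into overflow before the damping engages
        w, v = np.linalg.eigh(step * delta)
        update = _expm_sym((v * np.clip(w, -40.0, 40.0)) @ v.T)
        mean = half @ update @ half
    raise RuntimeError(
        f"affine-invariant mean did not converge in {max_iter} iterations")


def tangent_vectors(mats: np.ndarray, reference: np.ndarray) -> np.ndarray:
    """Log-map SPD matrices at ``reference`` and vectorize.

    The upper triangle is kept with off-diagonal entries scaled by sqrt(2)
    so the Euclidean inner product of vectors matches the Riemannian
    metric at the reference; d x d matrices give d(d+1)/2 features.
    """
    mats = np.asarray(mats, dtype=float)
    single = mats.ndim == 2
    if single:
        mats = mats[None]
    ihalf = _powm_spd(reference, -0.5)
    logs = _logm_spd(ihalf @ mats @ ihalf)
    d = logs.shape[-1]
    iu = np.triu_indices(d)
    scale = np.where(iu[0] == iu[1], 1.0, math.sqrt(2.0))
    vecs = logs[:, iu[0], iu[1]] * scale
    return vecs[0] if single else vecs


# ---------------------------------------------------------------------------
# Trained-model containers
# ---------------------------------------------------------------------------

@dataclass
class TrainedModel:
    """Fitted classifier exposing per-trial positive likelihood ratios."""

    kind: str
    input_shape: tuple[int, int]  # (channels, samples)
    metadata: dict = field(default_factory=dict)

    def _check(self, trials: np.ndarray) -> np.ndarray:
        trials = np.asarray(trials, dtype=float)
        if trials.ndim != 3 or trials.shape[1:] != self.input_shape:
            raise ValueError(
                f"expected trials of shape (n, {self.input_shape[0]}, "
                f"{self.input_shape[1]}), got {trials.shape}")
        return trials

    def likelihood_ratios(self, trials: np.ndarray) -> np.ndarray:
        raise NotImplementedError


@dataclass
class PrkModel(TrainedModel):
    channel_pcas: list = field(default_factory=list)
    means: dict = field(default_factory=dict)       # class -> mean vector
    cho_factors: dict = field(default_factory=dict)  # class -> (L, logdet)
    kdes: dict = field(default_factory=dict)        # class -> _GaussianKde1D

    def _features(self, trials: np.ndarray) -> np.ndarray:
        blocks = [pca.transform(trials[:, c, :])
                  for c, pca in enumerate(self.channel_pcas)]
        return np.concatenate(blocks, axis=1)

    def discriminant_scores(self, trials: np.ndarray) -> np.ndarray:
        x = self._features(self._check(trials))
        return _rda_scores(x, self.means, self.cho_factors)

    def likelihood_ratios(self, trials: np.ndarray) -> np.ndarray:
        s = self.discriminant_scores(trials)
        log_ratio = self.kdes[1].log_density(s) - self.kdes[0].log_density(s)
        return np.exp(np.clip(log_ratio, -690.0, 690.0))


@dataclass
class LogisticModel(TrainedModel):
    pipeline: object = None
    prior_odds: float = 1.0

    def likelihood_ratios(self, trials: np.ndarray) -> np.ndarray:
        # posterior odds divided by training prior odds: the
        # class-conditional likelihood ratio, balanced at 1.0
        trials = self._check(trials)
        x = trials.reshape(trials.shape[0], -1)
        p = np.clip(self.pipeline.predict_proba(x)[:, 1], 1e-15, 1 - 1e-15)
        return p / (1 - p) / self.prior_odds


@dataclass
class RldaModel(TrainedModel):
    filters: np.ndarray = None        # (n_classes*nf, channels)
    prototypes: np.ndarray = None     # (n_classes*nf, samples)
    reference_mean: np.ndarray = None
    lda: object = None
    eps: float = 0.0
    prior_odds: float = 1.0

    def _covariances(self, trials: np.ndarray) -> np.ndarray:
        n, _, s = trials.shape
        filt = np.einsum("fc,ncs->nfs", self.filters, trials)
        proto = np.broadcast_to(self.prototypes,
                                (n,) + self.prototypes.shape)
        supers = np.concatenate([proto, filt], axis=1)
        covs = supers @ supers.transpose(0, 2, 1) / (s - 1)
        d = covs.shape[-1]
        covs = covs + self.eps * np.eye(d)[None]
        return covs

    def likelihood_ratios(self, trials: np.ndarray) -> np.ndarray:
        trials = self._check(trials)
        covs = self._covariances(trials)
        vecs = tangent_vectors(covs, self.reference_mean)
        p = np.clip(self.lda.predict_proba(vecs)[:, 1], 1e-15, 1 - 1e-15)
        return p / (1 - p) / self.prior_odds


# ---------------------------------------------------------------------------
# Fitting
# ---------------------------------------------------------------------------

def _require_two_classes(labels: np.ndarray) -> None:
    if len(np.unique(labels)) < 2:
        raise ValueError("training data must contain both classes")


def _metadata(data: TrialDataset, seed: int) -> dict:
    return {"band": list(data.band), "provenance": data.provenance,
            "seed": int(seed), "effective_fs": data.effective_fs}


def _fit_rda(x: np.ndarray, labels: np.ndarray, lam: float, gam: float
             ) -> tuple[dict, dict]:
    """Class means and Cholesky factors of the regularized covariances.

    Sigma_c(lam) = (1-lam)*S_c + lam*S_pooled, then
    Sigma_c(lam,gam) = (1-gam)*Sigma_c(lam) + gam*(trace/d)*I.
    """
    d = x.shape[1]
    masks = {0: labels == 0, 1: labels == 1}
    s_class = {c: np.cov(x[m], rowvar=False, ddof=1).reshape(d, d)
               for c, m in masks.items()}
    n0, n1 = masks[0].sum(), masks[1].sum()
    pooled = ((n0 - 1) * s_class[0] + (n1 - 1) * s_class[1]) / (n0 + n1 - 2)
    means, chols = {}, {}
    for cls, m in masks.items():
        sigma = (1 - lam) * s_class[cls] + lam * pooled
        sigma = (1 - gam) * sigma + gam * (np.trace(sigma) / d) * np.eye(d)
        # absolute floor so exactly-zero covariance (noise-free degenerate
        # classes) stays invertible without perturbing realistic scales
        sigma = sigma + 1e-12 * np.eye(d)
        try:
            chol = linalg.cholesky(sigma, lower=True)
        except linalg.LinAlgError as exc:
            raise ValueError(
                "singular class covariance despite regularization; "
                "increase rda_gamma") from exc
        logdet = 2.0 * np.sum(np.log(np.diag(chol)))
        means[cls] = x[m].mean(axis=0)
        chols[cls] = (chol, logdet)
    return means, chols


def _rda_scores(x: np.ndarray, means: dict, chols: dict) -> np.ndarray:
    logp = {}
    d = x.shape[1]
    for cls in (0, 1):
        diff = x - means[cls]
        chol, logdet = chols[cls]
        sol = linalg.cho_solve((chol, True), diff.T)
        maha = np.einsum("ij,ji->i", diff, sol)
        logp[cls] = -0.5 * (maha + logdet + d * math.log(2 * math.pi))
    return logp[1] - logp[0]


def fit_prk(data: TrialDataset, hp: ModelHyperparams,
            seed: int = 0, calibration_folds: int = 10) -> PrkModel:
    """Channel-wise PCA -> regularized discriminant -> per-class KDE.

    Per channel, the PCA keeps the smallest component count whose
    cumulative explained variance reaches ``pca_variance_kept`` (fit on
    all trials).  The RDA shrinks each class covariance toward the pooled
    covariance (lambda) and toward a scaled identity (gamma); the 1-D
    Gaussian log-density difference is the discriminant score.

    The class-conditional KDEs are fit on *out-of-fold* discriminant
    scores from an internal stratified split of the training data:
    in-sample scores are optimistically separated, which would bias the
    density ratio at the 1.0 decision threshold.
    """
    _require_two_classes(data.labels)
    trials, labels = data.trials, data.labels
    n, n_ch, _ = trials.shape

    pcas = []
    feats = []
    for c in range(n_ch):
        ncomp = (hp.prk.pca_variance_kept
                 if hp.prk.pca_variance_kept < 1 else None)
        pca = PCA(n_components=ncomp, svd_solver="full")
        feats.append(pca.fit_transform(trials[:, c, :]))
        pcas.append(pca)
    x = np.concatenate(feats, axis=1)

    lam, gam = hp.prk.rda_lambda, hp.prk.rda_gamma
    model = PrkModel(kind="PRK", input_shape=trials.shape[1:],
                     metadata=_metadata(data, seed), channel_pcas=pcas)
    model.means, model.cho_factors = _fit_rda(x, labels, lam, gam)

    # out-of-fold calibration scores for the KDEs
    folds = min(calibration_folds, int(np.bincount(labels).min()))
    if folds >= 2:
        scores = np.empty(n)
        skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
        for tr, te in skf.split(x, labels):
            means, chols = _fit_rda(x[tr], labels[tr], lam, gam)
            scores[te] = _rda_scores(x[te], means, chols)
    else:  # too few minority trials to split; fall back to in-sample scores
        scores = _rda_scores(x, model.means, model.cho_factors)
    model.kdes = {c: _GaussianKde1D(scores[labels == c]) for c in (0, 1)}
    return model


def fit_logistic(data: TrialDataset, hp: ModelHyperparams,
                 seed: int = 0) -> LogisticModel:
    """L2 logistic regression on standardized flattened trials.

    Standardization parameters come from the training data only;
    zero-variance features are centered and left unscaled.
    """
    _require_two_classes(data.labels)
    x = data.trials.reshape(data.n_trials, -1)
    pipe = make_pipeline(
        StandardScaler(),
        LogisticRegression(C=hp.lr.inverse_regularization_C,
                           solver="lbfgs", max_iter=hp.lr.max_iter,
                           tol=hp.lr.tol, random_state=seed))
    pipe.fit(x, data.labels)
    n1 = int(data.labels.sum())
    n0 = len(data.labels) - n1
    return LogisticModel(kind="LR", input_shape=data.trials.shape[1:],
                         metadata=_metadata(data, seed), pipeline=pipe,
                         prior_odds=n1 / n0)


def _xdawn_filters(trials: np.ndarray, labels: np.ndarray,
                   n_filters: int) -> tuple[np.ndarray, np.ndarray]:
    """Per-class xDAWN spatial filters and filtered evoked prototypes.

    For each class, filters maximize evoked-response energy relative to
    the average single-trial covariance (generalized eigenproblem).
    """
    _, n_ch, n_s = trials.shape
    noise_cov = np.einsum("ncs,nds->cd", trials, trials) / (
        trials.shape[0] * (n_s - 1))
    noise_cov += 1e-10 * np.mean(np.diag(noise_cov) + 1e-30) * np.eye(n_ch)
    filters, protos = [], []
    for cls in (0, 1):
        evoked = trials[labels == cls].mean(axis=0)
        sig_cov = evoked @ evoked.T / (n_s - 1)
        w, v = linalg.eigh(sig_cov, noise_cov)
        v = v[:, np.argsort(w)[::-1][:n_filters]].T  # (nf, channels)
        v = v / np.linalg.norm(v, axis=1, keepdims=True)
        filters.append(v)
        protos.append(v @ evoked)
    return np.concatenate(filters), np.concatenate(protos)


def fit_rlda(data: TrialDataset, hp: ModelHyperparams,
             seed: int = 0) -> RldaModel:
    """xDAWN covariances -> Riemannian tangent space -> shrinkage LDA."""
    _require_two_classes(data.labels)
    trials, labels = data.trials, data.labels
    filters, protos = _xdawn_filters(trials, labels,
                                     hp.rlda.xdawn_filters_per_class)
    model = RldaModel(kind="RLDA", input_shape=trials.shape[1:],
                      metadata=_metadata(data, seed), filters=filters,
                      prototypes=protos)
    # epsilon jitter keeps super-trial covariances strictly SPD
    probe = np.einsum("fc,ncs->nfs", filters, trials)
    model.eps = 1e-10 * float(np.mean(probe ** 2) + 1e-30)
    covs = model._covariances(trials)
    model.reference_mean = airm_mean(covs)
    vecs = tangent_vectors(covs, model.reference_mean)
    lda = LinearDiscriminantAnalysis(solver="eigen",
                                     shrinkage=hp.rlda.shrinkage)
    lda.fit(vecs, labels)
    model.lda = lda
    n1 = int(labels.sum())
    model.prior_odds = n1 / (len(labels) - n1)
    return model


_FITTERS = {"PRK": fit_prk, "LR": fit_logistic, "RLDA": fit_rlda}


def fit_model(kind: str, data: TrialDataset, hp: ModelHyperparams,
              seed: int = 0) -> TrainedModel:
    if kind not in _FITTERS:
        raise ValueError(f"unknown model kind {kind!r}; one of {MODEL_KINDS}")
    return _FITTERS[kind](data, hp, seed)


def predict_likelihoods(model: TrainedModel, data) -> np.ndarray:
    """Per-trial positive likelihood ratio p(target)/p(non-target)."""
    trials = data.trials if isinstance(data, TrialDataset) else data
    out = model.likelihood_ratios(trials)
    return np.maximum(out, 1e-300)


# ---------------------------------------------------------------------------
# Cross-validation
# ---------------------------------------------------------------------------

def _subset(data: TrialDataset, idx: np.ndarray) -> TrialDataset:
    return TrialDataset(data.trials[idx], data.labels[idx],
                        data.trial_window_s, data.effective_fs,
                        data.provenance, data.band, data.channel_names)


def _cv_once(kind: str, data: TrialDataset, hp: ModelHyperparams,
             seed: int) -> MetricResult:
    skf = StratifiedKFold(n_splits=hp.cv_folds, shuffle=True,
                          random_state=seed)
    fold_ba, fold_mcc, fold_tpr, fold_tnr = [], [], [], []
    for train_idx, test_idx in skf.split(data.trials, data.labels):
        test_labels = data.labels[test_idx]
        if len(np.unique(data.labels[train_idx])) < 2 or \
                len(np.unique(test_labels)) < 2:
            raise ValueError("a CV fold lacks one of the classes")
        model = fit_model(kind, _subset(data, train_idx), hp, seed)
        lik = predict_likelihoods(model, data.trials[test_idx])
        cm = ConfusionMatrix.from_predictions(test_labels, lik > 1.0)
        fold_ba.append(balanced_accuracy(cm))
        fold_mcc.append(matthews_cc(cm))
        fold_tpr.append(cm.tp / cm.n_positive)
        fold_tnr.append(cm.tn / cm.n_negative)
    fold_ba = np.asarray(fold_ba)
    fold_mcc = np.asarray(fold_mcc)
    return MetricResult(ba=float(fold_ba.mean()), mcc=float(fold_mcc.mean()),
                        tpr=float(np.mean(fold_tpr)),
                        tnr=float(np.mean(fold_tnr)),
                        fold_ba=fold_ba, fold_mcc=fold_mcc,
                        ba_sd=float(fold_ba.std(ddof=1)),
                        mcc_sd=float(fold_mcc.std(ddof=1)))


def cross_validate(model_kind: str, data: TrialDataset,
                   hp: ModelHyperparams, seed: int = 0,
                   grid: Optional[Sequence[dict]] = None) -> MetricResult:
    """Stratified k-fold cross-validation of one model kind.

    Classification thresholds the likelihood ratio at 1.0.  When a
    hyperparameter ``grid`` (list of PRK ``{"rda_lambda", "rda_gamma"}``
    dicts) is supplied, each point is cross-validated and the one
    maximizing the mean selection metric is reported.
    """
    if data.n_trials < hp.cv_folds:
        raise ValueError("need at least cv_folds trials")
    if grid is None:
        return _cv_once(model_kind, data, hp, seed)
    best, best_params, best_score = None, None, -np.inf
    for point in grid:
        hp_point = ModelHyperparams(
            lr=LrParams(**asdict(hp.lr)),
            prk=PrkParams(**{**asdict(hp.prk), **point}),
            rlda=RldaParams(**asdict(hp.rlda)),
            cv_folds=hp.cv_folds, selection_metric=hp.selection_metric)
        res = _cv_once(model_kind, data, hp_point, seed)
        score = getattr(res, hp.selection_metric)
        if score > best_score:
            best, best_params, best_score = res, dict(point), score
    best.chosen_params = best_params
    return best


# ---------------------------------------------------------------------------
# Serialization
# ---------------------------------------------------------------------------

def save_model(model: TrainedModel, path: str | Path) -> None:
    """Single-file archive: pickled model plus a JSON-style manifest."""
    payload = {
        "manifest": {"kind": model.kind,
                     "input_shape": list(model.input_shape),
                     "metadata": model.metadata,
                     "likelihood_convention": "ratio p(target)/p(nontarget)"},
        "model": model,
    }
    with open(path, "wb") as fh:
        pickle.dump(payload, fh)


def load_model(path: str | Path) -> TrainedModel:
    with open(path, "rb") as fh:
        payload = pickle.load(fh)
    return payload["model"]
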