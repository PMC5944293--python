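"""Per-target multivariate-Gaussian baseline classifier.

Each gaze pair is summarized by the 4-vector of signed coordinate
differences between the target and the two gaze points,

    u = (x_t - x_l,  y_t - y_l,  x_t - x_r,  y_t - y_r),

and, per target j, the u-vectors of *normal* training subjects are modeled
as a 4-D Gaussian N(mu_j, Sigma_j).  Classification is a three-level
thresholding cascade:

1. a gaze pair is normal iff its density exceeds alpha_j (strict >);
2. a target is normal iff the proportion of its normal pairs exceeds
   beta_j (strict >);
3. a subject is normal iff *all nine* targets are normal — one abnormal
   fixation direction suffices for a strabismic call, because direction-
   specific misalignment (incomitant strabismus) is itself diagnostic.

A target at which the subject produced zero effective pairs is counted
strabismic: failing to fixate a direction at all is the severe presentation
of the same signal.

The (alpha_j, beta_j) thresholds are learnt by grid search maximizing
subject-level training accuracy.  The alpha grid is adaptive — low
percentiles of the normal training pairs' densities at that target — so it
tracks the density scale of each target; beta ranges over 0.05..0.95 in
steps of 0.05.  The nine (alpha_j, beta_j) pairs are optimized by one
coordinate-ascent pass in target order, each target's grid being scored
jointly with the other targets' current thresholds.  Densities are handled
in log space internally; stored thresholds are on the density scale.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.linalg import cho_factor, cho_solve

from .core import GazeSession

__all__ = [
    "GaussianTargetModel",
    "BaselineModel",
    "SubjectResult",
    "deviation_vectors",
    "fit_target_model",
    "log_density",
    "density",
    "classify_subject",
    "learn_thresholds",
    "fit_baseline",
]

_DIM = 4
_MIN_TRAIN_VECTORS = 5
_COND_LIMIT = 1e8
_ALPHA_PERCENTILES = (0.5,) + tuple(float(q) for q in range(1, 21))
_BETA_GRID = tuple(round(0.05 * k, 2) for k in range(1, 20))


@dataclass(frozen=True)
class GaussianTargetModel:
    """Fitted normal-fixation model for one target: N(mu, Sigma) + thresholds."""

    target_index: int
    mean: np.ndarray
    cov: np.ndarray
    alpha: float | None = None
    beta: float | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "mean", np.asarray(self.mean, dtype=float))
        object.__setattr__(self, "cov", np.asarray(self.cov, dtype=float))
        if self.mean.shape != (_DIM,) or self.cov.shape != (_DIM, _DIM):
            raise ValueError("mean must be length 4 and cov 4x4")
        if not np.allclose(self.cov, self.cov.T, atol=1e-12):
            raise ValueError("covariance must be symmetric")


def deviation_vectors(session: GazeSession) -> dict[int, np.ndarray]:
    """Per-target (n_j, 4) arrays of target-minus-gaze difference vectors."""
    out: dict[int, list[list[float]]] = {t.index: [] for t in session.protocol.targets}
    for p in session.pairs:
        tx, ty = session.protocol.target(p.target_index).position
        out[p.target_index].append(
            [tx - p.left[0], ty - p.left[1], tx - p.right[0], ty - p.right[1]]
        )
    return {
        j: (np.asarray(v, dtype=float) if v else np.empty((0, _DIM)))
        for j, v in out.items()
    }


def fit_target_model(vectors: np.ndarray, target_index: int) -> GaussianTargetModel:
    """Fit mu and Sigma from normal-subject difference vectors at one target.

    Sample mean and covariance (ddof=1); when the covariance is singular or
    ill-conditioned (condition number above 1e8 — e.g. noise-free synthetic
    data) a small ridge proportional to the mean diagonal is added so the
    density stays finite.
    """
    vectors = np.asarray(vectors, dtype=float)
    if vectors.ndim != 2 or vectors.shape[1] != _DIM:
        raise ValueError(f"expected (n, 4) array, got shape {vectors.shape}")
    if vectors.shape[0] < _MIN_TRAIN_VECTORS:
        raise ValueError(
            f"need at least {_MIN_TRAIN_VECTORS} training vectors, got {vectors.shape[0]}"
        )
    mean = vectors.mean(axis=0)
    cov = np.cov(vectors, rowvar=False, ddof=1)
    eigvals = np.linalg.eigvalsh(cov)
    if eigvals[0] <= 0 or eigvals[-1] / max(eigvals[0], np.finfo(float).tiny) > _COND_LIMIT:
        trace = float(np.trace(cov))
        ridge = 1e-8 * (trace / _DIM) if trace > 0 else 1e-12
        cov = cov + ridge * np.eye(_DIM)
    return GaussianTargetModel(target_index=target_index, mean=mean, cov=cov)


def _chol(model: GaussianTargetModel):
    try:
        return cho_factor(model.cov, lower=True)
    except np.linalg.LinAlgError as exc:  # pragma: no cover - unreachable after ridge
        raise ValueError("covariance is not positive definite") from exc


def log_density(u: np.ndarray, model: GaussianTargetModel) -> np.ndarray | float:
    """Log of the 4-D Gaussian density, evaluated via Cholesky.

    log p(u) = -2 log(2 pi) - 1/2 log|Sigma| - 1/2 (u-mu)^T Sigma^-1 (u-mu)
    """
    u = np.asarray(u, dtype=float)
    single = u.ndim == 1
    pts = np.atleast_2d(u) - model.mean
    c, lower = _chol(model)
    logdet = 2.0 * float(np.sum(np.log(np.diag(c))))
    maha = np.einsum("ij,ij->i", pts, cho_solve((c, lower), pts.T).T)
    out = -_DIM / 2.0 * math.log(2.0 * math.pi) - 0.5 * logdet - 0.5 * maha
    return float(out[0]) if single else out


def density(u: np.ndarray, model: GaussianTargetModel) -> np.ndarray | float:
    """Gaussian density p(u; mu_j, Sigma_j) = exp(log_density)."""
    return np.exp(log_density(u, model))


@dataclass(frozen=True)
class SubjectResult:
    """Per-subject baseline decision with per-target audit detail."""

    label: str
    target_normal_proportion: dict[int, float]
    target_strabismic: dict[int, bool]


def _target_flags(
    session_vectors: dict[int, np.ndarray], models: dict[int, GaussianTargetModel]
) -> SubjectResult:
    proportions: dict[int, float] = {}
    flags: dict[int, bool] = {}
    for j, model in models.items():
        if model.alpha is None or model.beta is None:
            raise ValueError(f"model for target {j} has no thresholds set")
        vecs = session_vectors.get(j)
        if vecs is None or len(vecs) == 0:
            # No effective fixation at this direction at all: the severe
            # presentation of the abnormality the threshold cascade detects.
            proportions[j] = 0.0
            flags[j] = True
            continue
        dens = np.asarray(density(vecs, model))
        prop = float(np.mean(dens > model.alpha))
        proportions[j] = prop
        flags[j] = not (prop > model.beta)
    label = "strabismic" if any(flags.values()) else "normal"
    return SubjectResult(
        label=label, target_normal_proportion=proportions, target_strabismic=flags
    )


def classify_subject(
    session: GazeSession, models: dict[int, GaussianTargetModel]
) -> SubjectResult:
    """Apply the three-level decision cascade to one session."""
    return _target_flags(deviation_vectors(session), models)


def _fit_all_targets(normal_sessions: list[GazeSession]) -> dict[int, GaussianTargetModel]:
    pooled: dict[int, list[np.ndarray]] = {}
    for s in normal_sessions:
        for j, v in deviation_vectors(s).items():
            if len(v):
                pooled.setdefault(j, []).append(v)
    models = {}
    for j in sorted(pooled):
        models[j] = fit_target_model(np.vstack(pooled[j]), j)
    return models


def learn_thresholds(
    sessions: list[GazeSession], models: dict[int, GaussianTargetModel]
) -> dict[int, GaussianTargetModel]:
    """Grid-search (alpha_j, beta_j) maximizing subject-level training accuracy.

    Requires both classes among ``sessions``.  Deterministic: the alpha grid
    is the fixed percentile ladder of normal-training log-densities, beta the
    fixed 0.05 ladder, targets are scanned once in ascending index order, and
    ties are broken toward the smallest alpha then the largest beta.
    """
    labels = np.array([s.label for s in sessions])
    if not {"normal", "strabismic"} <= set(labels):
        raise ValueError("threshold learning needs both normal and strabismic sessions")
    y_true = labels == "strabismic"
    targets = sorted(models)
    per_subject = [deviation_vectors(s) for s in sessions]

    # Precompute, per target: log-densities of every subject's pairs and the
    # alpha grid from the pooled normal-subject log-densities.
    subject_logdens: dict[int, list[np.ndarray | None]] = {}
    alpha_grids: dict[int, np.ndarray] = {}
    for j in targets:
        rows: list[np.ndarray | None] = []
        normal_pool = []
        for vecs, lab in zip(per_subject, labels):
            v = vecs.get(j)
            if v is None or len(v) == 0:
                rows.append(None)
            else:
                ld = np.asarray(log_density(v, models[j]))
                rows.append(ld)
                if lab == "normal":
                    normal_pool.append(ld)
        subject_logdens[j] = rows
        pool = np.concatenate(normal_pool) if normal_pool else np.array([0.0])
        alpha_grids[j] = np.percentile(pool, _ALPHA_PERCENTILES)

    betas = np.asarray(_BETA_GRID)

    def flags_for(j: int, log_alpha: float, beta: float) -> np.ndarray:
        out = np.empty(len(sessions), dtype=bool)
        for s_idx, ld in enumerate(subject_logdens[j]):
            if ld is None:
                out[s_idx] = True
            else:
                out[s_idx] = not (float(np.mean(ld > log_alpha)) > beta)
        return out

    # Initialize every target maximally lenient (smallest alpha, smallest
    # beta), then one coordinate-ascent pass in target order.
    chosen = {j: (float(alpha_grids[j][0]), float(betas[0])) for j in targets}
    current_flags = {j: flags_for(j, *chosen[j]) for j in targets}
    for j in targets:
        others = np.zeros(len(sessions), dtype=bool)
        for k in targets:
            if k != j:
                others |= current_flags[k]
        best_acc = -1.0
        best: tuple[float, float, np.ndarray] | None = None
        for log_alpha in alpha_grids[j]:  # ascending
            # Proportions only change at alpha steps; scan betas per alpha.
            props = np.array(
                [
                    -1.0 if ld is None else float(np.mean(ld > log_alpha))
                    for ld in subject_logdens[j]
                ]
            )
            for beta in betas:  # ascending
                flag_j = ~(props > beta)
                acc = float(np.mean((others | flag_j) == y_true))
                # Ties keep the smallest alpha (first seen) and, within the
                # same alpha, the largest beta (last seen).
                if acc > best_acc:
                    best_acc = acc
                    best = (float(log_alpha), float(beta), flag_j)
                elif acc == best_acc and best is not None and log_alpha == best[0]:
                    best = (float(log_alpha), float(beta), flag_j)
        assert best is not None
        chosen[j] = (best[0], best[1])
        current_flags[j] = best[2]
    return {
        j: replace(models[j], alpha=float(np.exp(chosen[j][0])), beta=chosen[j][1])
        for j in targets
    }


@dataclass
class BaselineModel:
    """The nine fitted-and-thresholded per-target Gaussian models."""

    models: dict[int, GaussianTargetModel] = field(default_factory=dict)

    def classify(self, session: GazeSession) -> SubjectResult:
        return classify_subject(session, self.models)

    def save(self, path) -> None:
        payload = {
            str(j): {
                "mean": m.mean.tolist(),
                "cov": m.cov.tolist(),
                "alpha": m.alpha,
                "beta": m.beta,
            }
            for j, m in self.models.items()
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)

    @classmethod
    def load(cls, path) -> "BaselineModel":
        with open(path) as fh:
            payload = json.load(fh)
        models = {
            int(j): GaussianTargetModel(
                target_index=int(j),
                mean=np.asarray(rec["mean"]),
                cov=np.asarray(rec["cov"]),
                alpha=rec["alpha"],
                beta=rec["beta"],
            )
            for j, rec in payload.items()
        }
        return cls(models=models)


def fit_baseline(train_sessions: list[GazeSession]) -> BaselineModel:
    """Fit mu/Sigma on the normal training subjects, then learn thresholds.

    ``train_sessions`` must contain both classes; only the normal sessions
    contribute to the Gaussian parameters, all sessions to the thresholds.
    """
    normals = [s for s in train_sessions if s.label == "normal"]
    if not normals:
        raise ValueError("no normal sessions to fit Gaussian models on")
    models = _fit_all_targets(normals)
    if len(models) < 9:
        missing = sorted(set(range(1, 10)) - set(models))
        raise ValueError(f"normal training data missing targets {missing}")
    return BaselineModel(models=learn_thresholds(train_sessions, models))
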