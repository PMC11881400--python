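"""HMC Bayesian Last Layer (HBLL).

The trained MLP body is frozen and its last layer is replaced by a Bayesian
logistic regression on the hidden features H: an isotropic Gaussian prior
N(0, tau^{-1} I) on the h+1 last-layer parameters (weights plus bias), a
Bernoulli likelihood through the sigmoid, and posterior samples drawn by
vanilla Hamiltonian Monte Carlo with a Metropolis correction.

The sampler is preconditioned with the curvature at the mode: the chain is
initialized at the MAP estimate and the mass matrix is set to the negative
log-posterior Hessian there (momenta drawn from N(0, Hessian), kinetic
energy (1/2) p^T Hessian^{-1} p, position update through Hessian^{-1}), so
every posterior direction oscillates at roughly unit frequency and the
Metropolis-corrected chain mixes even when the hidden features make the
posterior ill-conditioned.  Leapfrog integration runs L steps of size eps; no step-size
adaptation or NUTS is used.  Predictions average sigmoid(H~ w_m) over the
posterior draws, which by Jensen's inequality pulls them toward 0.5 relative
to the plug-in MAP prediction whenever the sampled logits vary.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import cho_factor, cho_solve, cholesky, solve_triangular

from .datasets import BioactivityDataset, FoldSplit
from .metrics import accuracy as _acc
from .metrics import adaptive_calibration_error, auc as _auc, bce_loss
from .mlp import TrainedMLP
from .utils import check_binary_labels, clip_probs, log_sigmoid, sigmoid

DEFAULT_TAU_GRID = tuple(np.logspace(-3, 3, 7))


class MAPConvergenceError(RuntimeError):
    pass


class DivergenceError(RuntimeError):
    pass


@dataclass
class BLRProblem:
    """Bayesian logistic regression on frozen hidden features.

    The design matrix is augmented with a ones column for the bias; the
    single scalar prior precision tau covers all h+1 parameters.
    """

    H: np.ndarray
    y: np.ndarray
    prior_precision: float

    def __post_init__(self):
        self.H = np.asarray(self.H, dtype=np.float64)
        self.y = check_binary_labels(self.y)
        if self.H.ndim != 2 or self.H.shape[0] != self.y.shape[0]:
            raise ValueError("H must be (n, h) with one row per label")
        if not np.isfinite(self.H).all():
            raise ValueError("H must be finite")
        if self.prior_precision <= 0:
            raise ValueError("prior precision tau must be > 0")
        self._Ht = np.hstack([self.H, np.ones((self.H.shape[0], 1))])

    @property
    def n_params(self) -> int:
        return self.H.shape[1] + 1

    @property
    def design(self) -> np.ndarray:
        """Augmented design matrix [H | 1]."""
        return self._Ht


def log_posterior(w, prob: BLRProblem) -> tuple[float, np.ndarray]:
    """Unnormalized log posterior and its exact gradient.

    value = sum_i [y_i log s(z_i) + (1-y_i) log(1-s(z_i))] - (tau/2)||w||^2
    with z = [H|1] w;  gradient = [H|1]^T (y - s(z)) - tau w.
    """
    w = np.asarray(w, dtype=np.float64)
    if not np.isfinite(w).all():
        raise ValueError("non-finite weight vector")
    if w.shape != (prob.n_params,):
        raise ValueError(f"w must have shape ({prob.n_params},)")
    Ht, y, tau = prob.design, prob.y, prob.prior_precision
    z = Ht @ w
    val = float(np.sum(y * log_sigmoid(z) + (1 - y) * log_sigmoid(-z))
                - 0.5 * tau * np.dot(w, w))
    grad = Ht.T @ (y - sigmoid(z)) - tau * w
    return val, grad


def hessian_at(w, prob: BLRProblem) -> np.ndarray:
    """Negative Hessian of the log posterior: [H|1]^T S [H|1] + tau I (SPD)."""
    w = np.asarray(w, dtype=np.float64)
    Ht = prob.design
    s = sigmoid(Ht @ w)
    A = (Ht * (s * (1.0 - s))[:, None]).T @ Ht
    A[np.diag_indices_from(A)] += prob.prior_precision
    return 0.5 * (A + A.T)  # symmetrize against round-off


def map_fit(prob: BLRProblem, max_iter: int = 100, gtol: float = 1e-6) -> np.ndarray:
    """Damped Newton ascent to the unique posterior mode.

    tau > 0 makes the log posterior strictly concave, so Newton with step
    halving converges to the global maximum; terminates when the gradient
    norm falls below gtol relative to its initial value (and 1).
    """
    w = np.zeros(prob.n_params)
    val, grad = log_posterior(w, prob)
    scale = max(1.0, float(np.linalg.norm(grad)))
    for _ in range(max_iter):
        gnorm = float(np.linalg.norm(grad))
        if gnorm <= gtol * scale:
            return w
        A = hessian_at(w, prob)
        step = cho_solve(cho_factor(A), grad)
        t = 1.0
        for _ in range(50):
            w_new = w + t * step
            val_new, grad_new = log_posterior(w_new, prob)
            if val_new >= val:
                break
            t *= 0.5
        else:
            raise MAPConvergenceError("Newton line search failed to improve")
        w, val, grad = w_new, val_new, grad_new
    gnorm = float(np.linalg.norm(grad))
    if gnorm <= gtol * scale:
        return w
    raise MAPConvergenceError(
        f"MAP did not converge in {max_iter} iterations (|grad| = {gnorm:.3g})"
    )


@dataclass
class HMCConfig:
    """Vanilla HMC settings; defaults follow the study protocol
    (500 burn-in, 1000 samples, L = 1200, eps = 0.01, one chain)."""

    n_burnin: int = 500
    n_samples: int = 1000
    leapfrog_steps: int = 1200
    step_size: float = 0.01
    inverse_mass_matrix: np.ndarray | None = None  # None => identity
    seed: int = 0
    n_chains: int = 1

    def __post_init__(self):
        if self.step_size <= 0 or self.leapfrog_steps < 1:
            raise ValueError("step_size must be > 0 and leapfrog_steps >= 1")
        if self.inverse_mass_matrix is not None:
            A = np.asarray(self.inverse_mass_matrix, dtype=np.float64)
            if A.ndim != 2 or A.shape[0] != A.shape[1]:
                raise ValueError("inverse mass matrix must be square")
            if not np.allclose(A, A.T, atol=1e-10):
                raise ValueError("inverse mass matrix must be symmetric")
            self.inverse_mass_matrix = 0.5 * (A + A.T)

    def replace(self, **kwargs) -> "HMCConfig":
        d = {**self.__dict__, **kwargs}
        return HMCConfig(**d)


@dataclass
class PosteriorSamples:
    """Retained posterior draws of the last-layer parameter vector."""

    samples: np.ndarray  # (n_samples, d)
    acceptance_rate: float
    log_post_trace: np.ndarray = field(repr=False, default=None)

    @property
    def n_samples(self) -> int:
        return self.samples.shape[0]

    def mean(self) -> np.ndarray:
        return self.samples.mean(axis=0)

    def var(self) -> np.ndarray:
        return self.samples.var(axis=0, ddof=1)


def _chol_with_jitter(A: np.ndarray) -> np.ndarray:
    """Lower Cholesky factor; adds 1e-8 I once if factorization fails."""
    try:
        return cholesky(A, lower=True)
    except np.linalg.LinAlgError:
        A = A + 1e-8 * np.eye(A.shape[0])
        return cholesky(A, lower=True)


def leapfrog(grad_fn, w, p, step_size: float, n_steps: int, A: np.ndarray | None):
    """L leapfrog steps of Hamiltonian dynamics.

    A is the inverse mass matrix (None = identity): position update uses
    dw/dt = M^{-1} p = A p.  Time-reversible and symplectic.
    """
    w = w.copy()
    p = p.copy()
    g = grad_fn(w)
    for _ in range(n_steps):
        p = p + 0.5 * step_size * g
        w = w + step_size * (A @ p if A is not None else p)
        g = grad_fn(w)
        p = p + 0.5 * step_size * g
    return w, p


def hmc_sample(target, init, cfg: HMCConfig) -> PosteriorSamples:
    """Vanilla HMC with Metropolis correction.

    ``target(w) -> (log_density, gradient)``.  Momenta are drawn from
    N(0, M) with M the inverse of ``cfg.inverse_mass_matrix`` (identity when
    unset); kinetic energy is (1/2) p^T A p.  Non-finite trajectories are
    rejected and logged; if more than half of all proposals diverge the
    sampler aborts.
    """
    init = np.asarray(init, dtype=np.float64)
    d = init.shape[0]
    val0, _ = target(init)
    if not np.isfinite(val0):
        raise ValueError("target must be finite at the initial point")

    A = cfg.inverse_mass_matrix
    if A is not None:
        L_A = _chol_with_jitter(A)  # A = L_A L_A^T ; momentum cov M = A^{-1}

    def draw_momentum(rng):
        z = rng.standard_normal(d)
        if A is None:
            return z
        # p = L_A^{-T} z  has covariance A^{-1} = M
        return solve_triangular(L_A.T, z, lower=False)

    def kinetic(p):
        return 0.5 * float(p @ (A @ p)) if A is not None else 0.5 * float(p @ p)

    def grad_fn(w):
        return target(w)[1]

    chains = []
    traces = []
    n_accept = 0
    n_diverge = 0
    n_total = 0
    for c in range(cfg.n_chains):
        rng = np.random.default_rng(cfg.seed + c)
        w = init.copy()
        logp, _ = target(w)
        kept = np.empty((cfg.n_samples, d))
        trace = np.empty(cfg.n_samples)
        for it in range(cfg.n_burnin + cfg.n_samples):
            n_total += 1
            p = draw_momentum(rng)
            H_old = -logp + kinetic(p)
            with np.errstate(over="ignore", invalid="ignore"):
                try:
                    w_new, p_new = leapfrog(grad_fn, w, p, cfg.step_size,
                                            cfg.leapfrog_steps, A)
                    logp_new, _ = target(w_new) if np.isfinite(w_new).all() else (-np.inf, None)
                except (ValueError, FloatingPointError):
                    logp_new, w_new, p_new = -np.inf, None, None
            if w_new is None or not (np.isfinite(logp_new) and np.isfinite(p_new).all()):
                n_diverge += 1
                accept = False
            else:
                H_new = -logp_new + kinetic(p_new)
                accept = np.log(rng.random()) < min(0.0, H_old - H_new)
            if accept:
                w, logp = w_new, logp_new
                n_accept += 1
            if it >= cfg.n_burnin:
                kept[it - cfg.n_burnin] = w
                trace[it - cfg.n_burnin] = logp
            if n_total >= 20 and n_diverge > 0.5 * n_total:
                raise DivergenceError(
                    f"{n_diverge}/{n_total} trajectories non-finite; "
                    "reduce step_size or check the target"
                )
        chains.append(kept)
        traces.append(trace)
    return PosteriorSamples(
        samples=np.vstack(chains),
        acceptance_rate=n_accept / n_total,
        log_post_trace=np.concatenate(traces),
    )


def build_blr_problem(model: TrainedMLP, data: BioactivityDataset,
                      split: FoldSplit, prior_precision: float) -> BLRProblem:
    """Hidden features of the training folds -> BLRProblem."""
    tr = data.fold_indices(split.train_folds)
    H = model.hidden_features(data.features.data[tr])
    return BLRProblem(H=H, y=data.labels[tr], prior_precision=prior_precision)


def _precondition_from_hessian(H: np.ndarray) -> np.ndarray:
    """Inverse mass matrix derived from the MAP curvature.

    The mass matrix is set to the negative log-posterior Hessian (momentum
    covariance = curvature), so the position update moves through
    Hessian^{-1} and every posterior direction oscillates at unit frequency.
    Computed via Cholesky of the (jittered) Hessian.
    """
    L = _chol_with_jitter(H)
    inv = cho_solve((L, True), np.eye(H.shape[0]))
    return 0.5 * (inv + inv.T)


def fit_hbll(model: TrainedMLP, data: BioactivityDataset, split: FoldSplit,
             prior_precision: float, cfg: HMCConfig | None = None) -> PosteriorSamples:
    """MAP fit, Hessian preconditioning, then HMC over the last-layer posterior."""
    cfg = cfg or HMCConfig()
    prob = build_blr_problem(model, data, split, prior_precision)
    w_map = map_fit(prob)
    A = _precondition_from_hessian(hessian_at(w_map, prob))
    cfg = cfg.replace(inverse_mass_matrix=A)
    return hmc_sample(lambda w: log_posterior(w, prob), w_map, cfg)


def hbll_predict(samples: PosteriorSamples, model: TrainedMLP, X) -> np.ndarray:
    """Posterior predictive mean: average of sigmoid([H|1] w_m) over draws."""
    H = model.hidden_features(X)
    Ht = np.hstack([H, np.ones((H.shape[0], 1))])
    if samples.samples.shape[1] != Ht.shape[1]:
        raise ValueError("posterior sample dimension does not match h+1")
    probs = sigmoid(Ht @ samples.samples.T).mean(axis=1)
    return clip_probs(probs)


_TUNE_DIRECTIONS = {"bce": min, "ace": min, "auc": max, "acc": max}


def tune_prior_precision(model: TrainedMLP, data: BioactivityDataset,
                         split: FoldSplit, tau_grid=DEFAULT_TAU_GRID,
                         cfg: HMCConfig | None = None,
                         criterion: str = "bce"):
    """Grid-tune tau on the validation fold; ties go to the larger tau.

    Returns (best_tau, report) where report lists the validation score per tau.
    """
    tau_grid = list(tau_grid)
    if not tau_grid:
        raise ValueError("tau grid must be non-empty")
    if criterion not in _TUNE_DIRECTIONS:
        raise ValueError(f"criterion must be one of {sorted(_TUNE_DIRECTIONS)}")
    cfg = cfg or HMCConfig()
    va = data.fold_indices(split.valid_fold)
    X_va, y_va = data.features.data[va], data.labels[va]
    scorers = {"bce": bce_loss, "ace": adaptive_calibration_error,
               "auc": _auc, "acc": _acc}
    rows = []
    for tau in tau_grid:
        samples = fit_hbll(model, data, split, tau, cfg)
        probs = hbll_predict(samples, model, X_va)
        rows.append({"tau": float(tau),
                     "score": float(scorers[criterion](probs, y_va)),
                     "criterion": criterion,
                     "acceptance_rate": samples.acceptance_rate})
    better = _TUNE_DIRECTIONS[criterion]
    best_score = better(r["score"] for r in rows)
    best_tau = max(r["tau"] for r in rows if r["score"] == best_score)
    return best_tau, rows


@dataclass
class HBLLResults:
    """Posterior samples plus the pieces needed for prediction and summary."""

    posterior: PosteriorSamples
    map_weights: np.ndarray
    prior_precision: float
    model: TrainedMLP

    def predict_proba(self, X) -> np.ndarray:
        return hbll_predict(self.posterior, self.model, X)

    def summary(self) -> str:
        m = self.posterior.mean()
        s = np.sqrt(self.posterior.var())
        lines = [
            "HMC Bayesian last layer (logistic regression on frozen hidden features)",
            f"  parameters: {len(m)} (incl. bias)   prior precision tau: {self.prior_precision:g}",
            f"  retained samples: {self.posterior.n_samples}   "
            f"acceptance rate: {self.posterior.acceptance_rate:.3f}",
            f"  posterior mean |w|: {np.linalg.norm(m):.4f}   mean sd: {s.mean():.4f}",
        ]
        return "\n".join(lines)


class BayesianLastLayer:
    """Model object over a trained MLP: ``fit()`` returns HBLLResults."""

    def __init__(self, model: TrainedMLP, data: BioactivityDataset, split: FoldSplit,
                 prior_precision: float = 1.0, hmc_config: HMCConfig | None = None):
        self.model = model
        self.data = data
        self.split = split
        self.prior_precision = prior_precision
        self.hmc_config = hmc_config or HMCConfig()

    def fit(self) -> HBLLResults:
        prob = build_blr_problem(self.model, self.data, self.split,
                                 self.prior_precision)
        w_map = map_fit(prob)
        A = _precondition_from_hessian(hessian_at(w_map, prob))
        cfg = self.hmc_config.replace(inverse_mass_matrix=A)
        posterior = hmc_sample(lambda w: log_posterior(w, prob), w_map, cfg)
        return HBLLResults(posterior=posterior, map_weights=w_map,
                           prior_precision=self.prior_precision, model=self.model)
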