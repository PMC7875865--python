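"""Gaussian-emission hidden Markov models on 2D fixation coordinates.

The model is the classic triplet lambda = (A, B, pi): an initial state
distribution pi, a row-stochastic transition matrix A, and per-state 2D
Gaussian emission densities B over pixel coordinates. Each hidden state is a
latent "attraction region" of the image; a scanpath is a sequence of emissions
from the state chain.

All recursions run in scaled arithmetic with a per-frame shift of the emission
log-densities, so likelihoods stay finite for sequences up to 10^4 fixations
even when fixations land hundreds of standard deviations from some state.
Hot loops (forward-backward, Viterbi) are JIT-compiled with numba.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np
from numba import njit

from .errors import DegenerateModelError, InfeasibleError, IntegrityError

#: smallest admissible per-axis emission variance (px^2); prevents a state from
#: collapsing onto a single fixation during EM
VARIANCE_FLOOR = 1.0

#: minimum fixations per state required to attempt an EM fit
MIN_OBS_PER_STATE = 5

_PROB_ATOL = 1e-9


def _as_xy(seq) -> np.ndarray:
    """Accept a FixationSequence or a (T, 2) array-like."""
    xy = seq.xy if hasattr(seq, "xy") else np.asarray(seq, dtype=float)
    xy = np.atleast_2d(xy)
    if xy.shape[1] != 2:
        raise IntegrityError("observation sequences must be (T, 2) coordinate arrays")
    return np.ascontiguousarray(xy, dtype=float)


def _as_xy_list(sequences) -> list[np.ndarray]:
    if hasattr(sequences, "xy") or (
        isinstance(sequences, np.ndarray) and sequences.ndim == 2
    ):
        sequences = [sequences]
    out = [_as_xy(s) for s in sequences]
    if not out:
        raise IntegrityError("need at least one observation sequence")
    return out


# ---------------------------------------------------------------------------
# model container
# ---------------------------------------------------------------------------

@dataclass
class GaussianHMM:
    """lambda = (A, B, pi) with 2D Gaussian emissions.

    Parameters
    ----------
    pi : (N,) initial state distribution.
    A : (N, N) row-stochastic transition matrix.
    means : (N, 2) emission centers in pixels.
    covars : (N, 2) per-axis variances (``covariance_kind="diag"``, default) or
        (N, 2, 2) full covariance matrices (``covariance_kind="full"``).
    """

    pi: np.ndarray
    A: np.ndarray
    means: np.ndarray
    covars: np.ndarray
    covariance_kind: str = "diag"

    def __post_init__(self):
        self.pi = np.asarray(self.pi, dtype=float)
        self.A = np.asarray(self.A, dtype=float)
        self.means = np.asarray(self.means, dtype=float)
        self.covars = np.asarray(self.covars, dtype=float)
        self.validate()

    @property
    def n_states(self) -> int:
        return len(self.pi)

    def validate(self) -> None:
        n = self.n_states
        if n < 1:
            raise IntegrityError("model needs at least one state")
        if self.A.shape != (n, n):
            raise IntegrityError(f"A must be {n}x{n}")
        if abs(self.pi.sum() - 1.0) > _PROB_ATOL or (self.pi < -_PROB_ATOL).any():
            raise IntegrityError("pi must be a probability vector")
        rows = self.A.sum(axis=1)
        if np.abs(rows - 1.0).max() > _PROB_ATOL or (self.A < -_PROB_ATOL).any():
            raise IntegrityError("A must be row-stochastic")
        if self.means.shape != (n, 2):
            raise IntegrityError(f"means must be ({n}, 2)")
        if self.covariance_kind == "diag":
            if self.covars.shape != (n, 2):
                raise IntegrityError(f"diag covars must be ({n}, 2)")
            if (self.covars < VARIANCE_FLOOR - 1e-12).any():
                raise IntegrityError(f"variances must be >= {VARIANCE_FLOOR} px^2")
        elif self.covariance_kind == "full":
            if self.covars.shape != (n, 2, 2):
                raise IntegrityError(f"full covars must be ({n}, 2, 2)")
            for k, c in enumerate(self.covars):
                if np.diag(c).min() < VARIANCE_FLOOR - 1e-12 or np.linalg.det(c) <= 0:
                    raise IntegrityError(f"state {k}: covariance not positive definite")
        else:
            raise IntegrityError(f"unknown covariance_kind {self.covariance_kind!r}")

    # -- emission densities -------------------------------------------------

    def emission_logprob(self, xy: np.ndarray) -> np.ndarray:
        """(T, N) log-density of each observation under each state's Gaussian."""
        xy = _as_xy(xy)
        if self.covariance_kind == "diag":
            d = xy[:, None, :] - self.means[None, :, :]  # (T, N, 2)
            var = self.covars[None, :, :]
            return -0.5 * (
                (d * d / var).sum(axis=2)
                + np.log(var).sum(axis=2)
                + 2.0 * math.log(2.0 * math.pi)
            )
        out = np.empty((len(xy), self.n_states))
        for k in range(self.n_states):
            c = self.covars[k]
            chol = np.linalg.cholesky(c)
            sol = np.linalg.solve(chol, (xy - self.means[k]).T)
            maha = (sol * sol).sum(axis=0)
            logdet = 2.0 * np.log(np.diag(chol)).sum()
            out[:, k] = -0.5 * (maha + logdet + 2.0 * math.log(2.0 * math.pi))
        return out

    # -- serialisation ------------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "n_states": self.n_states,
            "pi": self.pi.tolist(),
            "A": self.A.tolist(),
            "means": self.means.tolist(),
            "variances": self.covars.tolist(),
            "covariance_kind": self.covariance_kind,
        }

    def to_json(self, path=None) -> str:
        text = json.dumps(self.to_dict(), indent=1)
        if path is not None:
            with open(path, "w", encoding="utf-8") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_dict(cls, d: dict) -> "GaussianHMM":
        return cls(
            pi=np.array(d["pi"], dtype=float),
            A=np.array(d["A"], dtype=float),
            means=np.array(d["means"], dtype=float),
            covars=np.array(d["variances"], dtype=float),
            covariance_kind=d.get("covariance_kind", "diag"),
        )

    @classmethod
    def from_json(cls, source) -> "GaussianHMM":
        if isinstance(source, str) and source.lstrip().startswith("{"):
            return cls.from_dict(json.loads(source))
        with open(source, encoding="utf-8") as fh:
            return cls.from_dict(json.load(fh))


@dataclass
class FitResult:
    """Outcome of one Baum-Welch run."""

    model: GaussianHMM
    log_likelihood: float
    loglik_trace: list[float]
    n_iterations: int
    converged: bool
    seed: int
    n_observations: int

    def __post_init__(self):
        if self.n_observations <= 0:
            raise IntegrityError("a fit must use at least one observation")


# ---------------------------------------------------------------------------
# numba kernels (scaled forward-backward, Viterbi)
# ---------------------------------------------------------------------------

@njit(cache=True)
def _fb_kernel(pi, A, logB):  # pragma: no cover - exercised through wrappers
    T, N = logB.shape
    B = np.empty((T, N))
    shift = np.empty(T)
    for t in range(T):
        m = logB[t, 0]
        for j in range(1, N):
            if logB[t, j] > m:
                m = logB[t, j]
        shift[t] = m
        for j in range(N):
            B[t, j] = math.exp(logB[t, j] - m)
    alpha = np.empty((T, N))
    c = np.empty(T)
    s = 0.0
    for j in range(N):
        alpha[0, j] = pi[j] * B[0, j]
        s += alpha[0, j]
    if s <= 0.0 or not np.isfinite(s):
        return -np.inf, alpha, np.zeros((N, N)), alpha[0]
    c[0] = s
    for j in range(N):
        alpha[0, j] /= s
    for t in range(1, T):
        s = 0.0
        for j in range(N):
            acc = 0.0
            for i in range(N):
                acc += alpha[t - 1, i] * A[i, j]
            acc *= B[t, j]
            alpha[t, j] = acc
            s += acc
        if s <= 0.0 or not np.isfinite(s):
            return -np.inf, alpha, np.zeros((N, N)), alpha[0]
        c[t] = s
        for j in range(N):
            alpha[t, j] /= s
    beta = np.ones(N)
    gamma = np.empty((T, N))
    xi_sum = np.zeros((N, N))
    for j in range(N):
        gamma[T - 1, j] = alpha[T - 1, j]
    for t in range(T - 2, -1, -1):
        nb = np.empty(N)
        for i in range(N):
            acc = 0.0
            for j in range(N):
                term = A[i, j] * B[t + 1, j] * beta[j]
                acc += term
                xi_sum[i, j] += alpha[t, i] * term / c[t + 1]
            nb[i] = acc / c[t + 1]
        tot = 0.0
        for i in range(N):
            gamma[t, i] = alpha[t, i] * nb[i]
            tot += gamma[t, i]
        for i in range(N):
            gamma[t, i] /= tot
        beta = nb
    # xi rows need the same per-t normalisation already absorbed via c; rescale
    # so that sum_j xi_sum[i, j] == sum_t gamma[t, i] for t < T-1 (holds by
    # construction of the scaled recursion, no extra work needed)
    ll = 0.0
    for t in range(T):
        ll += math.log(c[t]) + shift[t]
    return ll, gamma, xi_sum, gamma[0].copy()


@njit(cache=True)
def _viterbi_kernel(log_pi, log_A, logB):  # pragma: no cover
    T, N = logB.shape
    delta = np.empty((T, N))
    psi = np.zeros((T, N), dtype=np.int64)
    for j in range(N):
        delta[0, j] = log_pi[j] + logB[0, j]
    for t in range(1, T):
        for j in range(N):
            best = delta[t - 1, 0] + log_A[0, j]
            arg = 0
            for i in range(1, N):
                v = delta[t - 1, i] + log_A[i, j]
                if v > best:  # strict: ties stay at the lower index
                    best = v
                    arg = i
            delta[t, j] = best + logB[t, j]
            psi[t, j] = arg
    best = delta[T - 1, 0]
    arg = 0
    for j in range(1, N):
        if delta[T - 1, j] > best:
            best = delta[T - 1, j]
            arg = j
    path = np.empty(T, dtype=np.int64)
    path[T - 1] = arg
    for t in range(T - 2, -1, -1):
        path[t] = psi[t + 1, path[t + 1]]
    return path, best


def _forward_backward(model: GaussianHMM, xy: np.ndarray):
    logB = model.emission_logprob(xy)
    ll, gamma, xi_sum, gamma0 = _fb_kernel(model.pi, model.A, logB)
    if not np.isfinite(ll):
        raise DegenerateModelError(
            "zero total emission probability at some step (degenerate variances?)"
        )
    return ll, gamma, xi_sum, gamma0


# ---------------------------------------------------------------------------
# inference API
# ---------------------------------------------------------------------------

def log_likelihood(model: GaussianHMM, sequences) -> float:
    """Sum of per-sequence log-likelihoods under the model (scaled forward pass).

    Each sequence independently starts from pi.
    """
    return float(sum(_forward_backward(model, xy)[0] for xy in _as_xy_list(sequences)))


def posterior_state_probs(model: GaussianHMM, sequence) -> np.ndarray:
    """(T, N) smoothed state probabilities P(state_t = j | whole sequence)."""
    _, gamma, _, _ = _forward_backward(model, _as_xy(sequence))
    return gamma


def viterbi_path(model: GaussianHMM, sequence) -> np.ndarray:
    """Most probable joint state path; ties broken toward the lower state index."""
    xy = _as_xy(sequence)
    with np.errstate(divide="ignore"):
        log_pi = np.log(model.pi)
        log_A = np.log(model.A)
    path, _ = _viterbi_kernel(log_pi, log_A, model.emission_logprob(xy))
    return path


def viterbi_logprob(model: GaussianHMM, sequence) -> float:
    xy = _as_xy(sequence)
    with np.errstate(divide="ignore"):
        _, lp = _viterbi_kernel(np.log(model.pi), np.log(model.A), model.emission_logprob(xy))
    return float(lp)


# ---------------------------------------------------------------------------
# initialisation and EM
# ---------------------------------------------------------------------------

def initialize_params(
    sequences,
    n_states: int,
    seed: int = 0,
    strategy: str = "kmeans",
    covariance_kind: str = "diag",
    self_transition: float = 0.8,
) -> GaussianHMM:
    """Build a starting model for EM.

    ``"kmeans"`` centers the emission means on coordinate clusters (stable
    default); ``"random"`` samples means from the observed fixations (used for
    restarts). The transition matrix starts with self-transition mass
    ``self_transition`` and the remainder spread uniformly — fixation sequences
    are strongly persistent. pi starts uniform. Deterministic given the seed.
    """
    xys = _as_xy_list(sequences)
    pooled = np.concatenate(xys, axis=0)
    n_obs = len(pooled)
    if n_states > n_obs:
        raise InfeasibleError(f"cannot place {n_states} states on {n_obs} fixations")
    rng = np.random.default_rng(seed)
    pooled_var = np.maximum(pooled.var(axis=0, ddof=0), VARIANCE_FLOOR)
    if strategy == "kmeans":
        from sklearn.cluster import KMeans

        km = KMeans(
            n_clusters=n_states,
            n_init=1,
            random_state=int(rng.integers(2**31 - 1)),
        ).fit(pooled)
        means = km.cluster_centers_.copy()
        variances = np.empty((n_states, 2))
        for k in range(n_states):
            pts = pooled[km.labels_ == k]
            if len(pts) >= 2:
                variances[k] = np.maximum(pts.var(axis=0, ddof=0), VARIANCE_FLOOR)
            else:
                variances[k] = pooled_var
    elif strategy == "random":
        idx = rng.choice(n_obs, size=n_states, replace=False)
        means = pooled[idx].copy()
        variances = np.tile(pooled_var / max(n_states, 1), (n_states, 1))
        variances = np.maximum(variances, VARIANCE_FLOOR)
    else:
        raise IntegrityError(f"unknown initialisation strategy {strategy!r}")
    if n_states == 1:
        A = np.ones((1, 1))
    else:
        off = (1.0 - self_transition) / (n_states - 1)
        A = np.full((n_states, n_states), off)
        np.fill_diagonal(A, self_transition)
    pi = np.full(n_states, 1.0 / n_states)
    if covariance_kind == "full":
        covars = np.zeros((n_states, 2, 2))
        covars[:, 0, 0] = variances[:, 0]
        covars[:, 1, 1] = variances[:, 1]
    else:
        covars = variances
    return GaussianHMM(pi=pi, A=A, means=means, covars=covars, covariance_kind=covariance_kind)


def _floor_covars(covars: np.ndarray, kind: str) -> np.ndarray:
    if kind == "diag":
        return np.maximum(covars, VARIANCE_FLOOR)
    out = covars.copy()
    for k in range(len(out)):
        out[k, 0, 0] = max(out[k, 0, 0], VARIANCE_FLOOR)
        out[k, 1, 1] = max(out[k, 1, 1], VARIANCE_FLOOR)
        # keep positive definite: cap |cov| below the geometric mean of variances
        cap = 0.999 * math.sqrt(out[k, 0, 0] * out[k, 1, 1])
        out[k, 0, 1] = np.clip(out[k, 0, 1], -cap, cap)
        out[k, 1, 0] = out[k, 0, 1]
    return out


def baum_welch(
    sequences,
    n_states: int,
    seed: int = 0,
    max_iter: int = 500,
    tol: float = 1e-6,
    strategy: str = "kmeans",
    covariance_kind: str = "diag",
    init: GaussianHMM | None = None,
) -> FitResult:
    """Unconstrained EM estimation of a Gaussian HMM from pooled scanpaths.

    Expected counts accumulate across sequences; pi is re-estimated from the
    per-sequence initial posteriors. Convergence when the relative
    log-likelihood improvement drops below ``tol`` (default 1e-6) or after
    ``max_iter`` iterations. A variance floor of 1 px^2 is enforced at every
    M-step.
    """
    xys = _as_xy_list(sequences)
    n_obs = sum(len(x) for x in xys)
    if n_obs < MIN_OBS_PER_STATE * n_states:
        raise InfeasibleError(
            f"{n_obs} fixations cannot support {n_states} states "
            f"(need >= {MIN_OBS_PER_STATE} per state)"
        )
    model = init if init is not None else initialize_params(
        xys, n_states, seed=seed, strategy=strategy, covariance_kind=covariance_kind
    )
    trace: list[float] = []
    prev_ll = -np.inf
    converged = False
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        # E-step
        ll_total = 0.0
        gamma_sum = np.zeros(n_states)          # sum over all t
        gamma_trans = np.zeros(n_states)        # sum over t < T-1 (rows of xi)
        xi_total = np.zeros((n_states, n_states))
        pi_acc = np.zeros(n_states)
        mean_acc = np.zeros((n_states, 2))
        if covariance_kind == "diag":
            sq_acc = np.zeros((n_states, 2))
        else:
            sq_acc = np.zeros((n_states, 2, 2))
        try:
            for xy in xys:
                ll, gamma, xi_sum, gamma0 = _forward_backward(model, xy)
                ll_total += ll
                pi_acc += gamma0
                gamma_sum += gamma.sum(axis=0)
                if len(xy) > 1:
                    gamma_trans += gamma[:-1].sum(axis=0)
                    xi_total += xi_sum
                mean_acc += gamma.T @ xy
                if covariance_kind == "diag":
                    sq_acc += gamma.T @ (xy * xy)
                else:
                    for k in range(n_states):
                        w = gamma[:, k][:, None]
                        sq_acc[k] += (w * xy).T @ xy
        except DegenerateModelError as exc:
            raise DegenerateModelError(
                f"numerical degeneracy at EM iteration {n_iter}", iteration=n_iter
            ) from exc
        trace.append(ll_total)
        # M-step
        pi = pi_acc / pi_acc.sum()
        if n_states == 1:
            A = np.ones((1, 1))
        else:
            rows = xi_total.sum(axis=1, keepdims=True)
            A = np.where(rows > 0, xi_total / np.where(rows > 0, rows, 1.0),
                         1.0 / n_states)
        denom = np.maximum(gamma_sum, 1e-300)[:, None]
        means = mean_acc / denom
        if covariance_kind == "diag":
            covars = sq_acc / denom - means**2
        else:
            covars = sq_acc / np.maximum(gamma_sum, 1e-300)[:, None, None] - np.einsum(
                "ki,kj->kij", means, means
            )
        covars = _floor_covars(covars, covariance_kind)
        model = GaussianHMM(
            pi=pi, A=A, means=means, covars=covars, covariance_kind=covariance_kind
        )
        if np.isfinite(prev_ll):
            denom_ll = max(abs(prev_ll), 1.0)
            if (ll_total - prev_ll) / denom_ll < tol:
                converged = True
                prev_ll = ll_total
                break
        prev_ll = ll_total
    # final likelihood under the last parameter update
    final_ll = log_likelihood(model, xys)
    trace.append(final_ll)
    return FitResult(
        model=model,
        log_likelihood=float(final_ll),
        loglik_trace=[float(v) for v in trace],
        n_iterations=n_iter,
        converged=converged,
        seed=seed,
        n_observations=n_obs,
    )


# ---------------------------------------------------------------------------
# model complexity and BIC
# ---------------------------------------------------------------------------

def n_free_parameters(n_states: int, covariance_kind: str = "diag") -> int:
    """Free parameters: (N-1) for pi, N(N-1) for A, 2N means, plus 2N diagonal
    variances (N^2 + 4N - 1) or 3N covariance entries (N^2 + 5N - 1)."""
    if n_states < 1:
        raise IntegrityError("n_states must be >= 1")
    n = n_states
    base = (n - 1) + n * (n - 1) + 2 * n
    if covariance_kind == "diag":
        return base + 2 * n
    if covariance_kind == "full":
        return base + 3 * n
    raise IntegrityError(f"unknown covariance_kind {covariance_kind!r}")


def bic(fit: FitResult, covariance_kind: str | None = None) -> float:
    """BIC = -2 logL + k ln(n), n = total fixations pooled over the fitted sequences."""
    kind = covariance_kind or fit.model.covariance_kind
    k = n_free_parameters(fit.model.n_states, kind)
    return -2.0 * fit.log_likelihood + k * math.log(fit.n_observations)
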