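"""Feature extraction and Bayesian-model-averaged LORETA source inversion.

Scalp features (window averages or component peak amplitudes) are inverted
onto the cortical generator grid under the Gaussian linear model

    v = K_M j + e,    e ~ N(0, beta^-1 I),
    j ~ N(0, (alpha * (L'L + eps I))^-1),

where K_M is the lead field restricted to a compartment subset M and L the
graph Laplacian of the generator neighbor graph on M applied blockwise to
the three moment components — the LORETA smoothness prior.  For each
candidate compartment subset the Gaussian log marginal likelihood (evidence)
is maximized over the hyperparameters (alpha, beta); posterior model
probabilities under a uniform model prior weight the per-model posterior-mean
solutions into a single Bayesian-model-averaged current-density map, after
pruning models that fall outside Occam's window.

The evidence and posterior mean are evaluated through the SVD of the
prior-whitened lead field, which depends only on the model and is therefore
precomputed once and reused across subjects and features.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import linalg as sla
from scipy.optimize import minimize
from scipy.sparse import csgraph, csr_matrix

from .headmodel import LeadField, SourceSpace
from .simulate import CONDITIONS, ErpSet

__all__ = [
    "FeatureVector",
    "WindowSpec",
    "PeakSpec",
    "CompartmentModel",
    "ModelPosterior",
    "ISMap",
    "extract_feature",
    "graph_laplacian",
    "loreta_solve",
    "log_evidence",
    "enumerate_models",
    "bma_solve",
    "BmaSourceModel",
    "BmaResults",
]

DEFAULT_OCCAM_WINDOW = 1.0 / 20.0
MODEL_COUNT_CAP = 1000


# ---------------------------------------------------------------------------
# Features
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class WindowSpec:
    """Window-average feature: per-channel mean voltage over [tmin, tmax] ms."""

    name: str
    tmin_ms: float
    tmax_ms: float
    conditions: tuple[str, ...] = CONDITIONS


@dataclass(frozen=True)
class PeakSpec:
    """Peak feature: find the extremum of the mean over ``channel_group``
    within the search window, then read all channels at that latency.

    ``polarity`` -1 looks for the most negative peak, +1 the most positive.
    """

    name: str
    polarity: int
    tmin_ms: float
    tmax_ms: float
    channel_group: tuple[str, ...] | None = None   # None = posterior sites
    conditions: tuple[str, ...] = CONDITIONS


@dataclass
class FeatureVector:
    """One voltage per channel for one subject/condition/component."""

    values: np.ndarray
    subject: int
    condition: str
    component: str
    definition: object = None
    peak_latency_ms: float | None = None


def _posterior_channels(names) -> list[int]:
    return [i for i, n in enumerate(names)
            if n.upper().startswith(("P", "PO", "O"))]


def extract_feature(erps: ErpSet, spec) -> list[FeatureVector]:
    """Extract per-subject, per-condition feature vectors from averaged ERPs.

    Window specs take the inclusive per-channel mean over the latency window.
    Peak specs search the channel-group mean for a local extremum of the
    required polarity inside the window; subjects without such an extremum
    are excluded with a warning.
    """
    t = erps.times_ms
    out = []
    if isinstance(spec, WindowSpec):
        win = (t >= spec.tmin_ms) & (t <= spec.tmax_ms)
        if not win.any():
            raise ValueError(f"window {spec.tmin_ms}-{spec.tmax_ms} ms outside epoch")
        for s in range(erps.n_subjects):
            for cond in spec.conditions:
                c = CONDITIONS.index(cond)
                out.append(FeatureVector(
                    values=erps.data[s, c][:, win].mean(axis=1),
                    subject=s, condition=cond, component=spec.name,
                    definition=spec))
        return out
    if isinstance(spec, PeakSpec):
        win = np.flatnonzero((t >= spec.tmin_ms) & (t <= spec.tmax_ms))
        if win.size < 3:
            raise ValueError("peak search window too narrow")
        if spec.channel_group is None:
            group = _posterior_channels(erps.channel_names)
        else:
            group = [erps.channel_names.index(n) for n in spec.channel_group]
        for s in range(erps.n_subjects):
            for cond in spec.conditions:
                c = CONDITIONS.index(cond)
                trace = spec.polarity * erps.data[s, c][group].mean(axis=0)[win]
                k = int(np.argmax(trace))
                interior = 0 < k < len(win) - 1
                if not interior:
                    warnings.warn(
                        f"{spec.name}: no interior {'positive' if spec.polarity > 0 else 'negative'} "
                        f"peak for subject {s}, condition {cond}; excluded",
                        stacklevel=2)
                    continue
                sample = win[k]
                out.append(FeatureVector(
                    values=erps.data[s, c][:, sample].copy(),
                    subject=s, condition=cond, component=spec.name,
                    definition=spec, peak_latency_ms=float(t[sample])))
        return out
    raise TypeError(f"unknown feature spec type {type(spec)!r}")


# ---------------------------------------------------------------------------
# Models and prior operators
# ---------------------------------------------------------------------------

@dataclass
class CompartmentModel:
    """LORETA inverse solution restricted to a subset of atlas compartments."""

    compartments: tuple[int, ...]
    generator_index: np.ndarray
    log_evidence: float | None = None
    alpha: float | None = None
    beta: float | None = None

    @property
    def n_generators(self) -> int:
        return len(self.generator_index)


@dataclass
class ModelPosterior:
    """Posterior model probabilities over retained compartment models."""

    models: list
    weights: np.ndarray

    def to_frame(self):
        """Tabular export: compartments, log_evidence, weight per model."""
        import pandas as pd

        return pd.DataFrame({
            "compartments": [" ".join(map(str, m.compartments))
                             for m in self.models],
            "log_evidence": [m.log_evidence for m in self.models],
            "weight": self.weights,
        }).sort_values("weight", ascending=False, ignore_index=True)

    def summary(self) -> str:
        rows = sorted(zip(self.models, self.weights),
                      key=lambda mw: -mw[1])
        lines = [f"{'compartments':<20}{'log evidence':>14}{'weight':>10}"]
        for m, w in rows:
            lines.append(f"{str(m.compartments):<20}{m.log_evidence:>14.2f}{w:>10.4f}")
        return "\n".join(lines)


@dataclass
class ISMap:
    """Voxelwise primary-current-density magnitudes (nA·m per voxel)."""

    magnitudes: np.ndarray
    vectors: np.ndarray | None = None      # (G, 3) averaged PCD
    subject: int | None = None
    condition: str | None = None
    component: str | None = None
    posterior: ModelPosterior | None = None


def graph_laplacian(space: SourceSpace, subset) -> csr_matrix:
    """Combinatorial Laplacian of the neighbor graph restricted to ``subset``.

    Returned per-generator (the 3 moment components share the operator via a
    Kronecker block structure); symmetric positive semi-definite, zero row
    sums.
    """
    idx = space.generators_in(np.atleast_1d(subset))
    if idx.size == 0:
        raise ValueError(f"compartment subset {subset} contains no generators")
    sub = space.neighbor_graph[np.ix_(idx, idx)]
    return csgraph.laplacian(sub).tocsr()


def enumerate_models(space: SourceSpace, max_size: int = 2,
                     cap: int = MODEL_COUNT_CAP) -> list[CompartmentModel]:
    """All nonempty compartment subsets of cardinality <= max_size.

    Deterministic order (increasing size, lexicographic).  Raises when the
    subset count exceeds ``cap``.
    """
    if max_size < 1:
        raise ValueError("max_size must be >= 1")
    labels = sorted(space.atlas)
    n = len(labels)
    count = sum(math.comb(n, k) for k in range(1, min(max_size, n) + 1))
    if count > cap:
        raise ValueError(
            f"{count} compartment subsets exceed the cap of {cap}; "
            "reduce max_size")
    models = []
    for k in range(1, min(max_size, n) + 1):
        for combo in itertools.combinations(labels, k):
            models.append(CompartmentModel(
                compartments=tuple(combo),
                generator_index=space.generators_in(list(combo))))
    return models


class _ModelOperator:
    """Per-model precomputation: whitened lead field SVD and prior factor.

    The prior precision on the stacked moment vector is
    ``alpha * (L (x) I3 + eps I)`` with eps the trace-normalized ridge jitter
    making the singular graph Laplacian invertible.  With P = R'R (Cholesky)
    and Ktilde = K R^-1 = U S V', both the evidence and the posterior mean
    are closed-form functions of (S, U'v) for any (alpha, beta).
    """

    def __init__(self, lf: LeadField, space: SourceSpace, model: CompartmentModel,
                 jitter: float = 1e-8):
        self.model = model
        K = lf.columns(model.generator_index)
        L = graph_laplacian(space, list(model.compartments))
        P1 = (L.T @ L).toarray()
        P = np.kron(P1, np.eye(3))
        eps = jitter * np.trace(P) / P.shape[0] if np.trace(P) > 0 else jitter
        P[np.diag_indices_from(P)] += eps
        self.R = sla.cholesky(P, lower=False)
        Kt = sla.solve_triangular(self.R, K.T, lower=False, trans="T").T
        U, s, Vt = sla.svd(Kt, full_matrices=False)
        self.U, self.s, self.Vt = U, s, Vt
        self.K = K
        self.n_channels = K.shape[0]

    def log_evidence(self, v: np.ndarray, alpha: float, beta: float) -> float:
        u = self.U.T @ v
        c = 1.0 / beta + self.s**2 / alpha
        quad = np.sum(u**2 / c) + (v @ v - u @ u) * beta
        logdet = np.sum(np.log(c)) + (self.n_channels - len(self.s)) * np.log(1.0 / beta)
        return -0.5 * (self.n_channels * np.log(2 * np.pi) + logdet + quad)

    def _evidence_from_projection(self, u2, vv, uu, alpha, beta):
        c = 1.0 / beta + self.s**2 / alpha
        quad = np.sum(u2 / c) + (vv - uu) * beta
        logdet = np.sum(np.log(c)) - (self.n_channels - len(self.s)) * np.log(beta)
        return -0.5 * (self.n_channels * np.log(2 * np.pi) + logdet + quad)

    def optimize(self, v: np.ndarray, grid_pts: int = 25):
        """Evidence maximization: coarse log-grid then Nelder-Mead refinement."""
        grid = np.linspace(-6.0, 6.0, grid_pts)
        u = self.U.T @ v
        u2 = u**2
        vv = v @ v
        uu = u @ u
        s2 = self.s**2
        # vectorized grid: axes (alpha, beta, singular value)
        alpha = 10.0 ** grid[:, None, None]
        beta = 10.0 ** grid[None, :, None]
        c = 1.0 / beta + s2[None, None, :] / alpha
        quad = np.sum(u2[None, None, :] / c, axis=2) + (vv - uu) * beta[..., 0]
        logdet = (np.sum(np.log(c), axis=2)
                  - (self.n_channels - len(s2)) * np.log(beta[..., 0]))
        le = -0.5 * (self.n_channels * np.log(2 * np.pi) + logdet + quad)
        ia, ib = np.unravel_index(np.argmax(le), le.shape)
        step = grid[1] - grid[0]
        # vectorized fine grid one coarse cell around the maximum
        fa = grid[ia] + np.linspace(-step, step, 17)[:, None, None]
        fb = grid[ib] + np.linspace(-step, step, 17)[None, :, None]
        c = 10.0 ** -fb + s2[None, None, :] / 10.0 ** fa
        quad = np.sum(u2[None, None, :] / c, axis=2) + (vv - uu) * 10.0 ** fb[..., 0]
        logdet = (np.sum(np.log(c), axis=2)
                  - (self.n_channels - len(s2)) * np.log(10.0 ** fb[..., 0]))
        lef = -0.5 * (self.n_channels * np.log(2 * np.pi) + logdet + quad)
        ja, jb = np.unravel_index(np.argmax(lef), lef.shape)
        res = minimize(
            lambda x: -self._evidence_from_projection(
                u2, vv, uu, 10.0 ** x[0], 10.0 ** x[1]),
            x0=np.array([fa[ja, 0, 0], fb[0, jb, 0]]), method="Nelder-Mead",
            options={"xatol": 1e-9, "fatol": 1e-12, "maxiter": 600})
        if not res.success:
            warnings.warn("evidence refinement did not fully converge; "
                          "using best value found", stacklevel=2)
        la, lb = res.x
        return 10.0**la, 10.0**lb, -res.fun

    def _apply_inverse(self, y: np.ndarray, alpha: float, beta: float):
        """A^{-1} y for A = beta K'K + alpha P, through the whitened SVD."""
        yt = sla.solve_triangular(self.R, y, lower=False, trans="T")
        z = self.Vt @ yt
        m_inv = yt / alpha + self.Vt.T @ (
            (1.0 / (beta * self.s**2 + alpha) - 1.0 / alpha) * z)
        return sla.solve_triangular(self.R, m_inv, lower=False)

    def posterior_mean(self, v: np.ndarray, alpha: float, beta: float):
        """Posterior-mean moment vector j (3 * n_gen,) and data residual.

        The whitened-SVD solve is followed by two steps of iterative
        refinement on the normal equations, which removes the amplification
        of rounding error by the ill-conditioned smoothness prior.
        """
        u = self.U.T @ v
        gain = beta * self.s / (beta * self.s**2 + alpha)
        w = self.Vt.T @ (gain * u)
        j = sla.solve_triangular(self.R, w, lower=False)
        b = beta * (self.K.T @ v)
        for _ in range(2):
            Rj = self.R @ j
            resid_ne = b - beta * (self.K.T @ (self.K @ j)) - alpha * (self.R.T @ Rj)
            j = j + self._apply_inverse(resid_ne, alpha, beta)
        return j, v - self.K @ j


def _operator(lf: LeadField, space: SourceSpace, model: CompartmentModel) -> _ModelOperator:
    return _ModelOperator(lf, space, model)


def loreta_solve(feature: FeatureVector, lf: LeadField, space: SourceSpace,
                 model: CompartmentModel, alpha: float, beta: float):
    """Posterior-mean LORETA solution for fixed hyperparameters.

    Returns ``(j, residual)`` where j is the stacked (3 * n_generators,)
    moment vector on the model's generators and residual = v - K j.
    """
    if alpha <= 0 or beta <= 0:
        raise ValueError("alpha and beta must be positive")
    op = _operator(lf, space, model)
    return op.posterior_mean(np.asarray(feature.values, float), alpha, beta)


def log_evidence(feature: FeatureVector, lf: LeadField, space: SourceSpace,
                 model: CompartmentModel) -> float:
    """Maximized Gaussian log marginal likelihood of a compartment model.

    Optimizes (alpha, beta) by evidence maximization and stores them with the
    achieved value on the model.
    """
    op = _operator(lf, space, model)
    alpha, beta, le = op.optimize(np.asarray(feature.values, float))
    model.alpha, model.beta, model.log_evidence = alpha, beta, le
    return le


def _bma_from_operators(v, operators, occam_window, n_generators):
    les = np.empty(len(operators))
    params = []
    for i, op in enumerate(operators):
        alpha, beta, le = op.optimize(v)
        op.model.alpha, op.model.beta, op.model.log_evidence = alpha, beta, le
        les[i] = le
        params.append((alpha, beta))
    shifted = les - les.max()            # rescale so weights never underflow
    w = np.exp(shifted)
    w /= w.sum()
    if occam_window > 0:
        keep = w / w.max() >= occam_window
    else:
        keep = np.ones_like(w, bool)
    w = np.where(keep, w, 0.0)
    w /= w.sum()

    vectors = np.zeros((n_generators, 3))
    for i, op in enumerate(operators):
        if w[i] == 0.0:
            continue
        j, _ = op.posterior_mean(v, *params[i])
        vectors[op.model.generator_index] += w[i] * j.reshape(-1, 3)
    posterior = ModelPosterior(
        models=[op.model for i, op in enumerate(operators) if w[i] > 0],
        weights=w[w > 0])
    return vectors, posterior


def bma_solve(feature: FeatureVector, lf: LeadField, space: SourceSpace,
              models: list, occam_window: float = DEFAULT_OCCAM_WINDOW):
    """Bayesian model averaging of LORETA solutions over compartment models.

    Posterior weights are proportional to exp(log evidence) under a uniform
    model prior; models whose posterior odds against the best fall below
    ``occam_window`` are pruned and the weights renormalized.  The averaged
    moment field is zero-padded outside each model's support; the ISMap
    magnitude is the per-voxel Euclidean norm of the averaged moment.
    """
    if not models:
        raise ValueError("need at least one compartment model")
    operators = [_operator(lf, space, m) for m in models]
    v = np.asarray(feature.values, float)
    vectors, posterior = _bma_from_operators(v, operators, occam_window,
                                             space.n_generators)
    ismap = ISMap(magnitudes=np.linalg.norm(vectors, axis=1), vectors=vectors,
                  subject=feature.subject, condition=feature.condition,
                  component=feature.component, posterior=posterior)
    return ismap, posterior


# ---------------------------------------------------------------------------
# Model / Results interface
# ---------------------------------------------------------------------------

class BmaSourceModel:
    """BMA-LORETA source reconstruction over a fixed compartment model space.

    Precomputes the per-model whitened-lead-field SVDs once, then inverts any
    number of feature vectors cheaply.
    """

    def __init__(self, lf: LeadField, space: SourceSpace, max_size: int = 2,
                 occam_window: float = DEFAULT_OCCAM_WINDOW,
                 models: list | None = None):
        self.lf = lf
        self.space = space
        self.occam_window = occam_window
        self.models = models if models is not None else enumerate_models(space, max_size)
        self._operators = [_ModelOperator(lf, space, m) for m in self.models]

    def invert(self, feature: FeatureVector) -> ISMap:
        v = np.asarray(feature.values, float)
        vectors, posterior = _bma_from_operators(
            v, self._operators, self.occam_window, self.space.n_generators)
        return ISMap(magnitudes=np.linalg.norm(vectors, axis=1),
                     vectors=vectors, subject=feature.subject,
                     condition=feature.condition, component=feature.component,
                     posterior=posterior)

    def fit(self, features) -> "BmaResults":
        if isinstance(features, FeatureVector):
            features = [features]
        return BmaResults(self, [self.invert(f) for f in features])


@dataclass
class BmaResults:
    """ISMaps and model posteriors for a batch of inverted features."""

    model: BmaSourceModel
    ismaps: list

    def summary(self) -> str:
        lines = [f"BMA-LORETA inversion: {len(self.model.models)} compartment "
                 f"models, Occam window {self.model.occam_window}",
                 f"{'subject':>8} {'condition':<16}{'component':<12}"
                 f"{'#models':>8}{'top model':>16}{'top w':>8}"]
        for m in self.ismaps:
            top = int(np.argmax(m.posterior.weights))
            lines.append(
                f"{str(m.subject):>8} {str(m.condition):<16}{str(m.component):<12}"
                f"{len(m.posterior.models):>8}"
                f"{str(m.posterior.models[top].compartments):>16}"
                f"{m.posterior.weights[top]:>8.3f}")
        return "\n".join(lines)
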