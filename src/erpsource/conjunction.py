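"""Second-level group analysis of source maps.

Individual current-density maps differ in scale across participants, so group
inference proceeds on binarized maps: a two-component Gaussian mixture fitted
to the log-magnitudes classifies every generator as null (non-active) or
alternative (active) through its local false discovery rate — the posterior
probability of the null component at the observed value.  Conjunction maps
are the per-voxel proportion of participants active; between-condition
contrasts subtract each participant's binary maps (values -1/0/1), average
with sign, and are thresholded by a paired sign-flip permutation test with
Benjamini-Hochberg FDR across voxels.  Per-compartment cluster tables
summarize suprathreshold voxels.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .headmodel import SourceSpace
from .inverse import ISMap

__all__ = [
    "BinaryMap",
    "ConjunctionMap",
    "DiffConjunctionMap",
    "binarize_lfdr",
    "conjunction",
    "diff_conjunction",
    "permutation_threshold",
    "cluster_table",
    "GroupConjunction",
    "GroupConjunctionResults",
]

DEFAULT_LFDR_THRESHOLD = 0.2
MIN_PERMUTATIONS = 100


@dataclass
class BinaryMap:
    """Active/inactive classification of one subject's source map."""

    active: np.ndarray                     # (G,) bool
    subject: int | None = None
    condition: str | None = None
    lfdr_threshold: float = DEFAULT_LFDR_THRESHOLD
    diagnostics: dict = field(default_factory=dict)


@dataclass
class ConjunctionMap:
    """Per-voxel proportion of participants active, in [0, 1]."""

    values: np.ndarray
    n_subjects: int
    condition: str | None = None
    component: str | None = None


@dataclass
class DiffConjunctionMap:
    """Signed between-condition conjunction with permutation p-values."""

    values: np.ndarray                     # (G,) in [-1, 1]
    n_subjects: int
    contrast: str | None = None
    p_values: np.ndarray | None = None
    mask: np.ndarray | None = None
    q: float | None = None
    #: tie-randomized p-values; exactly uniform under the null, used for
    #: calibration diagnostics (the conservative ``p_values`` drive inference)
    p_randomized: np.ndarray | None = None


def _em_two_gaussian(z: np.ndarray, max_iter: int = 2000, tol: float = 1e-9):
    """Two-component Gaussian mixture EM with deterministic quantile init.

    Initialization assumes a null-dominant mixture: means at the median and
    the 90th percentile, common spread, mixing 0.9/0.1.  Returns
    (pi, mu, sd, converged).
    """
    mu = np.array([np.quantile(z, 0.5), np.quantile(z, 0.9)])
    sd = np.array([z.std(), z.std()])
    sd = np.maximum(sd, 1e-8)
    pi = np.array([0.9, 0.1])
    ll_old = -np.inf
    converged = False
    for _ in range(max_iter):
        logpdf = (-0.5 * ((z[:, None] - mu) / sd) ** 2
                  - np.log(sd) - 0.5 * np.log(2 * np.pi) + np.log(pi))
        mx = logpdf.max(axis=1, keepdims=True)
        lse = mx[:, 0] + np.log(np.exp(logpdf - mx).sum(axis=1))
        resp = np.exp(logpdf - lse[:, None])
        ll = lse.mean()
        nk = resp.sum(axis=0)
        if np.any(nk < 1e-10):
            break
        pi = nk / len(z)
        mu = (resp * z[:, None]).sum(axis=0) / nk
        sd = np.sqrt((resp * (z[:, None] - mu) ** 2).sum(axis=0) / nk)
        sd = np.maximum(sd, 1e-6 * max(z.std(), 1e-12))
        if abs(ll - ll_old) < tol:
            converged = True
            break
        ll_old = ll
    return pi, mu, sd, converged


def binarize_lfdr(ismap, lfdr_threshold: float = DEFAULT_LFDR_THRESHOLD) -> BinaryMap:
    """Classify generators active/inactive by local FDR on log-magnitudes.

    Exact-zero magnitudes (voxels outside the averaged model support) are
    inactive by definition and excluded from the mixture fit.  The remaining
    log-magnitudes are standardized and fitted with a two-component Gaussian
    mixture (lower-mean component = null); a voxel is active when the
    posterior null probability at its value falls below ``lfdr_threshold``.
    The standardization makes the classification invariant to positive
    rescaling of the map.
    """
    if isinstance(ismap, ISMap):
        m = ismap.magnitudes
        subject, condition = ismap.subject, ismap.condition
    else:
        m = np.asarray(ismap, float)
        subject = condition = None
    if np.any(m < 0):
        raise ValueError("magnitudes must be nonnegative")
    if m.size < 50:
        raise ValueError("mixture fit needs at least 50 generators")
    active = np.zeros(m.size, dtype=bool)
    pos = m > 0
    diag = {"n_zero": int((~pos).sum())}
    if pos.sum() < 10:
        return BinaryMap(active=active, subject=subject, condition=condition,
                         lfdr_threshold=lfdr_threshold, diagnostics=diag)
    z = np.log(m[pos])
    spread = z.std()
    if spread < 1e-12:         # all positive magnitudes identical: no signal
        return BinaryMap(active=active, subject=subject, condition=condition,
                         lfdr_threshold=lfdr_threshold, diagnostics=diag)
    z = (z - z.mean()) / spread
    pi, mu, sd, converged = _em_two_gaussian(z)
    if not converged:
        warnings.warn("local-FDR mixture EM did not converge; map marked "
                      "all-inactive", stacklevel=2)
        return BinaryMap(active=active, subject=subject, condition=condition,
                         lfdr_threshold=lfdr_threshold, diagnostics=diag)
    null = int(np.argmin(mu))
    alt = 1 - null
    if pi[alt] < 1e-6:
        lfdr = np.ones_like(z)
    else:
        logpdf = (-0.5 * ((z[:, None] - mu) / sd) ** 2
                  - np.log(sd) + np.log(pi))
        mx = logpdf.max(axis=1, keepdims=True)
        tot = mx[:, 0] + np.log(np.exp(logpdf - mx).sum(axis=1))
        lfdr = np.exp(logpdf[:, null] - tot)
    active[pos] = lfdr < lfdr_threshold
    diag.update({"pi_null": float(pi[null]), "mu_null": float(mu[null]),
                 "sd_null": float(sd[null]), "mu_alt": float(mu[alt]),
                 "sd_alt": float(sd[alt])})
    return BinaryMap(active=active, subject=subject, condition=condition,
                     lfdr_threshold=lfdr_threshold, diagnostics=diag)


def conjunction(maps: list) -> ConjunctionMap:
    """Per-voxel proportion of participants with the voxel active."""
    if not maps:
        raise ValueError("need at least one binary map")
    arrs = [np.asarray(m.active if isinstance(m, BinaryMap) else m, bool)
            for m in maps]
    n = {a.shape for a in arrs}
    if len(n) != 1:
        raise ValueError(f"binary maps have inconsistent lengths: {n}")
    stack = np.array(arrs, dtype=float)
    first = maps[0]
    return ConjunctionMap(values=stack.mean(axis=0), n_subjects=len(maps),
                          condition=getattr(first, "condition", None))


def _pair_subjects(maps_a, maps_b):
    sa = [m.subject for m in maps_a]
    sb = [m.subject for m in maps_b]
    if sa != sb:
        raise ValueError(f"conditions are not paired by subject: {sa} vs {sb}")
    A = np.array([m.active for m in maps_a], dtype=float)
    B = np.array([m.active for m in maps_b], dtype=float)
    if A.shape != B.shape:
        raise ValueError("binary maps have inconsistent lengths")
    return A - B          # (S, G) in {-1, 0, 1}


def diff_conjunction(maps_a: list, maps_b: list,
                     contrast: str | None = None) -> DiffConjunctionMap:
    """Signed conjunction of per-subject binary-map differences.

    Per subject d = a - b in {-1, 0, 1} per voxel; the group value is the
    per-voxel mean of d (the proportion active in the subtraction maps,
    keeping the sign of the difference).
    """
    D = _pair_subjects(maps_a, maps_b)
    return DiffConjunctionMap(values=D.mean(axis=0), n_subjects=D.shape[0],
                              contrast=contrast)


def permutation_threshold(maps_a: list, maps_b: list, n_iter: int = 10000,
                          q: float = 0.05, seed: int = 0,
                          contrast: str | None = None) -> DiffConjunctionMap:
    """Paired sign-flip permutation test on the signed conjunction map.

    Under the null of equal conditions each subject's (a, b) pair is
    exchangeable, so the difference map's sign is flipped independently per
    subject; the per-voxel two-sided p-value is
    ``(1 + #{|perm| >= |observed|}) / (n_iter + 1)``, and voxels are selected
    by Benjamini-Hochberg FDR at level ``q``.
    """
    if n_iter < MIN_PERMUTATIONS:
        raise ValueError(f"n_iter must be >= {MIN_PERMUTATIONS}, got {n_iter}")
    D = _pair_subjects(maps_a, maps_b)
    S = D.shape[0]
    observed = D.mean(axis=0)
    rng = np.random.default_rng(seed)
    signs = rng.choice([-1.0, 1.0], size=(n_iter, S))
    perm = np.abs(signs @ D) / S                       # (n_iter, G)
    obs = np.abs(observed)[None, :]
    strict = (perm > obs).sum(axis=0)
    ties = (perm == obs).sum(axis=0)
    p = (1.0 + strict + ties) / (n_iter + 1.0)
    # tie-randomized companion: uniform under the null even though the
    # signed-conjunction statistic is discrete (calibration diagnostic only)
    p_rand = (strict + rng.random(D.shape[1]) * (1.0 + ties)) / (n_iter + 1.0)
    mask = multipletests(p, alpha=q, method="fdr_bh")[0]
    return DiffConjunctionMap(values=observed, n_subjects=S, contrast=contrast,
                              p_values=p, mask=mask, q=q, p_randomized=p_rand)


def cluster_table(cmap, space: SourceSpace, min_value: float = 0.5) -> pd.DataFrame:
    """Per-compartment summary of suprathreshold voxels.

    Voxels with ``|value| >= min_value`` (restricted to the FDR mask when the
    map carries one) are grouped by compartment: cluster size, mean |value|
    and SD, sorted by size descending.  For signed difference maps, positive
    and negative voxels are tabulated separately (``direction`` column).
    """
    if not 0.0 <= min_value <= 1.0:
        raise ValueError("min_value must be in [0, 1]")
    values = np.asarray(cmap.values, float)
    sel = np.abs(values) >= min_value
    mask = getattr(cmap, "mask", None)
    if mask is not None:
        sel &= mask
    signed = isinstance(cmap, DiffConjunctionMap)
    rows = []
    for direction, dsel in ((("+", sel & (values > 0)), ("-", sel & (values < 0)))
                            if signed else (("", sel),)):
        for label, name in space.atlas.items():
            vox = dsel & (space.compartment_labels == label)
            k = int(vox.sum())
            if k == 0:
                continue
            vals = np.abs(values[vox])
            sd = float(vals.std(ddof=1)) if k > 1 else 0.0
            rows.append({
                "compartment": name,
                **({"direction": direction} if signed else {}),
                "cluster_size": k,
                "mean_conjunction": float(vals.mean()),
                "sd_conjunction": sd if sd > 1e-12 else 0.0,
            })
    df = pd.DataFrame(rows)
    if len(df):
        df = df.sort_values("cluster_size", ascending=False, ignore_index=True)
    return df


# ---------------------------------------------------------------------------
# Model / Results interface
# ---------------------------------------------------------------------------

class GroupConjunction:
    """Second-level conjunction analysis of paired per-subject source maps.

    ``ismaps_a`` / ``ismaps_b`` are subject-ordered lists of ISMaps (or
    magnitude arrays) for the two compared conditions.  ``fit()`` binarizes
    each map by local FDR, forms the two plain conjunction maps, the signed
    difference conjunction with its permutation threshold, and cluster
    tables.
    """

    def __init__(self, ismaps_a: list, ismaps_b: list, space: SourceSpace,
                 lfdr_threshold: float = DEFAULT_LFDR_THRESHOLD,
                 n_iter: int = 10000, q: float = 0.05, seed: int = 0,
                 min_value: float = 0.5, contrast: str | None = None):
        self.ismaps_a = ismaps_a
        self.ismaps_b = ismaps_b
        self.space = space
        self.lfdr_threshold = lfdr_threshold
        self.n_iter = n_iter
        self.q = q
        self.seed = seed
        self.min_value = min_value
        self.contrast = contrast

    def fit(self) -> "GroupConjunctionResults":
        bin_a = [binarize_lfdr(m, self.lfdr_threshold) for m in self.ismaps_a]
        bin_b = [binarize_lfdr(m, self.lfdr_threshold) for m in self.ismaps_b]
        conj_a = conjunction(bin_a)
        conj_b = conjunction(bin_b)
        diff = permutation_threshold(bin_a, bin_b, n_iter=self.n_iter,
                                     q=self.q, seed=self.seed,
                                     contrast=self.contrast)
        tables = {
            "a": cluster_table(conj_a, self.space, self.min_value),
            "b": cluster_table(conj_b, self.space, self.min_value),
            "diff": cluster_table(diff, self.space, min_value=0.0),
        }
        return GroupConjunctionResults(self, bin_a, bin_b, conj_a, conj_b,
                                       diff, tables)


@dataclass
class GroupConjunctionResults:
    model: GroupConjunction
    binary_a: list
    binary_b: list
    conjunction_a: ConjunctionMap
    conjunction_b: ConjunctionMap
    difference: DiffConjunctionMap
    cluster_tables: dict

    def summary(self) -> str:
        d = self.difference
        lines = [
            f"Group conjunction ({d.n_subjects} subjects, "
            f"lfdr < {self.model.lfdr_threshold}, {self.model.n_iter} permutations, "
            f"FDR q = {self.model.q})",
            f"condition A: max conjunction {self.conjunction_a.values.max():.2f}",
            f"condition B: max conjunction {self.conjunction_b.values.max():.2f}",
            f"difference:  {int(d.mask.sum())} significant voxels, "
            f"min p = {d.p_values.min():.4g}",
            "",
            "difference cluster table:",
            self.cluster_tables["diff"].to_string(index=False)
            if len(self.cluster_tables["diff"]) else "  (empty)",
        ]
        return "\n".join(lines)
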