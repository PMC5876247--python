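"""Mass-univariate sensor-level statistics for 2x2 repeated-measures designs.

A two-way repeated-measures ANOVA (factors TASK and MATCH, two levels each)
is computed at every electrode and time point.  For a 2x2 within-subject
design each effect reduces to a paired contrast: with condition means
(intra-match, intra-mismatch, cross-match, cross-mismatch) and contrast
weights c, the effect F equals n * mean(c'y)^2 / var(c'y) on df (1, n-1) —
identically the square of the paired t statistic — so no sphericity
correction arises.  Multiplicity over electrodes x time is controlled with
Benjamini-Hochberg FDR; post hoc paired-t maps are computed only at points
significant for the corresponding main effect and FDR-corrected jointly
across the within-factor comparisons.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .simulate import CONDITIONS, ErpSet

__all__ = [
    "StatMap",
    "EFFECT_CONTRASTS",
    "rm_anova_2x2",
    "fdr_select",
    "posthoc_maps",
    "p_to_z",
    "dprime",
    "MassUnivariateAnova",
    "MassUnivariateAnovaResults",
]

#: Contrast weights over CONDITIONS for each ANOVA effect.
EFFECT_CONTRASTS = {
    "TASK": np.array([1.0, 1.0, -1.0, -1.0]) / 2.0,
    "MATCH": np.array([1.0, -1.0, 1.0, -1.0]) / 2.0,
    "TASK_x_MATCH": np.array([1.0, -1.0, -1.0, 1.0]) / 2.0,
}

#: Post hoc paired contrasts per main effect: within-factor simple effects.
POSTHOC_CONTRASTS = {
    "TASK": {
        "intra_vs_cross@match": np.array([1.0, 0.0, -1.0, 0.0]),
        "intra_vs_cross@mismatch": np.array([0.0, 1.0, 0.0, -1.0]),
    },
    "MATCH": {
        "match_vs_mismatch@intra": np.array([1.0, -1.0, 0.0, 0.0]),
        "match_vs_mismatch@cross": np.array([0.0, 0.0, 1.0, -1.0]),
    },
}


@dataclass
class StatMap:
    """Electrode x time statistical map with optional FDR mask."""

    values: np.ndarray               # statistic (F, t, or Z)
    p: np.ndarray
    kind: str                        # "F" | "t" | "Z"
    effect: str
    df: tuple
    channel_names: tuple[str, ...]
    times_ms: np.ndarray
    mask: np.ndarray | None = None
    q: float | None = None
    fdr_threshold: float | None = None

    @property
    def n_significant(self) -> int:
        return 0 if self.mask is None else int(self.mask.sum())

    def to_frame(self) -> pd.DataFrame:
        """Long-format export: electrode, time_ms, value, p, significant."""
        C, T = self.values.shape
        mask = self.mask if self.mask is not None else np.zeros_like(self.values, bool)
        return pd.DataFrame({
            "electrode": np.repeat(self.channel_names, T),
            "time_ms": np.tile(self.times_ms, C),
            "value": self.values.ravel(),
            "p": self.p.ravel(),
            "significant": mask.ravel(),
        })


def _contrast_stats(data: np.ndarray, weights: np.ndarray):
    """Per-point paired-contrast t and two-sided p over subjects.

    data: (n_subjects, 4, C, T); returns (t, p, mean, n).
    """
    n = data.shape[0]
    y = np.tensordot(weights, data, axes=(0, 1))  # (n, C, T)
    m = y.mean(axis=0)
    v = y.var(axis=0, ddof=1)
    degenerate = v <= np.finfo(float).tiny
    if np.any(degenerate):
        warnings.warn(
            f"{int(degenerate.sum())} electrode/time points have zero contrast "
            "variance; their p is set to 1", stacklevel=3)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(degenerate, 0.0, m / np.sqrt(v / n))
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 1)
    p = np.where(degenerate, 1.0, p)
    return t, p, m, n


def rm_anova_2x2(erps: ErpSet) -> dict[str, StatMap]:
    """Mass-univariate 2x2 repeated-measures ANOVA over electrodes x time.

    Returns F maps for TASK, MATCH and their interaction, each with
    df = (1, n-1).  Points with zero contrast variance get F = 0, p = 1.
    """
    data = np.asarray(erps.data, float)
    if data.ndim != 4 or data.shape[1] != len(CONDITIONS):
        raise ValueError("ErpSet must be subject x 4 conditions x channel x time")
    n = data.shape[0]
    if n < 3:
        raise ValueError(f"need at least 3 subjects, got {n}")
    out = {}
    for effect, w in EFFECT_CONTRASTS.items():
        t, p, _, _ = _contrast_stats(data, w)
        out[effect] = StatMap(values=t**2, p=p, kind="F", effect=effect,
                              df=(1, n - 1), channel_names=erps.channel_names,
                              times_ms=erps.times_ms)
    return out


def fdr_select(statmap: StatMap, q: float = 0.05) -> StatMap:
    """Benjamini-Hochberg step-up over all electrode x time p-values.

    Returns a copy with the rejection mask and the realized p threshold
    (largest rejected p; 0 when nothing is rejected).
    """
    if not 0.0 < q < 1.0:
        raise ValueError(f"q must be in (0, 1), got {q}")
    p = np.asarray(statmap.p, float)
    if p.size == 0:
        raise ValueError("empty p-value map")
    finite = np.isfinite(p)
    reject = np.zeros(p.shape, bool)
    reject[finite] = multipletests(p[finite].ravel(), alpha=q,
                                   method="fdr_bh")[0]
    thr = float(p[reject].max()) if reject.any() else 0.0
    return replace(statmap, mask=reject, q=q, fdr_threshold=thr)


def posthoc_maps(erps: ErpSet, anova_maps: dict[str, StatMap],
                 q: float = 0.05) -> list[StatMap]:
    """Post hoc paired-t maps at points significant for each main effect.

    For TASK: intra- vs cross-domain within each MATCH level; for MATCH:
    match vs mismatch within each task.  FDR is applied jointly across the
    two within-factor comparisons and all retained electrode x time points of
    that factor.
    """
    data = np.asarray(erps.data, float)
    n = data.shape[0]
    out = []
    for factor, contrasts in POSTHOC_CONTRASTS.items():
        amap = anova_maps.get(factor)
        sel = amap.mask if (amap is not None and amap.mask is not None) \
            else np.zeros(data.shape[2:], bool)
        maps, pooled_p = [], []
        for label, w in contrasts.items():
            t, p, _, _ = _contrast_stats(data, w)
            values = np.where(sel, t, np.nan)
            pmap = np.where(sel, p, np.nan)
            m = StatMap(values=values, p=pmap, kind="t", effect=label,
                        df=(n - 1,), channel_names=erps.channel_names,
                        times_ms=erps.times_ms, q=q)
            maps.append(m)
            pooled_p.append(pmap[sel])
        pooled = np.concatenate(pooled_p)
        if pooled.size:
            rej = multipletests(pooled, alpha=q, method="fdr_bh")[0]
            halves = np.split(rej, len(maps))
            for m, r in zip(maps, halves):
                mask = np.zeros(sel.shape, bool)
                mask[sel] = r
                m.mask = mask
                m.fdr_threshold = float(m.p[mask].max()) if mask.any() else 0.0
        else:
            for m in maps:
                m.mask = np.zeros(sel.shape, bool)
                m.fdr_threshold = 0.0
        out.extend(maps)
    return out


def p_to_z(statmap: StatMap, signed_by: StatMap | None = None,
           mode: str = "two_sided") -> StatMap:
    """Transform a p-map to standard-normal Z scores for display.

    ``mode="two_sided"`` (default) treats p as two-sided and returns the
    unsigned quantile Z = Phi^{-1}(1 - p/2); ``mode="one_sided"`` returns
    Z = Phi^{-1}(1 - p).  When ``signed_by`` is given (a t-map), its sign is
    copied onto Z.  p = 0 is clipped to the machine minimum with a warning;
    Z is clipped to +/-38 (the finite double range of the normal quantile).
    """
    p = np.asarray(statmap.p, float).copy()
    if np.any(p == 0.0):
        warnings.warn("p = 0 clipped to machine minimum", stacklevel=2)
        p[p == 0.0] = np.finfo(float).tiny
    if mode == "two_sided":
        z = stats.norm.isf(p / 2.0)
    elif mode == "one_sided":
        z = stats.norm.isf(p)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    z = np.clip(z, -38.0, 38.0)
    if signed_by is not None:
        z = z * np.sign(np.where(np.isnan(signed_by.values), 1.0,
                                 signed_by.values))
    return replace(statmap, values=z, kind="Z")


def dprime(p_hit: float, p_fa: float, log_base: float = 10.0) -> float:
    """Discrimination sensitivity d' = 0.6 log[(pH(1-pF)) / (pF(1-pH))].

    ``log_base`` selects the logarithm (default base 10); hit and
    false-alarm probabilities must lie strictly inside (0, 1) — callers must
    apply their own correction rule for boundary values.
    """
    if not (0.0 < p_hit < 1.0) or not (0.0 < p_fa < 1.0):
        raise ValueError(
            "p_hit and p_fa must be strictly inside (0, 1); apply a "
            "boundary-correction rule before calling dprime")
    ratio = (p_hit * (1.0 - p_fa)) / (p_fa * (1.0 - p_hit))
    return 0.6 * np.log(ratio) / np.log(log_base)


# ---------------------------------------------------------------------------
# Model / Results interface
# ---------------------------------------------------------------------------

class MassUnivariateAnova:
    """Mass-univariate 2x2 repeated-measures ANOVA model over an ErpSet.

    ``fit()`` computes the three effect F maps, applies FDR selection at
    level ``q`` and runs the FDR-corrected post hoc contrasts.
    """

    def __init__(self, erps: ErpSet, q: float = 0.05):
        self.erps = erps
        self.q = q

    def fit(self) -> "MassUnivariateAnovaResults":
        anova = {k: fdr_select(m, self.q) for k, m in rm_anova_2x2(self.erps).items()}
        posthoc = posthoc_maps(self.erps, anova, q=self.q)
        return MassUnivariateAnovaResults(self, anova, posthoc)


@dataclass
class MassUnivariateAnovaResults:
    """F maps with FDR masks, post hoc t maps, and Z transforms."""

    model: MassUnivariateAnova
    anova: dict[str, StatMap]
    posthoc: list[StatMap]

    def z_map(self, effect: str) -> StatMap:
        return p_to_z(self.anova[effect])

    def summary(self) -> str:
        lines = ["Mass-univariate 2x2 repeated-measures ANOVA",
                 f"subjects: {self.model.erps.n_subjects}, "
                 f"points: {self.anova['TASK'].values.size}, "
                 f"FDR q = {self.model.q}", ""]
        lines.append(f"{'effect':<26}{'df':<10}{'max F':>8}{'min p':>12}"
                     f"{'# sig':>8}{'p_thr':>10}")
        for name, m in self.anova.items():
            lines.append(f"{name:<26}{str(m.df):<10}{np.nanmax(m.values):>8.2f}"
                         f"{np.nanmin(m.p):>12.2e}{m.n_significant:>8d}"
                         f"{(m.fdr_threshold or 0):>10.2e}")
        lines.append("")
        lines.append("post hoc (paired t at significant main-effect points):")
        for m in self.posthoc:
            mx = np.nanmax(np.abs(m.values)) if np.any(np.isfinite(m.values)) else 0.0
            lines.append(f"  {m.effect:<28}{'max |t|':>8} {mx:>6.2f}"
                         f"   # sig {m.n_significant}")
        return "\n".join(lines)

    def plot(self, effect: str = "MATCH", ax=None):  # pragma: no cover - viz
        """Heatmap of the signed/unsigned Z map with the FDR mask outline."""
        import matplotlib.pyplot as plt

        z = self.z_map(effect)
        if ax is None:
            _, ax = plt.subplots(figsize=(8, 4))
        masked = np.where(z.mask if z.mask is not None else True, z.values, np.nan)
        im = ax.imshow(masked, aspect="auto", origin="lower",
                       extent=[z.times_ms[0], z.times_ms[-1], 0,
                               len(z.channel_names)], cmap="magma")
        ax.set_xlabel("time (ms)")
        ax.set_ylabel("electrode")
        ax.set_title(f"{effect}: |Z| at FDR q = {z.q}")
        plt.colorbar(im, ax=ax, label="Z")
        return ax
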