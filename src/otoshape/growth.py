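"""Von Bertalanffy growth curve (Francis parameterization) and the growth
rate index G.

The Francis (1988) re-parameterization expresses the von Bertalanffy curve
through the expected lengths L1, L2, L3 at three anchor ages t1 < t2 < t3
with t2 midway between t1 and t3:

    E[L | t] = L1 + (L3 - L1) * (1 - r^(2 (t - t1) / (t3 - t1))) / (1 - r^2)
    r = (L3 - L2) / (L2 - L1)

Anchoring the parameters at observable ages makes them directly comparable
across samples and keeps the least-squares problem well conditioned.  The
per-fish growth rate index G is the residual of observed length from the
fitted curve at the fish's age (cm): positive G marks a fish larger than
expected for its age, and the index is comparable across age groups by
construction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

_R_ONE_TOL = 1e-8


@dataclass
class VBGFParams:
    """Expected lengths (cm) at the three anchor ages (years)."""

    L1: float
    L2: float
    L3: float
    t1: float = 6.0
    t2: float = 10.0
    t3: float = 14.0

    def __post_init__(self) -> None:
        if not np.isclose(self.t2, 0.5 * (self.t1 + self.t3)):
            raise ValueError("t2 must be midway between t1 and t3")
        if not self.t1 < self.t2 < self.t3:
            raise ValueError("anchor ages must be strictly increasing")

    @property
    def r(self) -> float:
        denom = self.L2 - self.L1
        if denom == 0:
            raise ValueError("degenerate parameters: L1 == L2")
        return (self.L3 - self.L2) / denom


@dataclass
class VBGFFit:
    params: VBGFParams
    rss: float
    n: int
    iterations: int
    converged: bool
    residuals: np.ndarray = field(repr=False)
    warnings: list[str] = field(default_factory=list)

    def summary(self) -> pd.DataFrame:
        p = self.params
        return pd.DataFrame({
            "L1": [p.L1], "L2": [p.L2], "L3": [p.L3],
            "t1": [p.t1], "t2": [p.t2], "t3": [p.t3],
            "r": [p.r], "rss": [self.rss], "n": [self.n],
            "converged": [self.converged],
        })


@dataclass
class GrowthIndex:
    """Per-fish residual from the fitted growth curve (cm)."""

    G: pd.Series
    extrapolated: pd.Series      # ages outside the fitted support


def vbgf_predict(params: VBGFParams, age) -> np.ndarray | float:
    """Expected length at ``age`` under the Francis form.

    The ``r -> 1`` degeneracy (uniform growth over the anchor span) is
    handled by its analytic limit, linear interpolation through the anchors.
    """
    age = np.asarray(age, dtype=float)
    p = params
    r = p.r
    tau = (age - p.t1) / (p.t3 - p.t1)
    if abs(r - 1.0) < _R_ONE_TOL:
        out = p.L1 + (p.L3 - p.L1) * tau
    else:
        # sign(r) |r|^(2 tau) == r^(2 tau) for r > 0 and keeps intermediate
        # optimizer iterates with r < 0 finite; such optima are flagged later
        rp = np.sign(r) * np.abs(r) ** (2.0 * tau)
        out = p.L1 + (p.L3 - p.L1) * (1.0 - rp) / (1.0 - r * r)
    return float(out) if out.ndim == 0 else out


def fit_vbgf(ages, lengths, anchor_ages: tuple[float, float, float] = (6.0, 10.0, 14.0)
             ) -> VBGFFit:
    """Nonlinear least-squares fit of (L1, L2, L3) to length-at-age data.

    Initialization is a small multistart around the empirical mean lengths at
    (or nearest to) the anchor ages; the best of the converged runs by
    residual sum of squares is kept.  A non-monotone optimum (r <= 0) is
    retained but flagged with a warning, mirroring how a practitioner would
    inspect a pathological fit rather than have it silently discarded.
    """
    ages = np.asarray(ages, float)
    lengths = np.asarray(lengths, float)
    if ages.shape != lengths.shape or ages.ndim != 1:
        raise ValueError("ages and lengths must be equal-length 1-D arrays")
    if len(np.unique(ages)) < 3:
        raise ValueError("need at least 3 distinct ages to fit three anchors")
    t1, t2, t3 = map(float, anchor_ages)
    if not np.isclose(t2, 0.5 * (t1 + t3)):
        raise ValueError("anchor ages must satisfy t2 = (t1 + t3) / 2")

    def nearest_mean(t0: float) -> float:
        d = np.abs(ages - t0)
        sel = d <= d.min() + 0.5
        return float(lengths[sel].mean())

    base = np.array([nearest_mean(t1), nearest_mean(t2), nearest_mean(t3)])
    # keep strictly increasing start
    for j in (1, 2):
        if base[j] <= base[j - 1]:
            base[j] = base[j - 1] + max(1.0, 0.05 * abs(base[j - 1]))

    def residual(theta: np.ndarray) -> np.ndarray:
        p = VBGFParams(*theta, t1=t1, t2=t2, t3=t3)
        return vbgf_predict(p, ages) - lengths

    starts = [base, base * np.array([0.9, 1.0, 1.1]),
              base * np.array([1.1, 1.0, 0.95])]
    best = None
    for x0 in starts:
        try:
            sol = least_squares(residual, x0, method="lm", xtol=1e-12,
                                ftol=1e-12, gtol=1e-12, max_nfev=5000)
        except Exception:
            continue
        rss = float((sol.fun ** 2).sum())
        if best is None or rss < best[0]:
            best = (rss, sol)
    if best is None:
        raise RuntimeError("growth-curve optimization failed from all starts")
    rss, sol = best
    params = VBGFParams(*sol.x, t1=t1, t2=t2, t3=t3)
    notes: list[str] = []
    try:
        r = params.r
        if r <= 0:
            notes.append(f"non-monotone optimum: r = {r:.4f} <= 0")
            warnings.warn(notes[-1])
    except ValueError:
        notes.append("degenerate optimum: L1 == L2")
        warnings.warn(notes[-1])
    return VBGFFit(params=params, rss=rss, n=len(ages), iterations=int(sol.nfev),
                   converged=bool(sol.success), residuals=-sol.fun,
                   warnings=notes)


def growth_index(fit: VBGFFit, fish: pd.DataFrame,
                 age_col: str = "age", length_col: str = "length",
                 age_support: tuple[float, float] | None = None) -> GrowthIndex:
    """G_i = observed length - predicted length at the fish's age."""
    pred = vbgf_predict(fit.params, fish[age_col].to_numpy(float))
    g = pd.Series(fish[length_col].to_numpy(float) - pred, index=fish.index,
                  name="G")
    if age_support is None:
        age_support = (fit.params.t1, fit.params.t3)
    lo, hi = age_support
    extrap = pd.Series(~fish[age_col].between(lo, hi), index=fish.index,
                       name="extrapolated")
    if extrap.any():
        warnings.warn(f"{int(extrap.sum())} fish have ages outside "
                      f"[{lo}, {hi}]; their G is extrapolated")
    return GrowthIndex(G=g, extrapolated=extrap)
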