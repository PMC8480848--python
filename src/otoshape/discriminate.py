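"""Stepwise discriminant analysis of genotype groups from shape descriptors.

The selection criterion is Wilks' lambda, the ratio of the within-group to
the total generalized variance on the current feature set; small values mean
well-separated groups.  At each step the candidate feature with the largest
partial F enters if it clears ``F_enter``, and any previously entered feature
whose partial F has dropped below ``F_remove`` leaves again — the classic
stepwise-DFA loop.  Classification uses the shared-covariance Gaussian model
with priors proportional to group sizes, and accuracy is estimated by
leave-one-out cross-validation (model refitted without the held-out fish;
feature selection either fixed from the full sample — the default, matching
how stepwise DFA is conventionally run — or re-run inside every fold).

Heterozygous (AB) fish, excluded from a two-group AA-vs-BB model, can be
scored on its discriminant axis and assigned to whichever homozygote shape
they resemble most.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg


@dataclass
class StepwiseResult:
    selected: list[str]
    steps: pd.DataFrame        # entry/removal log: step, action, feature, F, wilks


@dataclass
class DiscriminantModel:
    features: list[str]
    classes: np.ndarray
    priors: np.ndarray
    means: np.ndarray                      # (g, p) group means
    pooled_cov: np.ndarray                 # (p, p) within-group covariance
    axes: np.ndarray                       # (p, n_axes) canonical coefficients
    axis_eigvals: np.ndarray
    selection: StepwiseResult | None = None

    def _log_likelihoods(self, X: np.ndarray) -> np.ndarray:
        prec = np.linalg.pinv(self.pooled_cov)
        ll = np.empty((X.shape[0], len(self.classes)))
        for g, mu in enumerate(self.means):
            d = X - mu
            ll[:, g] = -0.5 * np.einsum("ij,jk,ik->i", d, prec, d) \
                + np.log(self.priors[g])
        return ll

    def posteriors(self, X) -> np.ndarray:
        ll = self._log_likelihoods(np.asarray(X, float))
        ll -= ll.max(axis=1, keepdims=True)
        p = np.exp(ll)
        return p / p.sum(axis=1, keepdims=True)

    def predict(self, X) -> np.ndarray:
        return self.classes[np.argmax(self._log_likelihoods(
            np.asarray(X, float)), axis=1)]

    def scores(self, X) -> np.ndarray:
        """Canonical discriminant scores (centered at the grand mean)."""
        X = np.asarray(X, float)
        grand = (self.priors[:, None] * self.means).sum(axis=0)
        return (X - grand) @ self.axes


@dataclass
class ClassificationResult:
    confusion: pd.DataFrame                 # true x predicted counts
    per_group_pct: pd.Series
    overall_pct: float
    posteriors: pd.DataFrame
    scores: pd.DataFrame
    features: list[str]


@dataclass
class AbAssignment:
    assigned: pd.Series                     # per-AB-fish label
    posterior: pd.DataFrame
    scores: pd.Series
    summary_pct: pd.Series                  # % assigned to each homozygote

    def __post_init__(self) -> None:
        assert abs(self.summary_pct.sum() - 100.0) < 1e-9


def _as_frame(X) -> pd.DataFrame:
    if isinstance(X, pd.DataFrame):
        return X
    X = np.asarray(X, float)
    return pd.DataFrame(X, columns=[f"x{j}" for j in range(X.shape[1])])


def _scatter(X: np.ndarray, groups: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Within-group (W) and total (T) SSCP matrices."""
    Xc = X - X.mean(axis=0)
    T = Xc.T @ Xc
    W = np.zeros_like(T)
    for g in np.unique(groups):
        Xg = X[groups == g]
        d = Xg - Xg.mean(axis=0)
        W += d.T @ d
    return W, T


def wilks_lambda(X, groups) -> float:
    """det(W) / det(T) on the given feature set; 1 means no separation."""
    X = np.asarray(X, float)
    if X.ndim == 1:
        X = X[:, None]
    W, T = _scatter(X, np.asarray(groups))
    sw, ldw = np.linalg.slogdet(W)
    st, ldt = np.linalg.slogdet(T)
    if sw <= 0 or st <= 0:
        return np.nan
    return float(np.exp(ldw - ldt))


def _partial_f(lam_small: float, lam_big: float, n: int, g: int, p: int) -> float:
    """Partial F for the feature whose addition took lambda from
    ``lam_small``-feature-set value to ``lam_big`` (p features already in
    before the addition)."""
    if not np.isfinite(lam_big) or lam_big <= 0:
        return np.nan
    return (lam_small / lam_big - 1.0) * (n - g - p) / (g - 1)


def stepwise_select(X, groups, F_enter: float = 3.84, F_remove: float = 2.71,
                    max_steps: int = 200) -> StepwiseResult:
    """Greedy Wilks'-lambda stepwise feature selection.

    Deterministic: ties in partial F are broken by column order.  Features
    producing a singular pooled covariance (lambda undefined) are skipped
    with a warning at that step.
    """
    Xf = _as_frame(X)
    groups = np.asarray(groups)
    classes, counts = np.unique(groups, return_counts=True)
    if len(classes) < 2 or counts.min() < 2:
        raise ValueError("need >= 2 groups with >= 2 members each")
    if (Xf.std(axis=0) == 0).any():
        bad = list(Xf.columns[Xf.std(axis=0) == 0])
        raise ValueError(f"constant columns not allowed: {bad}")
    n, g = len(groups), len(classes)
    cols = list(Xf.columns)
    Xv = Xf.to_numpy(float)
    selected: list[int] = []
    log_rows = []
    lam_cur = 1.0
    for step in range(max_steps):
        changed = False
        # --- entry ---
        best = None
        p = len(selected)
        for j, name in enumerate(cols):
            if j in selected:
                continue
            lam = wilks_lambda(Xv[:, selected + [j]], groups)
            if not np.isfinite(lam):
                warnings.warn(f"feature {name!r} skipped: singular scatter")
                continue
            F = _partial_f(lam_cur, lam, n, g, p)
            if np.isfinite(F) and F >= F_enter:
                if best is None or F > best[0] + 1e-12:
                    best = (F, j, lam)
        if best is not None:
            F, j, lam = best
            selected.append(j)
            lam_cur = lam
            log_rows.append((len(log_rows) + 1, "enter", cols[j], F, lam))
            changed = True
        # --- removal ---
        while len(selected) > 1:
            worst = None
            p = len(selected)
            for j in selected:
                rest = [k for k in selected if k != j]
                lam_wo = wilks_lambda(Xv[:, rest], groups)
                if not np.isfinite(lam_wo):
                    continue
                F = _partial_f(lam_wo, lam_cur, n, g, p - 1)
                if worst is None or F < worst[0] - 1e-12:
                    worst = (F, j, lam_wo)
            if worst is None or not np.isfinite(worst[0]) or worst[0] >= F_remove:
                break
            F, j, lam_wo = worst
            # never remove the feature that just entered (would loop)
            if log_rows and log_rows[-1][1] == "enter" and cols[j] == log_rows[-1][2]:
                break
            selected.remove(j)
            lam_cur = lam_wo
            log_rows.append((len(log_rows) + 1, "remove", cols[j], F, lam_wo))
            changed = True
        if not changed:
            break
    steps = pd.DataFrame(log_rows,
                         columns=["step", "action", "feature", "F", "wilks"])
    return StepwiseResult(selected=[cols[j] for j in selected], steps=steps)


def fit_lda(X, groups, priors: np.ndarray | None = None,
            selection: StepwiseResult | None = None) -> DiscriminantModel:
    """Canonical LDA with shared covariance and group-size priors.

    Axes solve the between/within generalized eigenproblem; at most
    ``n_groups - 1`` axes are retained.
    """
    Xf = _as_frame(X)
    groups = np.asarray(groups)
    classes, counts = np.unique(groups, return_counts=True)
    n, p, g = len(groups), Xf.shape[1], len(classes)
    if p == 0:
        raise ValueError("no features selected")
    if priors is None:
        priors = counts / n
    priors = np.asarray(priors, float)
    Xv = Xf.to_numpy(float)
    means = np.vstack([Xv[groups == c].mean(axis=0) for c in classes])
    W, _ = _scatter(Xv, groups)
    if n - g < p:
        raise ValueError("too few observations for the pooled covariance; "
                         "reduce the feature set")
    Sw = W / (n - g)
    grand = (counts[:, None] * means).sum(axis=0) / n
    Mb = means - grand
    Sb = (counts[:, None] * Mb).T @ Mb / (n - g)
    try:
        evals, evecs = linalg.eigh(Sb, Sw)
    except linalg.LinAlgError as err:
        raise ValueError("within-group covariance is singular; reduce the "
                         "feature set") from err
    order = np.argsort(evals)[::-1]
    n_axes = min(g - 1, p)
    axes = evecs[:, order[:n_axes]]
    # deterministic sign: largest-magnitude loading positive
    for k in range(axes.shape[1]):
        j = int(np.argmax(np.abs(axes[:, k])))
        if axes[j, k] < 0:
            axes[:, k] = -axes[:, k]
    return DiscriminantModel(features=list(Xf.columns), classes=classes,
                             priors=priors, means=means, pooled_cov=Sw,
                             axes=axes, axis_eigvals=evals[order[:n_axes]],
                             selection=selection)


def loo_classify(X, groups, selection_mode: str = "fixed",
                 F_enter: float = 3.84, F_remove: float = 2.71,
                 features: list[str] | None = None) -> ClassificationResult:
    """Leave-one-out cross-validated classification.

    ``selection_mode='fixed'`` runs the stepwise selection once on the full
    sample and refits only the discriminant inside each fold (conventional
    stepwise-DFA reporting); ``'nested'`` re-runs the selection inside every
    fold (honest error estimate); ``'none'`` uses all columns (or
    ``features``).
    """
    Xf = _as_frame(X)
    groups = np.asarray(groups)
    classes, counts = np.unique(groups, return_counts=True)
    n = len(groups)
    if n < len(classes) + 2:
        raise ValueError("too few observations for leave-one-out")
    if selection_mode == "fixed":
        sel = stepwise_select(Xf, groups, F_enter, F_remove)
        if not sel.selected:
            raise ValueError("stepwise selection chose no features")
        feats = sel.selected
    elif selection_mode == "none":
        feats = features if features is not None else list(Xf.columns)
        sel = None
    elif selection_mode == "nested":
        feats = None
        sel = None
    else:
        raise ValueError("selection_mode must be 'fixed', 'nested' or 'none'")

    singletons = set(classes[counts == 1])
    if singletons:
        warnings.warn(f"groups of size 1 skipped in LOO: {sorted(singletons)}")

    idx = Xf.index
    pred = pd.Series(index=idx, dtype=object)
    post = pd.DataFrame(np.nan, index=idx, columns=classes)
    n_axes = len(classes) - 1
    scores = pd.DataFrame(np.nan, index=idx,
                          columns=[f"LD{k + 1}" for k in range(n_axes)])
    mask_all = np.ones(n, bool)
    for i in range(n):
        if groups[i] in singletons:
            continue
        mask = mask_all.copy()
        mask[i] = False
        Xtr, gtr = Xf.iloc[mask], groups[mask]
        if selection_mode == "nested":
            fold_sel = stepwise_select(Xtr, gtr, F_enter, F_remove)
            fold_feats = fold_sel.selected or list(Xf.columns)
        else:
            fold_feats = feats
        model = fit_lda(Xtr[fold_feats], gtr)
        xi = Xf.iloc[[i]][fold_feats]
        pred.iloc[i] = model.predict(xi)[0]
        po = model.posteriors(xi)[0]
        post.loc[idx[i], model.classes] = po
        sc = model.scores(xi)[0]
        scores.iloc[i, :sc.shape[0]] = sc

    keep = pred.notna()
    confusion = pd.crosstab(pd.Series(groups, index=idx)[keep], pred[keep],
                            rownames=["true"], colnames=["predicted"])
    confusion = confusion.reindex(index=classes, columns=classes, fill_value=0)
    correct = np.array([confusion.loc[c, c] for c in classes], float)
    sizes = confusion.sum(axis=1).to_numpy(float)
    with np.errstate(invalid="ignore"):
        per_group = pd.Series(100.0 * correct / np.where(sizes > 0, sizes, np.nan),
                              index=classes, name="pct_correct")
    overall = 100.0 * correct.sum() / sizes.sum()
    return ClassificationResult(confusion=confusion, per_group_pct=per_group,
                                overall_pct=float(overall), posteriors=post,
                                scores=scores, features=feats or [])


def resubstitution_accuracy(X, groups, features: list[str] | None = None) -> float:
    Xf = _as_frame(X)
    if features is not None:
        Xf = Xf[features]
    groups = np.asarray(groups)
    model = fit_lda(Xf, groups)
    return float(100.0 * (model.predict(Xf) == groups).mean())


def assign_heterozygotes(model: DiscriminantModel, X_ab) -> AbAssignment:
    """Score AB fish on the AA-vs-BB axis and assign by maximum posterior."""
    Xf = _as_frame(X_ab)
    if len(Xf) == 0:
        raise ValueError("no heterozygote fish to assign")
    missing = [f for f in model.features if f not in Xf.columns]
    if missing:
        raise ValueError(f"descriptor columns missing from AB data: {missing}")
    if len(model.classes) != 2:
        raise ValueError("heterozygote assignment needs a two-group model")
    Xs = Xf[model.features]
    post = pd.DataFrame(model.posteriors(Xs), index=Xf.index,
                        columns=model.classes)
    assigned = pd.Series(model.predict(Xs), index=Xf.index, name="assigned")
    scores = pd.Series(model.scores(Xs)[:, 0], index=Xf.index, name="LD1")
    counts = assigned.value_counts().reindex(model.classes, fill_value=0)
    summary = 100.0 * counts / counts.sum()
    return AbAssignment(assigned=assigned, posterior=post, scores=scores,
                        summary_pct=summary)
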