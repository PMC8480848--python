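"""Inferential statistics for the growth/shape/genotype analysis.

Contains the genotype-proportion chi-squared tests, the per-descriptor linear
model significance scans, an unbalanced-design Type III ANOVA, and Tukey HSD
post-hoc comparisons with compact letter displays.

Type III sums of squares are computed literally as their definition: the
increase in residual sum of squares when a term's columns are removed from
the otherwise full design, with every categorical factor coded by
sum-to-zero contrasts so main effects are evaluated at the unweighted level
average.  Unbalanced and missing-cell designs are supported; a term whose
columns add no rank to the design (empty cells making it inestimable) is
flagged as aliased and carries no F or p.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats


# --------------------------------------------------------------------------
# design-matrix utilities (sum-to-zero contrasts)

def sum_contrasts(levels: list) -> dict:
    """Map each (sorted) level to its sum-to-zero contrast row (k-1 columns)."""
    levels = sorted(levels)
    k = len(levels)
    rows = {}
    for i, lev in enumerate(levels):
        if i < k - 1:
            v = np.zeros(k - 1)
            v[i] = 1.0
        else:
            v = -np.ones(k - 1)
        rows[lev] = v
    return rows


def _encode_factor(values: np.ndarray) -> np.ndarray:
    contrasts = sum_contrasts(list(pd.unique(values)))
    return np.vstack([contrasts[v] for v in values])


def term_columns(data: pd.DataFrame, term: str,
                 categorical: set[str]) -> np.ndarray:
    """Design columns for a term like ``'location'`` or ``'G:cohort'``.

    Interaction columns are element-wise products of the component blocks.
    Numeric variables contribute a single column of their values.
    """
    blocks = []
    for var in term.split(":"):
        col = data[var].to_numpy()
        if var in categorical:
            blocks.append(_encode_factor(col))
        else:
            blocks.append(col.astype(float)[:, None])
    out = blocks[0]
    for b in blocks[1:]:
        out = (out[:, :, None] * b[:, None, :]).reshape(len(data), -1)
    return out


def _rss(X: np.ndarray, Y: np.ndarray) -> np.ndarray:
    """Residual sum of squares per response column (Y may be 1-D or 2-D)."""
    beta = np.linalg.lstsq(X, Y, rcond=None)[0]
    resid = Y - X @ beta
    return (resid ** 2).sum(axis=0)


def _sweep_select(columns: list[np.ndarray], rtol: float = 1e-8) -> list[np.ndarray]:
    """Greedy rank-preserving column selection in the given order.

    Mirrors the sweep-based pivoting of the classical ANOVA packages: a
    column linearly dependent on the columns already accepted is dropped, so
    with terms ordered intercept, main effects, interactions, empty-cell
    redundancy is charged to the interactions and main effects stay
    testable.  Returns, per input column, a boolean keep flag.
    """
    kept: list[bool] = []
    Q: list[np.ndarray] = []
    for c in columns:
        r = c.astype(float)
        norm0 = np.linalg.norm(r)
        for q in Q:
            r = r - (q @ r) * q
        # re-orthogonalize once for numerical safety
        for q in Q:
            r = r - (q @ r) * q
        norm = np.linalg.norm(r)
        if norm0 > 0 and norm > rtol * norm0:
            Q.append(r / norm)
            kept.append(True)
        else:
            kept.append(False)
    return kept


def _contains(big: str, small: str) -> bool:
    return big != small and set(small.split(":")) < set(big.split(":"))


# --------------------------------------------------------------------------
# chi-squared tests of genotype proportions

@dataclass
class ContingencyTable:
    counts: pd.DataFrame

    def __post_init__(self) -> None:
        c = self.counts.to_numpy()
        if (c < 0).any() or not np.allclose(c, np.round(c)):
            raise ValueError("counts must be non-negative integers")
        if self.counts.shape[0] < 2 or self.counts.shape[1] < 2:
            raise ValueError("need at least a 2 x 2 table")


def proportion_chisq(table: ContingencyTable | pd.DataFrame
                     ) -> tuple[float, int, float]:
    """Pearson chi-squared test of independence (no continuity correction).

    Zero rows/columns are dropped with a warning; a warning is also issued
    when any expected count falls below 5.
    """
    counts = table.counts if isinstance(table, ContingencyTable) else table
    c = counts.to_numpy(float)
    keep_r = c.sum(axis=1) > 0
    keep_c = c.sum(axis=0) > 0
    if not keep_r.all() or not keep_c.all():
        warnings.warn("dropping empty rows/columns from the contingency table")
        c = c[keep_r][:, keep_c]
    if c.shape[0] < 2 or c.shape[1] < 2:
        raise ValueError("table degenerate after dropping empty rows/columns")
    stat, p, dof, expected = stats.chi2_contingency(c, correction=False)
    if (expected < 5).any():
        warnings.warn("some expected counts are below 5; chi-squared "
                      "approximation may be poor")
    return float(stat), int(dof), float(p)


# --------------------------------------------------------------------------
# Type III ANOVA

@dataclass
class AnovaTable:
    table: pd.DataFrame        # index: terms + Error + Corrected Total
    aliased: list[str] = field(default_factory=list)

    def significant(self, term: str, alpha: float = 0.05) -> bool:
        return bool(self.table.loc[term, "p"] < alpha)


def _build_terms(factors: list[str], two_way_interactions) -> list[str]:
    terms = list(factors)
    if two_way_interactions is True:
        terms += [f"{a}:{b}" for a, b in itertools.combinations(factors, 2)]
    elif two_way_interactions:
        terms += list(two_way_interactions)
    return terms


def linear_model_terms(data: pd.DataFrame, response: str, terms: list[str],
                       categorical: set[str]) -> AnovaTable:
    """Type III F-tests for each term in a linear model.

    SS(term) is the increase in residual sum of squares when the term's
    sum-coded columns are removed from the otherwise full design (the
    literal Type III definition), computed on a full-rank basis obtained by
    sweep-order pivoting (intercept, mains, interactions, in the order
    given), so empty-cell redundancy is charged to the interactions.

    Empty-cell designs need one departure from the literal definition: once
    an interaction is rank-deficient, the classic test of a term it contains
    degenerates (the interaction columns absorb the term's explanatory
    directions), so such a term is instead tested *marginally* — both the
    reduced and the augmented model exclude the deficient containing
    interactions — which keeps the term at its full df and its marginal
    power, the convention of the classical ANOVA packages.  On any design
    with fully populated cells every containing interaction is full rank
    and the plain full-vs-reduced RSS difference is what is computed.  A
    term whose own columns add no rank at all is reported aliased, with no
    F or p.
    """
    y = data[response].to_numpy(float)
    n = len(y)
    blocks = {t: term_columns(data, t, categorical) for t in terms}
    cols: list[np.ndarray] = [np.ones(n)]
    owner: list[str | None] = [None]
    for t in terms:
        for j in range(blocks[t].shape[1]):
            cols.append(blocks[t][:, j])
            owner.append(t)
    kept = _sweep_select(cols)
    X_full = np.column_stack([c for c, k in zip(cols, kept) if k])
    rank_full = X_full.shape[1]
    df_err = n - rank_full
    if df_err <= 0:
        raise ValueError(
            "fewer observations than estimable parameters "
            f"(n={n}, rank={rank_full}); design is saturated")
    rss_full = float(_rss(X_full, y))
    mse = rss_full / df_err
    kept_owner = [o for o, k in zip(owner, kept) if k]
    kept_count = {t: sum(o == t for o in kept_owner) for t in terms}
    deficient = {t: kept_count[t] < blocks[t].shape[1] for t in terms}
    rows, aliased = [], []
    for t in terms:
        bad_parents = [u for u in terms if _contains(u, t) and deficient[u]]
        if not bad_parents:
            # classic Type III: remove the term's columns from the full basis
            df_t = kept_count[t]
            if df_t == 0:
                aliased.append(t)
                rows.append((t, np.nan, 0, np.nan, np.nan, np.nan))
                continue
            X_red = X_full[:, [o != t for o in kept_owner]]
            ss = max(float(_rss(X_red, y)) - rss_full, 0.0)
        else:
            # marginal test: deficient containing interactions excluded from
            # both models
            base_terms = [u for u in terms if u != t and u not in bad_parents]
            base_cols = [np.ones(n)] + \
                [blocks[u][:, j] for u in base_terms
                 for j in range(blocks[u].shape[1])]
            keep_base = _sweep_select(base_cols)
            aug_cols = base_cols + [blocks[t][:, j]
                                    for j in range(blocks[t].shape[1])]
            keep_aug = _sweep_select(aug_cols)
            df_t = sum(keep_aug) - sum(keep_base)
            if df_t == 0:
                aliased.append(t)
                rows.append((t, np.nan, 0, np.nan, np.nan, np.nan))
                continue
            X_base = np.column_stack([c for c, k in zip(base_cols, keep_base) if k])
            X_aug = np.column_stack([c for c, k in zip(aug_cols, keep_aug) if k])
            ss = max(float(_rss(X_base, y)) - float(_rss(X_aug, y)), 0.0)
        ms = ss / df_t
        F = ms / mse
        p = stats.f.sf(F, df_t, df_err)
        rows.append((t, ss, df_t, ms, F, p))
    y_c = y - y.mean()
    rows.append(("Error", rss_full, df_err, mse, np.nan, np.nan))
    rows.append(("Corrected Total", float(y_c @ y_c), n - 1, np.nan,
                 np.nan, np.nan))
    table = pd.DataFrame(rows, columns=["term", "SS", "df", "MS", "F", "p"]
                         ).set_index("term")
    return AnovaTable(table=table, aliased=aliased)


def anova_type3(data: pd.DataFrame, response: str = "G",
                factors: list[str] = ("genotype", "location", "cohort"),
                two_way_interactions=True) -> AnovaTable:
    """Type III ANOVA of the growth index over categorical factors.

    By default all three main effects and every two-way interaction are
    included, mirroring the three-way growth-rate variance partition.  Each
    retained factor needs at least two observed levels.
    """
    factors = list(factors)
    for f in factors:
        if data[f].nunique() < 2:
            raise ValueError(f"factor {f!r} has fewer than 2 observed levels")
    terms = _build_terms(factors, two_way_interactions)
    return linear_model_terms(data, response, terms, categorical=set(factors))


# --------------------------------------------------------------------------
# per-descriptor GLM scans

@dataclass
class GlmScanResult:
    p_values: pd.DataFrame       # descriptors x terms
    significant_counts: pd.Series
    alpha: float
    aliased: dict = field(default_factory=dict)


def descriptor_glm_scan(matrix, data: pd.DataFrame,
                        terms: list[str] = ("G", "location", "cohort",
                                            "genotype", "G:cohort"),
                        categorical: set[str] = frozenset(
                            {"location", "cohort", "genotype"}),
                        alpha: float = 0.05) -> GlmScanResult:
    """Per-descriptor linear models with per-term F-tests.

    For every descriptor column the same design (growth index G as a numeric
    covariate, location/cohort/genotype as factors, plus the G-by-cohort
    interaction by default) is fitted and each term's Type III F-test
    p-value recorded.  The headline quantity is the count of descriptors
    significant per term at ``alpha``; no multiplicity correction is applied.
    """
    desc = matrix.data if hasattr(matrix, "data") else pd.DataFrame(matrix)
    if len(desc) != len(data):
        raise ValueError("descriptor matrix and metadata must align")
    terms = list(terms)
    categorical = set(categorical)
    n = len(data)
    blocks = {t: term_columns(data, t, categorical) for t in terms}
    cols: list[np.ndarray] = [np.ones(n)]
    owner: list[str | None] = [None]
    for t in terms:
        for j in range(blocks[t].shape[1]):
            cols.append(blocks[t][:, j])
            owner.append(t)
    kept = _sweep_select(cols)
    X_full = np.column_stack([c for c, k in zip(cols, kept) if k])
    kept_owner = [o for o, k in zip(owner, kept) if k]
    df_err = n - X_full.shape[1]
    if df_err <= 0:
        raise ValueError("design is saturated; cannot test terms")
    Y = desc.to_numpy(float)
    rss_full = _rss(X_full, Y)
    pvals = pd.DataFrame(index=desc.columns, columns=terms, dtype=float)
    aliased = {}
    for t in terms:
        df_t = sum(o == t for o in kept_owner)
        if df_t == 0:
            aliased[t] = "aliased (no estimable contrast)"
            warnings.warn(f"term {t!r} is aliased; excluded from counts")
            continue
        X_red = X_full[:, [o != t for o in kept_owner]]
        rss_red = _rss(X_red, Y)
        F = ((rss_red - rss_full) / df_t) / (rss_full / df_err)
        pvals[t] = stats.f.sf(np.maximum(F, 0.0), df_t, df_err)
    counts = (pvals < alpha).sum(axis=0)
    counts[list(aliased)] = 0
    return GlmScanResult(p_values=pvals, significant_counts=counts,
                         alpha=alpha, aliased=aliased)


# --------------------------------------------------------------------------
# Tukey HSD

@dataclass
class TukeyResult:
    comparisons: pd.DataFrame    # pairs: difference, SE, q, p_adj, significant
    letters: pd.Series           # compact letter display per group
    mse: float
    df_error: int


def _letter_display(groups: list, sig_pairs: set[tuple]) -> pd.Series:
    """Compact letter display: two groups share a letter iff their
    difference is not significant.

    Letters are assigned to the maximal cliques of the non-significance
    graph (Bron-Kerbosch), which satisfies the display contract exactly.
    """
    adj = {g: set() for g in groups}
    for a, b in itertools.combinations(groups, 2):
        if (min(a, b), max(a, b)) not in sig_pairs:
            adj[a].add(b)
            adj[b].add(a)
    cliques: list[set] = []

    def bron_kerbosch(r: set, p: set, x: set) -> None:
        if not p and not x:
            cliques.append(r)
            return
        for v in sorted(p):
            bron_kerbosch(r | {v}, p & adj[v], x & adj[v])
            p = p - {v}
            x = x | {v}

    bron_kerbosch(set(), set(groups), set())
    cliques.sort(key=lambda c: sorted(c))
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    letters = {g: set() for g in groups}
    for k, col in enumerate(cliques):
        for g in col:
            letters[g].add(alphabet[k % len(alphabet)])
    return pd.Series(["".join(sorted(letters[g])) for g in groups],
                     index=groups, name="letters")


def tukey_hsd(values, groups, alpha: float = 0.05) -> TukeyResult:
    """Tukey(-Kramer) pairwise comparisons after a one-way layout.

    Uses the pooled one-way MSE and the studentized-range distribution;
    unequal group sizes are handled by the Kramer standard error.  Groups of
    size 1 are excluded with a warning.
    """
    values = np.asarray(values, float)
    groups = np.asarray(groups)
    classes, counts = np.unique(groups, return_counts=True)
    drop = classes[counts < 2]
    if drop.size:
        warnings.warn(f"groups of size 1 excluded from Tukey test: {list(drop)}")
        keep = ~np.isin(groups, drop)
        values, groups = values[keep], groups[keep]
        classes, counts = np.unique(groups, return_counts=True)
    k = len(classes)
    if k < 2:
        raise ValueError("need at least two groups of size >= 2")
    n = len(values)
    means = np.array([values[groups == c].mean() for c in classes])
    sse = sum(((values[groups == c] - m) ** 2).sum()
              for c, m in zip(classes, means))
    df_err = n - k
    mse = sse / df_err
    rows = []
    sig_pairs = set()
    for (i, a), (j, b) in itertools.combinations(enumerate(classes), 2):
        diff = means[i] - means[j]
        se = np.sqrt(mse / 2.0 * (1.0 / counts[i] + 1.0 / counts[j]))
        q = abs(diff) / se
        p = float(stats.studentized_range.sf(q, k, df_err))
        sig = p < alpha
        if sig:
            sig_pairs.add((min(a, b), max(a, b)))
        rows.append((a, b, diff, se, q, p, sig))
    comp = pd.DataFrame(rows, columns=["group1", "group2", "difference",
                                       "SE", "q", "p_adj", "significant"])
    letters = _letter_display(list(classes), sig_pairs)
    return TukeyResult(comparisons=comp, letters=letters, mse=float(mse),
                       df_error=int(df_err))
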