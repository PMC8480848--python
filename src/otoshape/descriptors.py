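"""Descriptor matrices and length detrending.

Otolith shape covaries with fish size even after the size standardization
built into the descriptors, so each descriptor is screened against fish
length with a linear model that allows location-specific intercepts but a
common (within-group) slope:

    descriptor ~ length + location

Descriptors whose length slope is significant at ``alpha`` are replaced by
``descriptor - beta * length`` (strict mode) or, by default, by
``descriptor - beta * (length - mean(length))`` which removes the trend while
preserving the descriptor's scale; the constant shift is irrelevant to any
downstream discriminant or ANOVA result.  Non-significant descriptors pass
through unchanged.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .fourier import fourier_descriptors
from .outline import Outline
from .wavelet import radius_profile, wavelet_descriptors


@dataclass
class DescriptorMatrix:
    """Fish-by-descriptor table with its detrending state and provenance."""

    data: pd.DataFrame                      # index: fish ids, columns: F01.. / W01..
    kind: str = "fourier"                   # 'fourier' | 'wavelet' | 'mixed'
    detrended: bool = False
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.data.isna().any().any():
            raise ValueError("descriptor matrix must have no missing cells")

    @property
    def fish_ids(self) -> list:
        return list(self.data.index)

    @property
    def descriptor_names(self) -> list[str]:
        return list(self.data.columns)

    def values(self) -> np.ndarray:
        return self.data.to_numpy()

    def drop(self, names: list[str]) -> "DescriptorMatrix":
        return DescriptorMatrix(self.data.drop(columns=list(names)),
                                kind=self.kind, detrended=self.detrended,
                                provenance=dict(self.provenance))

    def to_csv(self, path) -> None:
        self.data.to_csv(path, index_label="id")

    @classmethod
    def from_csv(cls, path, kind: str = "fourier") -> "DescriptorMatrix":
        return cls(pd.read_csv(path, index_col="id"), kind=kind)


@dataclass
class DetrendModel:
    """Per-descriptor length slope, its p-value, and whether it was removed."""

    table: pd.DataFrame                     # columns: beta, p_value, detrended

    @property
    def alpha(self) -> float:
        return float(self.table.attrs.get("alpha", 0.05))


def describe_outlines(outlines: dict, kind: str = "fourier",
                      n_harmonics: int = 12, wavelet_family: str = "db4",
                      n_profile: int = 1024) -> DescriptorMatrix:
    """Compute one descriptor row per outline.

    ``outlines`` maps fish id -> :class:`~otoshape.outline.Outline`.  Left
    otolith outlines are mirrored before description so all shapes share the
    right-otolith chirality.
    """
    rows, ids = [], []
    names: list[str] | None = None
    for fish_id, outline in outlines.items():
        if outline.side == "left":
            outline = outline.mirrored()
        if kind == "fourier":
            desc = fourier_descriptors(outline, n_harmonics=n_harmonics)
        elif kind == "wavelet":
            desc = wavelet_descriptors(radius_profile(outline, n_profile),
                                       family=wavelet_family)
        else:
            raise ValueError("kind must be 'fourier' or 'wavelet'")
        rows.append(desc.values)
        ids.append(fish_id)
        names = desc.names
    data = pd.DataFrame(np.vstack(rows), index=pd.Index(ids, name="id"),
                        columns=names)
    prov = {"kind": kind, "n_harmonics": n_harmonics,
            "wavelet_family": wavelet_family, "n_profile": n_profile}
    return DescriptorMatrix(data, kind=kind, provenance=prov)


def detrend(matrix: DescriptorMatrix, lengths, locations,
            alpha: float = 0.05, mode: str = "centered"
            ) -> tuple[DescriptorMatrix, DetrendModel]:
    """Remove the fish-length trend from every significantly affected column.

    For each descriptor a linear model with a common length slope and
    location-specific intercepts is fitted by least squares; the slope's
    t-test decides (at ``alpha``) whether the column is detrended.

    ``mode='centered'`` subtracts ``beta * (length - mean length)``;
    ``mode='strict'`` subtracts ``beta * length``.
    """
    if mode not in ("centered", "strict"):
        raise ValueError("mode must be 'centered' or 'strict'")
    lengths = np.asarray(lengths, float)
    locations = np.asarray(locations)
    y_all = matrix.values()
    n = len(lengths)
    if y_all.shape[0] != n or len(locations) != n:
        raise ValueError("lengths/locations must align with matrix rows")
    levels = sorted(pd.unique(locations))
    X = np.zeros((n, 1 + len(levels)))
    X[:, 0] = lengths
    for j, lev in enumerate(levels):
        X[locations == lev, 1 + j] = 1.0
    rank = np.linalg.matrix_rank(X)
    dof = n - rank
    if dof < 1:
        raise ValueError("too few fish to estimate the length slope "
                         f"(n={n}, parameters={rank})")
    beta_hat, _, _, _ = np.linalg.lstsq(X, y_all, rcond=None)
    resid = y_all - X @ beta_hat
    rss = (resid ** 2).sum(axis=0)
    xtx_inv = np.linalg.pinv(X.T @ X)
    se = np.sqrt(np.maximum(rss / dof * xtx_inv[0, 0], 1e-300))
    slopes = beta_hat[0]
    tstat = slopes / se
    pvals = 2.0 * stats.t.sf(np.abs(tstat), dof)
    significant = pvals < alpha

    out = y_all.copy()
    offset = lengths - lengths.mean() if mode == "centered" else lengths
    out[:, significant] -= np.outer(offset, slopes[significant])

    table = pd.DataFrame({"beta": slopes, "p_value": pvals,
                          "detrended": significant},
                         index=matrix.descriptor_names)
    table.attrs["alpha"] = alpha
    new = DescriptorMatrix(
        pd.DataFrame(out, index=matrix.data.index, columns=matrix.data.columns),
        kind=matrix.kind, detrended=True,
        provenance={**matrix.provenance, "detrend_mode": mode,
                    "detrend_alpha": alpha})
    return new, DetrendModel(table=table)
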