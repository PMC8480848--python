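"""Normalized Elliptic Fourier shape descriptors.

A closed outline ``(x(t), y(t))`` traversed at constant speed is expanded in
harmonic ellipses (the chain-sum formulation of Kuhl & Giardina):

    x(t) = A0 + sum_n a_n cos(2 pi n t / T) + b_n sin(2 pi n t / T)
    y(t) = C0 + sum_n c_n cos(2 pi n t / T) + d_n sin(2 pi n t / T)

The raw coefficients depend on where the traversal starts, on the outline's
position, orientation and size.  ``normalize_fourier`` removes all four:
the start point and orientation are standardized on the first harmonic
ellipse, translation is dropped with the DC terms, and size is divided out
(by the maximum Feret diameter, following common otolith practice, or by the
first semi-major axis length).  After standardization the first harmonic's
``a1`` carries only size, and ``b1 = c1 = 0`` exactly, so those three are
dropped: ``n`` harmonics yield ``4 n - 3`` descriptors (45 for the default
12 harmonics).  The retained first-harmonic term ``d1`` is the aspect
(minor/major) of the best-fitting ellipse.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .outline import Outline, feret_diameter


@dataclass
class FourierDescriptors:
    """Normalized elliptic Fourier descriptor vector for one outline."""

    values: np.ndarray          # length 4*n_harmonics - 3
    n_harmonics: int
    normalization: dict = field(default_factory=dict)

    @property
    def names(self) -> list[str]:
        return [f"F{i + 1:02d}" for i in range(len(self.values))]


def elliptic_fourier(outline: Outline, n_harmonics: int = 12) -> np.ndarray:
    """Raw elliptic Fourier coefficients of a closed polygon.

    Returns an ``(n_harmonics, 4)`` array of rows ``(a_n, b_n, c_n, d_n)``.
    The chain-sum formulas integrate exactly over the polygon's straight
    segments, so reconstruction from all harmonics converges to the outline.
    """
    pts = outline.points if isinstance(outline, Outline) else np.asarray(outline, float)
    d = np.diff(np.vstack([pts, pts[:1]]), axis=0)
    dt = np.hypot(d[:, 0], d[:, 1])
    if not (dt > 0).all():
        d = d[dt > 0]
        dt = dt[dt > 0]
    T = dt.sum()
    if T <= 0:
        raise ValueError("degenerate outline with zero perimeter")
    t = np.concatenate([[0.0], np.cumsum(dt)])
    n = np.arange(1, n_harmonics + 1)[:, None]
    phi = 2.0 * np.pi * t / T                       # (m+1,)
    c1 = np.cos(n * phi[None, 1:]) - np.cos(n * phi[None, :-1])
    s1 = np.sin(n * phi[None, 1:]) - np.sin(n * phi[None, :-1])
    k = T / (2.0 * (n.ravel() ** 2) * np.pi ** 2)
    dxdt = d[:, 0] / dt
    dydt = d[:, 1] / dt
    coeffs = np.empty((n_harmonics, 4))
    coeffs[:, 0] = k * (c1 @ dxdt)
    coeffs[:, 1] = k * (s1 @ dxdt)
    coeffs[:, 2] = k * (c1 @ dydt)
    coeffs[:, 3] = k * (s1 @ dydt)
    return coeffs


def elliptic_fourier_dc(outline: Outline) -> tuple[float, float]:
    """DC (position) terms A0, C0 of the expansion."""
    pts = outline.points if isinstance(outline, Outline) else np.asarray(outline, float)
    d = np.diff(np.vstack([pts, pts[:1]]), axis=0)
    dt = np.hypot(d[:, 0], d[:, 1])
    keep = dt > 0
    d, dt = d[keep], dt[keep]
    T = dt.sum()
    t1 = np.concatenate([[0.0], np.cumsum(dt)])[:-1]
    p = pts[np.concatenate([keep.nonzero()[0]])]
    # integral of the piecewise-linear x(t): trapezoid on each segment
    x0, y0 = p[:, 0], p[:, 1]
    a0 = ((x0 + x0 + d[:, 0]) / 2.0 * dt).sum() / T
    c0 = ((y0 + y0 + d[:, 1]) / 2.0 * dt).sum() / T
    return float(a0), float(c0)


def reconstruct(coeffs: np.ndarray, n_points: int = 256,
                dc: tuple[float, float] = (0.0, 0.0)) -> np.ndarray:
    """Inverse elliptic Fourier synthesis: sample the harmonic sum."""
    coeffs = np.asarray(coeffs, float)
    n_harm = coeffs.shape[0]
    t = np.linspace(0.0, 2.0 * np.pi, n_points, endpoint=False)
    n = np.arange(1, n_harm + 1)[:, None]
    cos, sin = np.cos(n * t), np.sin(n * t)
    x = dc[0] + coeffs[:, 0] @ cos + coeffs[:, 1] @ sin
    y = dc[1] + coeffs[:, 2] @ cos + coeffs[:, 3] @ sin
    return np.column_stack([x, y])


def _rotate_coeffs(coeffs: np.ndarray, theta: float, psi: float) -> np.ndarray:
    """Apply start-point shift theta and spatial rotation psi."""
    n_harm = coeffs.shape[0]
    out = np.empty_like(coeffs)
    cpsi, spsi = np.cos(psi), np.sin(psi)
    rot_space = np.array([[cpsi, spsi], [-spsi, cpsi]])
    for i in range(n_harm):
        m = coeffs[i].reshape(2, 2)
        nt = (i + 1) * theta
        rot_start = np.array([[np.cos(nt), -np.sin(nt)],
                              [np.sin(nt), np.cos(nt)]])
        out[i] = (rot_space @ m @ rot_start).ravel()
    return out


def _canonical(coeffs: np.ndarray) -> np.ndarray:
    """Resolve the residual 180-degree start/rotation ambiguity.

    Shifting the start point by half a period and rotating by pi leaves the
    first harmonic unchanged but negates every even harmonic.  Of the two
    equivalent forms, keep the one whose first even-harmonic coefficient of
    decisive magnitude is positive.
    """
    flipped = coeffs.copy()
    flipped[1::2] *= -1.0
    scale = max(abs(coeffs[0, 0]), abs(coeffs[0, 3]), 1e-30)
    even = coeffs[1::2].ravel()
    decisive = np.abs(even) > 1e-9 * scale
    if not decisive.any():
        return coeffs
    j = int(np.argmax(decisive))
    return coeffs if even[j] > 0 else flipped


def normalize_fourier(raw: np.ndarray, feret: float,
                      n_harmonics: int | None = None,
                      size_norm: str = "feret") -> FourierDescriptors:
    """Standardize raw elliptic Fourier coefficients.

    Start point and rotation are aligned to the first harmonic ellipse (its
    traversal begins on the semi-major axis, which is rotated onto +x), the
    sign ambiguities are resolved canonically, and size is divided out by
    ``feret`` (default) or by the first semi-major axis (``size_norm='a1'``).
    The three first-harmonic coefficients pinned by the standardization are
    dropped, leaving ``4 n - 3`` values.
    """
    coeffs = np.asarray(raw, float).copy()
    if n_harmonics is not None:
        coeffs = coeffs[:n_harmonics]
    a1, b1, c1, d1 = coeffs[0]
    if feret <= 0:
        raise ValueError("feret must be positive")
    # start-point phase of the first-harmonic ellipse
    denom = a1 ** 2 - b1 ** 2 + c1 ** 2 - d1 ** 2
    theta = 0.5 * np.arctan2(2.0 * (a1 * b1 + c1 * d1), denom)
    # candidate start shifts a quarter turn apart map the start onto either
    # semi-axis; pick the one landing on the major axis with a1* > 0
    best = None
    for th in (theta, theta + np.pi / 2.0, theta + np.pi, theta + 3 * np.pi / 2.0):
        m = coeffs[0].reshape(2, 2) @ np.array(
            [[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
        axis_len = np.hypot(m[0, 0], m[1, 0])
        if best is None or axis_len > best[0] + 1e-15:
            psi = np.arctan2(m[1, 0], m[0, 0])
            best = (axis_len, th, psi)
    _, theta, psi = best
    out = _rotate_coeffs(coeffs, theta, psi)
    out = _canonical(out)
    semi_major = out[0, 0]
    scale = feret if size_norm == "feret" else semi_major
    if size_norm not in ("feret", "a1"):
        raise ValueError("size_norm must be 'feret' or 'a1'")
    out = out / scale
    values = np.concatenate([[out[0, 3]], out[1:].ravel()])
    return FourierDescriptors(
        values=values,
        n_harmonics=out.shape[0],
        normalization={
            "start_shift": float(theta),
            "rotation": float(psi),
            "size_norm": size_norm,
            "scale": float(scale),
            "semi_major": float(semi_major),
        },
    )


def fourier_descriptors(outline: Outline, n_harmonics: int = 12,
                        size_norm: str = "feret") -> FourierDescriptors:
    """Outline -> normalized descriptor vector (convenience chain)."""
    raw = elliptic_fourier(outline, n_harmonics)
    return normalize_fourier(raw, feret_diameter(outline.points),
                             size_norm=size_norm)
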