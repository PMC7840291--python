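"""Minimum-area enclosing ellipse (ellipsoid hull) in the plane.

The daily activity-space ellipse is the smallest-area ellipse containing all
of a day's projected GPS fixes.  It is computed with Khachiyan's iterative
barycentric-coordinate-ascent algorithm for the minimum-volume enclosing
ellipsoid (MVEE), specialised to 2-D.  Degenerate point sets (a single
point, or collinear points) are handled explicitly: they yield an ellipse
with one or both semi-axes equal to zero, hence zero area.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import ConvexHull, QhullError


@dataclass(frozen=True)
class Ellipse:
    """An ellipse in planar (km) coordinates.

    ``orientation`` is the angle of the major axis in radians,
    counter-clockwise from the +x axis, in (-pi/2, pi/2].
    """

    center: tuple[float, float]
    semi_major: float
    semi_minor: float
    orientation: float

    @property
    def area(self) -> float:
        return float(np.pi * self.semi_major * self.semi_minor)

    def contains(self, points, tol: float = 1e-6):
        """Elementwise containment test with an absolute km tolerance."""
        pts = np.atleast_2d(np.asarray(points, dtype=float)) - np.asarray(self.center)
        c, s = np.cos(self.orientation), np.sin(self.orientation)
        u = pts @ np.array([c, s])   # coordinate along major axis
        v = pts @ np.array([-s, c])  # coordinate along minor axis
        a = self.semi_major + tol
        b = self.semi_minor + tol
        return (u / a) ** 2 + (v / b) ** 2 <= 1.0


class EllipseConvergenceError(RuntimeError):
    """Raised when the MVEE iteration fails to reach tolerance."""

    def __init__(self, iterations: int, err: float):
        super().__init__(
            f"MVEE did not converge after {iterations} iterations (err={err:.3g})"
        )
        self.iterations = iterations
        self.err = err


def _degenerate_ellipse(points: np.ndarray) -> Ellipse | None:
    """Handle rank-deficient point sets; return None when full rank."""
    mean = points.mean(axis=0)
    centered = points - mean
    # singular values of the centered cloud reveal its affine rank
    s = np.linalg.svd(centered, compute_uv=False) if len(points) > 1 else np.zeros(2)
    scale = max(float(s[0]), 1.0)
    if len(points) == 1 or s[0] <= 1e-12:
        return Ellipse((float(points[0, 0]), float(points[0, 1])), 0.0, 0.0, 0.0)
    if s[1] <= 1e-9 * scale:
        # collinear: a zero-width ellipse along the principal direction
        _, _, vt = np.linalg.svd(centered)
        direction = vt[0]
        t = centered @ direction
        center = mean + direction * (t.max() + t.min()) / 2.0
        half_extent = float(t.max() - t.min()) / 2.0
        angle = float(np.arctan2(direction[1], direction[0]))
        if angle <= -np.pi / 2 or angle > np.pi / 2:
            angle = angle - np.sign(angle) * np.pi
        return Ellipse((float(center[0]), float(center[1])), half_extent, 0.0, angle)
    return None


def _gap_state(q: np.ndarray, u: np.ndarray, d: int):
    """Dual iterate state: leverages m_i, X^-1 q_i, extreme indices, gap."""
    x = q.T @ (u[:, None] * q)
    xinv_qt = np.linalg.solve(x, q.T)
    m = np.einsum("ij,ji->i", q, xinv_qt)
    j_add = int(np.argmax(m))
    eps_add = m[j_add] / (d + 1.0) - 1.0
    m_active = np.where(u > 0, m, np.inf)
    j_away = int(np.argmin(m_active))
    eps_away = 1.0 - m[j_away] / (d + 1.0)
    return m, xinv_qt, j_add, j_away, max(eps_add, eps_away)


def _khachiyan_weights(pts: np.ndarray, tol: float, max_iter: int):
    """Optimal barycentric weights of the MVEE of ``pts``.

    Maximises log det of the weighted scatter of the lifted points over the
    simplex.  Khachiyan-style first-order ascent with pairwise
    (add/away-combined) steps does the bulk of the work; because pure
    first-order steps can zigzag among three or more support points before
    reaching a 1e-7 duality gap, the support set is then polished with
    Newton steps on the KKT conditions (every support point has leverage
    m_i = d + 1), whose Jacobian is the closed form -(q_i' X^-1 q_j)^2.
    """
    n, d = pts.shape
    q = np.column_stack([pts, np.ones(n)])
    u = np.full(n, 1.0 / n)
    gap = np.inf
    it = 0
    while it < max_iter:
        for _ in range(200):  # first-order phase
            m, xinv_qt, j_add, j_away, gap = _gap_state(q, u, d)
            it += 1
            if gap < tol or it >= max_iter:
                break
            a, b = m[j_add], m[j_away]
            cross2 = (q[j_add] @ xinv_qt[:, j_away]) ** 2
            curv = cross2 - a * b
            t = (a - b) / (-2.0 * curv) if curv < 0 else u[j_away]
            t = min(max(t, 0.0), u[j_away])
            if t <= 0:  # pairwise direction blocked: plain Khachiyan add step
                step = (a - d - 1.0) / ((d + 1.0) * (a - 1.0))
                u *= 1.0 - step
                u[j_add] += step
            else:
                u[j_add] += t
                u[j_away] -= t
        if gap < tol:
            return u, it, gap
        for _ in range(30):  # Newton polish on the active support
            if it >= max_iter:
                break
            support = np.flatnonzero(u > 1e-10)
            if len(support) < d + 1:
                break
            x = q.T @ (u[:, None] * q)
            try:
                g = q[support] @ np.linalg.solve(x, q[support].T)
                k = len(support)
                jac = np.zeros((k + 1, k + 1))
                jac[:k, :k] = -(g**2)
                jac[:k, k] = 1.0  # Lagrange multiplier of sum(u) = 1
                jac[k, :k] = 1.0
                resid = np.concatenate([np.diag(g) - (d + 1.0), [0.0]])
                delta = np.linalg.solve(jac, -resid)[:k]
            except np.linalg.LinAlgError:
                break
            u_new = u.copy()
            u_new[support] = u[support] + delta
            if u_new.min() < 0:  # step to the boundary, dropping the blocker
                shrink = np.min(
                    np.where(u_new < 0, u / np.maximum(u - u_new, 1e-300), np.inf)
                )
                u_new = np.maximum(u + shrink * (u_new - u), 0.0)
            u = u_new / u_new.sum()
            it += 1
            m, xinv_qt, j_add, j_away, gap = _gap_state(q, u, d)
            if gap < tol:
                return u, it, gap
    return u, it, gap


def min_enclosing_ellipse(
    points, tol: float = 1e-7, max_iter: int = 10_000
) -> Ellipse:
    """Minimum-area ellipse containing all ``points`` (array-like, shape (n, 2)).

    Parameters
    ----------
    points
        Planar coordinates in km.
    tol
        Convergence tolerance on the Khachiyan weight update.
    max_iter
        Iteration cap; exceeding it raises :class:`EllipseConvergenceError`
        rather than returning a silently unconverged ellipse.
    """
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError("points must have shape (n, 2)")
    if len(pts) == 0:
        raise ValueError("at least one point required")
    if not np.all(np.isfinite(pts)):
        raise ValueError("non-finite point coordinates")

    degenerate = _degenerate_ellipse(pts)
    if degenerate is not None:
        return degenerate

    # the MVEE depends only on the convex hull; reducing to hull vertices
    # removes interior/duplicate points and speeds convergence greatly
    all_pts = pts
    if len(pts) > 3:
        try:
            pts = pts[ConvexHull(pts).vertices]
        except QhullError:
            pass  # near-degenerate sets fall through to the full point set

    # the MVEE commutes with affine maps, and Khachiyan's ascent is slow on
    # very elongated clouds (a day of travel can be km long but metres
    # wide), so whiten by the covariance, solve, and map back
    mean = pts.mean(axis=0)
    cov = np.cov(pts.T) if len(pts) > 1 else np.eye(2)
    w_eig, w_vec = np.linalg.eigh(cov)
    w_eig = np.maximum(w_eig, 1e-18 * max(float(w_eig.max()), 1.0))
    whiten = w_vec @ np.diag(1.0 / np.sqrt(w_eig)) @ w_vec.T
    pts = (pts - mean) @ whiten

    u, iterations, err = _khachiyan_weights(pts, tol, max_iter)
    if err >= tol:
        raise EllipseConvergenceError(iterations, err)

    center_w = u @ pts
    scatter = pts.T @ (u[:, None] * pts) - np.outer(center_w, center_w)
    a_w = np.linalg.inv(scatter) / 2.0  # (x-c)' A (x-c) <= 1 in whitened space
    # undo the whitening: x_w = whiten @ (x - mean)
    a_mat = whiten @ a_w @ whiten
    center = mean + np.linalg.solve(whiten, center_w)
    # guarantee containment: expand minimally so every original point is inside
    diffs = all_pts - center
    quad = np.einsum("ij,jk,ik->i", diffs, a_mat, diffs)
    worst = float(quad.max())
    if worst > 1.0:
        a_mat = a_mat / worst

    eigvals, eigvecs = np.linalg.eigh(a_mat)
    # smallest eigenvalue of A corresponds to the longest semi-axis
    semi_axes = 1.0 / np.sqrt(eigvals)
    major_vec = eigvecs[:, 0]
    angle = float(np.arctan2(major_vec[1], major_vec[0]))
    if angle <= -np.pi / 2 or angle > np.pi / 2:
        angle = angle - np.sign(angle) * np.pi
    return Ellipse(
        (float(center[0]), float(center[1])),
        float(semi_axes[0]),
        float(semi_axes[1]),
        angle,
    )
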