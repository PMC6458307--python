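"""2-D polynomial coordinate transforms.

Used both to synthesize inter-channel misalignment (the warp that maps one
camera channel onto the other) and to fit the fiducial-based registration
that undoes it.  A transform maps (x, y) -> (P(x, y), Q(x, y)) where P and Q
are polynomials of total degree 1 (affine) or 2.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

# Monomial exponents per degree, in fixed order: 1, x, y [, x^2, x*y, y^2]
_EXPONENTS = {
    1: [(0, 0), (1, 0), (0, 1)],
    2: [(0, 0), (1, 0), (0, 1), (2, 0), (1, 1), (0, 2)],
}


def n_terms(degree: int) -> int:
    """Number of monomials: (degree+1)(degree+2)/2."""
    return (degree + 1) * (degree + 2) // 2


def design_matrix(xy: np.ndarray, degree: int) -> np.ndarray:
    """Monomial design matrix, shape (n, n_terms)."""
    if degree not in _EXPONENTS:
        raise ValueError("degree must be 1 or 2")
    xy = np.atleast_2d(np.asarray(xy, dtype=float))
    x, y = xy[:, 0], xy[:, 1]
    return np.column_stack([x**i * y**j for i, j in _EXPONENTS[degree]])


@dataclass
class PolynomialTransform:
    """x' = coef_x . basis(x, y), y' = coef_y . basis(x, y)."""

    degree: int
    coef_x: np.ndarray
    coef_y: np.ndarray
    rms_residual: float = 0.0

    def __post_init__(self) -> None:
        self.coef_x = np.asarray(self.coef_x, dtype=float)
        self.coef_y = np.asarray(self.coef_y, dtype=float)
        k = n_terms(self.degree)
        if self.coef_x.shape != (k,) or self.coef_y.shape != (k,):
            raise ValueError(f"coefficient vectors must have length {k}")

    @classmethod
    def identity(cls, degree: int = 1) -> "PolynomialTransform":
        k = n_terms(degree)
        cx = np.zeros(k)
        cy = np.zeros(k)
        cx[1] = 1.0  # x term
        cy[2] = 1.0  # y term
        return cls(degree, cx, cy)

    @classmethod
    def translation(cls, dx: float, dy: float, degree: int = 1) -> "PolynomialTransform":
        t = cls.identity(degree)
        t.coef_x[0] = dx
        t.coef_y[0] = dy
        return t

    def apply(self, xy: np.ndarray) -> np.ndarray:
        xy = np.asarray(xy, dtype=float)
        squeeze = xy.ndim == 1
        a = design_matrix(xy, self.degree)
        out = np.column_stack([a @ self.coef_x, a @ self.coef_y])
        return out[0] if squeeze else out

    def invert_points(
        self, xy: np.ndarray, tol: float = 0.1, max_iter: int = 100
    ) -> np.ndarray:
        """Invert the transform point-wise by fixed-point iteration.

        Writes the map as identity + perturbation and iterates
        x_{k+1} = y - perturbation(x_k); converges for the near-identity
        warps that model channel misalignment.
        """
        y = np.atleast_2d(np.asarray(xy, dtype=float))
        x = y.copy()
        for _ in range(max_iter):
            pert = self.apply(x) - x
            x_new = y - pert
            if np.max(np.abs(x_new - x)) < tol * 0.01:
                x = x_new
                break
            x = x_new
        if np.max(np.abs(self.apply(x) - y)) > tol:
            raise RuntimeError("transform inversion did not converge")
        return x[0] if np.asarray(xy).ndim == 1 else x

    @classmethod
    def fit(
        cls, moving: np.ndarray, fixed: np.ndarray, degree: int = 1
    ) -> "PolynomialTransform":
        """Least-squares polynomial mapping moving -> fixed control points."""
        moving = np.atleast_2d(np.asarray(moving, dtype=float))
        fixed = np.atleast_2d(np.asarray(fixed, dtype=float))
        if moving.shape != fixed.shape:
            raise ValueError("moving and fixed point sets must match in shape")
        k = n_terms(degree)
        if len(moving) < k:
            raise ValueError(
                f"degree-{degree} fit needs at least {k} matched points, "
                f"got {len(moving)}"
            )
        a = design_matrix(moving, degree)
        # Condition check catches collinear bead layouts for degree 2.
        if np.linalg.matrix_rank(a) < k:
            raise np.linalg.LinAlgError(
                "control points are degenerate for the requested degree"
            )
        cx, *_ = np.linalg.lstsq(a, fixed[:, 0], rcond=None)
        cy, *_ = np.linalg.lstsq(a, fixed[:, 1], rcond=None)
        pred = np.column_stack([a @ cx, a @ cy])
        rms = float(np.sqrt(np.mean(np.sum((pred - fixed) ** 2, axis=1))))
        return cls(degree, cx, cy, rms_residual=rms)


# The synthetic inter-channel warp and the fitted registration share one
# representation; the alias keeps call sites readable.
ChannelWarp = PolynomialTransform
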