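"""Trilinear 8-node hexahedral element primitives.

Shared by the finite-element solver (voxel elements of edge ``h`` = voxel
size) and by the DVC grid strain computation (cells of edge ``NS * h``).
All elements here are axis-aligned cubes, so the Jacobian is diagonal and
constant and everything reduces to closed-form tensor products.

Conventions
-----------
* Local corner order follows the usual hexahedron numbering, expressed as
  fractional offsets ``(x, y, z)``::

      0:(0,0,0) 1:(1,0,0) 2:(1,1,0) 3:(0,1,0)
      4:(0,0,1) 5:(1,0,1) 6:(1,1,1) 7:(0,1,1)

* Element degrees of freedom are corner-major: dof ``3*a + c`` is component
  ``c`` (x, y, z) of corner ``a``.
* Strain components are ordered ``(exx, eyy, ezz, gxy, gyz, gzx)`` with
  engineering shears.
"""

from __future__ import annotations

import numpy as np

from .errors import ParameterError

#: Fractional (x, y, z) offsets of the 8 corners, in local order.
CORNERS = np.array(
    [
        [0, 0, 0],
        [1, 0, 0],
        [1, 1, 0],
        [0, 1, 0],
        [0, 0, 1],
        [1, 0, 1],
        [1, 1, 1],
        [0, 1, 1],
    ],
    dtype=float,
)

_SIGNS = 2.0 * CORNERS - 1.0  # d/dt of the per-axis factor, +-1


def shape_functions(t: np.ndarray) -> np.ndarray:
    """Trilinear shape functions at fractional coordinates.

    Parameters
    ----------
    t : array_like, shape (..., 3)
        Fractional coordinates ``(tx, ty, tz)`` in ``[0, 1]^3``.

    Returns
    -------
    ndarray, shape (..., 8)
        ``N_a(t)``; rows sum to 1.
    """
    t = np.asarray(t, dtype=float)
    f = CORNERS * t[..., None, :] + (1.0 - CORNERS) * (1.0 - t[..., None, :])
    return f.prod(axis=-1)


def shape_gradients(t: np.ndarray, h: float = 1.0) -> np.ndarray:
    """Physical gradients ``dN_a/d(x,y,z)`` at fractional coordinates.

    ``h`` is the physical edge length of the cube element.
    Returns an array of shape ``(..., 8, 3)``.
    """
    t = np.asarray(t, dtype=float)
    f = CORNERS * t[..., None, :] + (1.0 - CORNERS) * (1.0 - t[..., None, :])
    g = np.empty(f.shape, dtype=float)
    for k in range(3):
        o1, o2 = [j for j in range(3) if j != k]
        g[..., k] = (_SIGNS[:, k] / h) * f[..., o1] * f[..., o2]
    return g


def b_matrix(t: np.ndarray, h: float = 1.0) -> np.ndarray:
    """Strain-displacement matrix (6 x 24) at fractional coordinates ``t``.

    Maps the 24 corner dofs to the small-strain vector
    ``(exx, eyy, ezz, gxy, gyz, gzx)``.
    """
    g = shape_gradients(t, h)  # (..., 8, 3)
    shp = g.shape[:-2]
    B = np.zeros(shp + (6, 24), dtype=float)
    a = np.arange(8)
    B[..., 0, 3 * a + 0] = g[..., :, 0]
    B[..., 1, 3 * a + 1] = g[..., :, 1]
    B[..., 2, 3 * a + 2] = g[..., :, 2]
    B[..., 3, 3 * a + 0] = g[..., :, 1]
    B[..., 3, 3 * a + 1] = g[..., :, 0]
    B[..., 4, 3 * a + 1] = g[..., :, 2]
    B[..., 4, 3 * a + 2] = g[..., :, 1]
    B[..., 5, 3 * a + 0] = g[..., :, 2]
    B[..., 5, 3 * a + 2] = g[..., :, 0]
    return B


def centroid_b_matrix(h: float = 1.0) -> np.ndarray:
    """B-matrix evaluated at the element centroid."""
    return b_matrix(np.array([0.5, 0.5, 0.5]), h)


def isotropic_elasticity(E: float, nu: float) -> np.ndarray:
    """Isotropic elasticity matrix (6 x 6) in Voigt notation.

    ``E`` in any stress unit; ``nu`` must satisfy ``0 <= nu < 0.5``
    (the incompressible limit makes the matrix singular).
    """
    if E <= 0:
        raise ParameterError(f"elastic modulus must be positive, got {E}")
    if not (0.0 <= nu < 0.5):
        raise ParameterError(f"Poisson ratio must be in [0, 0.5), got {nu}")
    lam = E * nu / ((1.0 + nu) * (1.0 - 2.0 * nu))
    mu = E / (2.0 * (1.0 + nu))
    D = np.zeros((6, 6))
    D[:3, :3] = lam
    D[np.arange(3), np.arange(3)] = lam + 2.0 * mu
    D[np.arange(3, 6), np.arange(3, 6)] = mu
    return D


def gauss_points() -> np.ndarray:
    """2x2x2 Gauss points in fractional coordinates, weight 1/8 each (unit cube)."""
    q = 0.5 + np.array([-1.0, 1.0]) / (2.0 * np.sqrt(3.0))
    pts = np.array([[x, y, z] for z in q for y in q for x in q])
    return pts


def stiffness_matrix(E: float, nu: float, h: float) -> np.ndarray:
    """Stiffness matrix (24 x 24) of a cube element of edge ``h``.

    Exact 2x2x2 Gauss integration of ``B^T D B`` over the element.  With
    lengths in um and ``E`` in N/um^2 the product ``K u`` is in N.
    """
    if h <= 0:
        raise ParameterError(f"element edge length must be positive, got {h}")
    D = isotropic_elasticity(E, nu)
    K = np.zeros((24, 24))
    vol_per_point = h**3 / 8.0
    for t in gauss_points():
        B = b_matrix(t, h)
        K += B.T @ D @ B * vol_per_point
    return 0.5 * (K + K.T)


def strain_tensor(eps6: np.ndarray) -> np.ndarray:
    """Voigt strain vector(s) ``(..., 6)`` to symmetric tensor(s) ``(..., 3, 3)``."""
    eps6 = np.asarray(eps6, dtype=float)
    T = np.zeros(eps6.shape[:-1] + (3, 3))
    T[..., 0, 0] = eps6[..., 0]
    T[..., 1, 1] = eps6[..., 1]
    T[..., 2, 2] = eps6[..., 2]
    T[..., 0, 1] = T[..., 1, 0] = 0.5 * eps6[..., 3]
    T[..., 1, 2] = T[..., 2, 1] = 0.5 * eps6[..., 4]
    T[..., 0, 2] = T[..., 2, 0] = 0.5 * eps6[..., 5]
    return T


def principal_strains(eps6: np.ndarray) -> np.ndarray:
    """Principal strains sorted descending ``(e_p1 >= e_p2 >= e_p3)``.

    Computed by symmetric eigendecomposition of the strain tensor; the
    trace is preserved exactly up to floating-point roundoff.
    """
    vals = np.linalg.eigvalsh(strain_tensor(eps6))
    return vals[..., ::-1]
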