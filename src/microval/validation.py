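"""Agreement statistics between measured (DVC) and predicted (microFE) fields.

Covers the full statistical chain: extraction of paired comparison
points at DVC grid nodes inside bone elements (restricted to the middle
portion of the model height to limit boundary-condition effects),
one-pass Cook's-distance outlier removal, ordinary least squares of
predicted on experimental values with prediction-error metrics (RMSE
against the 1:1 line, RMSE%, maximum error) and Lin's concordance
correlation coefficient, axial-force percentage differences, and
back-calculation of the tissue modulus from force pairs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from . import hexa
from .dvc import DisplacementGrid
from .errors import DegenerateDataError, ParameterError, SampleSizeError
from .fe import FESolution, HexMesh

#: Column layout of the comparison table.
COMPARISON_COLUMNS = [
    "node_id", "x_um", "y_um", "z_um",
    "ux_dvc", "uy_dvc", "uz_dvc",
    "ux_fe", "uy_fe", "uz_fe",
    "compartment",
]

DIRECTIONS = ("x", "y", "z")


def select_comparison_points(
    field: DisplacementGrid,
    mesh: HexMesh,
    sol: FESolution,
    labels: np.ndarray | None = None,
    height_fraction: float = 0.7,
) -> pd.DataFrame:
    """Pair measured and predicted displacements at DVC grid nodes.

    Keeps grid nodes whose position falls inside a bone element of the
    mesh and inside the centred axial slab spanning ``height_fraction`` of
    the mesh height.  The predicted displacement is the trilinear
    interpolation of the 8 nodal FE values of the containing element; the
    measured displacement is the DVC nodal value; the compartment label is
    taken from the containing voxel.

    Returns a DataFrame with columns :data:`COMPARISON_COLUMNS`; raises
    :class:`SampleSizeError` if no point qualifies.
    """
    if not (0.0 < height_fraction <= 1.0):
        raise ParameterError("height fraction must be in (0, 1]")
    pts = field.node_positions_um().reshape(-1, 3)
    u_dvc = field.u.reshape(-1, 3)
    node_ids = np.arange(pts.shape[0])

    h = mesh.voxel_size
    origin = mesh.origin_um
    dims_zyx = mesh.element_of_voxel.shape
    # containing voxel of each point, (z, y, x)
    local = (pts - origin) / h  # (x, y, z) in voxel units
    idx = np.floor(local[:, ::-1]).astype(np.int64)  # (z, y, x)
    inside = np.all(idx >= 0, axis=1) & np.all(idx < np.asarray(dims_zyx), axis=1)

    zmin, zmax = mesh.axial_extent()
    margin = 0.5 * (1.0 - height_fraction) * (zmax - zmin)
    in_slab = (pts[:, 2] >= zmin + margin) & (pts[:, 2] <= zmax - margin)

    keep = inside & in_slab
    elem = np.full(pts.shape[0], -1, dtype=np.int64)
    elem[keep] = mesh.element_of_voxel[tuple(idx[keep].T)]
    keep &= elem >= 0
    if not keep.any():
        raise SampleSizeError("no DVC grid node lies inside a bone element in the comparison slab")

    kept_idx = np.flatnonzero(keep)
    t = local[kept_idx] - np.floor(local[kept_idx])  # fractional (x, y, z) in the voxel
    weights = hexa.shape_functions(t)  # (n, 8)
    u_nodes = sol.u[mesh.elements[elem[kept_idx]]]  # (n, 8, 3)
    u_fe = np.einsum("na,nac->nc", weights, u_nodes)

    if labels is not None:
        comp = labels[tuple(idx[kept_idx].T)].astype(int)
    else:
        comp = np.zeros(kept_idx.size, dtype=int)

    return pd.DataFrame(
        {
            "node_id": node_ids[kept_idx],
            "x_um": pts[kept_idx, 0],
            "y_um": pts[kept_idx, 1],
            "z_um": pts[kept_idx, 2],
            "ux_dvc": u_dvc[kept_idx, 0],
            "uy_dvc": u_dvc[kept_idx, 1],
            "uz_dvc": u_dvc[kept_idx, 2],
            "ux_fe": u_fe[:, 0],
            "uy_fe": u_fe[:, 1],
            "uz_fe": u_fe[:, 2],
            "compartment": comp,
        }
    )


@dataclass
class OutlierRule:
    """Remove points with Cook's distance >= ``multiplier`` times its mean."""

    multiplier: float = 5.0

    def __post_init__(self):
        if not self.multiplier > 0:
            raise ParameterError("Cook's distance multiplier must be positive")


def cooks_filter(x: np.ndarray, y: np.ndarray, rule: OutlierRule | None = None):
    """One-pass Cook's-distance outlier removal for the regression of y on x.

    Returns ``(kept_indices, removed_indices)``.  Points with Cook's
    distance at or above ``multiplier * mean(D)`` are removed; if the fit
    is perfect (all distances zero or undefined) nothing is removed.  The
    filter is applied once, not iterated.
    """
    rule = rule or OutlierRule()
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ParameterError("x and y must have equal length")
    if x.size < 4:
        raise SampleSizeError(f"Cook's filtering needs >= 4 points, got {x.size}")
    res = sm.OLS(y, sm.add_constant(x)).fit()
    all_idx = np.arange(x.size)
    # a perfect (collinear) fit leaves only roundoff residuals; Cook's
    # distances are then 0/0 noise and nothing is an outlier
    if np.sqrt(res.mse_resid) <= 1e-12 * max(1.0, float(np.abs(y).max())):
        return all_idx, np.array([], dtype=int)
    d = res.get_influence().cooks_distance[0]
    if not np.all(np.isfinite(d)) or d.mean() == 0.0:
        return all_idx, np.array([], dtype=int)
    removed = all_idx[d >= rule.multiplier * d.mean()]
    kept = all_idx[d < rule.multiplier * d.mean()]
    return kept, removed


@dataclass
class RegressionStats:
    """Agreement metrics between experimental (x) and predicted (y) values.

    ``slope``, ``intercept`` and ``r2`` come from ordinary least squares of
    y on x; ``rmse`` is the prediction error against the 1:1 line,
    ``rmse_pct`` its percentage of the absolute maximum experimental value,
    ``max_error`` the largest absolute prediction error, and ``cc`` Lin's
    concordance correlation coefficient (population moments).
    """

    slope: float
    intercept: float
    r2: float
    rmse: float
    rmse_pct: float
    max_error: float
    cc: float
    n_points: int
    n_removed: int = 0


def lin_concordance(x: np.ndarray, y: np.ndarray) -> float:
    """Lin's concordance correlation coefficient with population (1/n) moments."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    sx2 = x.var()
    sy2 = y.var()
    sxy = ((x - x.mean()) * (y - y.mean())).mean()
    denom = sx2 + sy2 + (x.mean() - y.mean()) ** 2
    if denom == 0.0:
        raise DegenerateDataError("concordance undefined for identical constant data")
    return float(2.0 * sxy / denom)


def regression_stats(x: np.ndarray, y: np.ndarray, n_removed: int = 0) -> RegressionStats:
    """Full agreement statistics of predicted (y) against experimental (x) values.

    The experimental values sit on the abscissa.  Needs at least 4 points
    and non-zero variance in x.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ParameterError("x and y must have equal length")
    if x.size < 4:
        raise SampleSizeError(f"regression needs >= 4 points, got {x.size}")
    if x.var() == 0.0:
        raise DegenerateDataError("experimental values have zero variance")
    fit = stats.linregress(x, y)
    diff = y - x
    rmse = float(np.sqrt(np.mean(diff**2)))
    max_abs_x = float(np.max(np.abs(x)))
    return RegressionStats(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r2=float(fit.rvalue**2),
        rmse=rmse,
        rmse_pct=100.0 * rmse / max_abs_x if max_abs_x > 0 else float("nan"),
        max_error=float(np.max(np.abs(diff))),
        cc=lin_concordance(x, y),
        n_points=int(x.size),
        n_removed=int(n_removed),
    )


def evaluate_agreement(
    table: pd.DataFrame,
    rule: OutlierRule | None = None,
    compartment: int | None = None,
) -> dict:
    """Per-direction regression statistics with Cook's filtering.

    ``table`` is a comparison table from :func:`select_comparison_points`;
    the filter is applied independently per displacement direction, once,
    before the regression.  Optionally restricts to one compartment label.
    Returns ``{"x": RegressionStats, "y": ..., "z": ...}``.
    """
    rule = rule or OutlierRule()
    if compartment is not None:
        table = table[table["compartment"] == compartment]
    out = {}
    for d in DIRECTIONS:
        x = table[f"u{d}_dvc"].to_numpy()
        y = table[f"u{d}_fe"].to_numpy()
        kept, removed = cooks_filter(x, y, rule)
        out[d] = regression_stats(x[kept], y[kept], n_removed=removed.size)
    return out


@dataclass
class ForceComparison:
    """Experimental vs predicted axial force with absolute percentage difference."""

    af_exp: float
    af_pred: float
    pct_diff: float

    @property
    def pct_diff_rounded(self) -> int:
        """Percentage difference rounded to integer percent for reporting."""
        return int(round(self.pct_diff))


def force_diff(af_exp: float, af_pred: float) -> ForceComparison:
    """Absolute percentage difference ``100 * |pred - exp| / exp``."""
    if not af_exp > 0:
        raise ParameterError(f"experimental axial force must be positive, got {af_exp}")
    return ForceComparison(af_exp, af_pred, 100.0 * abs(af_pred - af_exp) / af_exp)


@dataclass
class BackCalcResult:
    """Back-calculated tissue modulus from force pairs."""

    e_backcalc: float  # GPa
    scale: float  # dimensionless multiplier applied to the reference modulus
    residual_norm: float  # N


def back_calculate_modulus(af_pred_ref, af_exp, e_ref: float) -> BackCalcResult:
    """Least-squares tissue modulus matching predicted to experimental forces.

    The linear elastic model makes the predicted force exactly proportional
    to the tissue modulus, so the best least-squares fit has the closed
    form ``s = sum(pred * exp) / sum(pred^2)`` and
    ``E_backcalc = s * E_ref`` — no re-solve at trial moduli is needed.
    """
    p = np.asarray(af_pred_ref, dtype=float)
    e = np.asarray(af_exp, dtype=float)
    if p.size == 0 or p.size != e.size:
        raise ParameterError("force lists must be nonempty and of equal length")
    if not e_ref > 0:
        raise ParameterError("reference modulus must be positive")
    denom = float(p @ p)
    if denom == 0.0:
        raise DegenerateDataError("all predicted forces are zero; scale undefined")
    s = float(p @ e) / denom
    return BackCalcResult(
        e_backcalc=s * e_ref,
        scale=s,
        residual_norm=float(np.linalg.norm(s * p - e)),
    )
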