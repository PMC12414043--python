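"""Per-node haemodynamic metrics from a time-resolved surface shear field.

All time integrals use trapezoidal quadrature on the stored time grid over
one cardiac cycle [0, T].  Definitions:

    TaWSS = (1/T) * integral_0^T |WSS(s,t)| dt                     [Pa]
    OSI   = 1/2 * (1 - |integral WSS dt| / integral |WSS| dt)      [-]
    RRT   = 1 / (TaWSS * (1 - 2*OSI))                              [1/Pa]
    WSSD  = dWSSx/dx + dWSSy/dy + dWSSz/dz                         [Pa/mm]

WSSD is the divergence of a chosen WSS vector field (time-averaged by
default, or at the systolic instant); each component's spatial gradient is a
weighted least-squares linear fit over the node's 1-ring neighbourhood in
ambient 3D coordinates, with inverse-edge-length weights.  The fit is exact
on linear fields.  Nodes where the metric is undefined (OSI = 0.5 for RRT,
a degenerate neighbourhood for WSSD) carry NaN — never a silently clipped
number.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .fields import WSSFieldSeries
from .mesh import SurfaceMesh

RRT_DENOM_EPS = 1e-9

METRIC_UNITS = {
    "wss": "Pa",
    "tawss": "Pa",
    "osi": "-",
    "rrt": "1/Pa",
    "wssd": "Pa/mm",
    "pressure": "Pa",
}


@dataclass
class MetricField:
    """One scalar per mesh node for a named metric; NaN marks undefined."""

    name: str
    values: np.ndarray
    units: str

    @property
    def defined(self) -> np.ndarray:
        return np.isfinite(self.values)

    def __len__(self) -> int:
        return len(self.values)


def _check_series(series: WSSFieldSeries) -> None:
    if series.cycle_duration <= 0:
        raise ValueError("cycle duration T must be positive")
    if len(series.times) < 2:
        raise ValueError("need at least 2 time samples")


def tawss(series: WSSFieldSeries) -> MetricField:
    """Time-averaged WSS magnitude (Pa)."""
    _check_series(series)
    mag = np.linalg.norm(series.wss, axis=2)             # (t, n)
    vals = np.trapezoid(mag, series.times, axis=0) / series.cycle_duration
    return MetricField("tawss", vals, METRIC_UNITS["tawss"])


def osi(series: WSSFieldSeries) -> MetricField:
    """Oscillatory shear index in [0, 0.5]; 0 where the field vanishes."""
    _check_series(series)
    vec_int = np.trapezoid(series.wss, series.times, axis=0)       # (n, 3)
    mag_int = np.trapezoid(np.linalg.norm(series.wss, axis=2),
                           series.times, axis=0)                   # (n,)
    num = np.linalg.norm(vec_int, axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        ratio = np.where(mag_int > 0, num / np.where(mag_int > 0, mag_int, 1.0), 1.0)
    vals = 0.5 * (1.0 - np.clip(ratio, 0.0, 1.0))
    return MetricField("osi", vals, METRIC_UNITS["osi"])


def rrt(tawss_field: MetricField, osi_field: MetricField) -> MetricField:
    """Relative residence time 1/(TaWSS*(1-2*OSI)); NaN where degenerate."""
    if len(tawss_field) != len(osi_field):
        raise ValueError("TaWSS and OSI fields have mismatched node counts")
    denom = tawss_field.values * (1.0 - 2.0 * osi_field.values)
    vals = np.where(np.abs(denom) > RRT_DENOM_EPS, 1.0 / np.where(denom == 0, 1, denom), np.nan)
    return MetricField("rrt", vals, METRIC_UNITS["rrt"])


def systolic_index(series: WSSFieldSeries) -> int:
    """Time index of peak mesh-mean |WSS| — the systolic instant."""
    mag = np.linalg.norm(series.wss, axis=2)
    return int(np.argmax(mag.mean(axis=1)))


def systolic_wss(series: WSSFieldSeries) -> MetricField:
    """|WSS| at the systolic instant (Pa); the scalar reported as "WSS"."""
    _check_series(series)
    idx = systolic_index(series)
    vals = np.linalg.norm(series.wss[idx], axis=1)
    return MetricField("wss", vals, METRIC_UNITS["wss"])


def pressure_summary(series: WSSFieldSeries, mode: str = "systolic") -> MetricField:
    """Per-node pressure (Pa) at systole (default) or time-averaged."""
    if mode == "systolic":
        vals = series.pressure[systolic_index(series)]
    elif mode == "time_averaged":
        vals = (np.trapezoid(series.pressure, series.times, axis=0)
                / series.cycle_duration)
    else:
        raise ValueError(f"unknown pressure mode {mode!r}")
    return MetricField("pressure", np.array(vals, dtype=float),
                       METRIC_UNITS["pressure"])


def time_averaged_vector(series: WSSFieldSeries) -> np.ndarray:
    """(1/T) * integral of the WSS vector: the mean shear vector per node."""
    return (np.trapezoid(series.wss, series.times, axis=0)
            / series.cycle_duration)


def vector_field_divergence(field: np.ndarray, mesh: SurfaceMesh) -> np.ndarray:
    """Divergence of a per-node 3-vector field via 1-ring least squares.

    For node i the Jacobian J (J[a, b] = dW_a/dx_b) minimises
    sum_j w_j |J d_j - (W_j - W_i)|^2 over 1-ring offsets d_j with weights
    w_j = 1/|d_j|; the divergence is trace(J).  NaN where the neighbourhood
    is degenerate (< 3 neighbours or rank-deficient offsets).
    """
    field = np.asarray(field, dtype=float)
    if field.shape != (mesh.n_nodes, 3):
        raise ValueError("field shape must be (n_nodes, 3)")
    pts = mesh.points
    out = np.full(mesh.n_nodes, np.nan)
    for i, neigh in enumerate(mesh.adjacency):
        if len(neigh) < 3:
            continue
        d = pts[neigh] - pts[i]                  # (k, 3)
        lengths = np.linalg.norm(d, axis=1)
        ok = lengths > 1e-12
        if ok.sum() < 3:
            continue
        d, lengths = d[ok], lengths[ok]
        w = 1.0 / lengths
        dw = (field[neigh[ok]] - field[i])       # (k, 3)
        A = (d * w[:, None]).T @ d               # 3x3 normal matrix
        B = (d * w[:, None]).T @ dw              # 3x3, B = A @ J^T at optimum
        if np.linalg.matrix_rank(A, tol=1e-9 * max(np.abs(A).max(), 1e-30)) < 3:
            continue
        jac_t = np.linalg.solve(A, B)            # J^T
        out[i] = np.trace(jac_t)
    return out


def wssd(series_or_field, mesh: SurfaceMesh,
         mode: str = "time_averaged_field") -> MetricField:
    """WSS divergence (Pa/mm) of the time-averaged or systolic vector field.

    Accepts either a :class:`WSSFieldSeries` (reduced according to ``mode``)
    or a ready (n_nodes, 3) vector field, in which case ``mode`` is ignored.
    """
    if isinstance(series_or_field, WSSFieldSeries):
        if mode == "time_averaged_field":
            field = time_averaged_vector(series_or_field)
        elif mode == "systolic_instant":
            field = series_or_field.wss[systolic_index(series_or_field)]
        else:
            raise ValueError(f"unknown WSSD mode {mode!r}")
    else:
        field = series_or_field
    vals = vector_field_divergence(field, mesh)
    return MetricField("wssd", vals, METRIC_UNITS["wssd"])


def compute_all_metrics(series: WSSFieldSeries, mesh: SurfaceMesh,
                        wssd_mode: str = "time_averaged_field",
                        pressure_mode: str = "systolic") -> dict[str, MetricField]:
    """The six reported metrics, keyed by lowercase name."""
    ta = tawss(series)
    os_ = osi(series)
    return {
        "wss": systolic_wss(series),
        "tawss": ta,
        "osi": os_,
        "rrt": rrt(ta, os_),
        "wssd": wssd(series, mesh, mode=wssd_mode),
        "pressure": pressure_summary(series, mode=pressure_mode),
    }
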