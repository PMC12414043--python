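"""Triangulated aneurysm wall geometry.

The surface model is an idealised sidewall aneurysm: a spherical dome whose
neck opens into a short cylindrical segment of parent vessel.  Coordinates
are in millimetres throughout; the dome is centred at the origin with the
parent vessel extending along the negative z axis.  Node positions carry a
small seeded in-surface jitter so that triangulations are irregular, the way
body-fitted CFD surface meshes are.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components, dijkstra

DOME = "dome"
PARENT_VESSEL = "parent_vessel"

#: (n_dome_rings, n_azimuth, n_vessel_rings) per resolution preset
RESOLUTION_PRESETS = {
    "coarse": (10, 20, 6),
    "medium": (16, 32, 10),
    "fine": (24, 48, 14),
}

MIN_NODES = 200


def preset_node_count(resolution: str | tuple[int, int, int]) -> int:
    """Node count implied by a resolution preset (pole + ring nodes)."""
    n_theta, n_phi, n_cyl = _resolve_resolution(resolution)
    return 1 + (n_theta + n_cyl) * n_phi


def _resolve_resolution(resolution):
    if isinstance(resolution, str):
        try:
            return RESOLUTION_PRESETS[resolution]
        except KeyError:
            raise ValueError(
                f"unknown resolution preset {resolution!r}; "
                f"choose from {sorted(RESOLUTION_PRESETS)}"
            ) from None
    n_theta, n_phi, n_cyl = (int(v) for v in resolution)
    return n_theta, n_phi, n_cyl


@dataclass
class SurfaceMesh:
    """Triangulated wall surface with node adjacency.

    Attributes
    ----------
    points : (n, 3) float array, node coordinates in mm.
    triangles : (m, 3) int array of node index triples, outward winding.
    node_region : length-n array of ``"dome"`` / ``"parent_vessel"`` tags.
    """

    points: np.ndarray
    triangles: np.ndarray
    node_region: np.ndarray
    _adjacency: list[np.ndarray] | None = field(default=None, repr=False)
    _normals: np.ndarray | None = field(default=None, repr=False)
    _graph: csr_matrix | None = field(default=None, repr=False)

    @property
    def n_nodes(self) -> int:
        return len(self.points)

    @property
    def dome_nodes(self) -> np.ndarray:
        return np.flatnonzero(self.node_region == DOME)

    @property
    def vessel_nodes(self) -> np.ndarray:
        return np.flatnonzero(self.node_region == PARENT_VESSEL)

    @property
    def adjacency(self) -> list[np.ndarray]:
        """Per-node sorted arrays of 1-ring neighbour indices."""
        if self._adjacency is None:
            neigh = [set() for _ in range(self.n_nodes)]
            for a, b, c in self.triangles:
                neigh[a].update((b, c))
                neigh[b].update((a, c))
                neigh[c].update((a, b))
            self._adjacency = [np.array(sorted(s), dtype=int) for s in neigh]
        return self._adjacency

    @property
    def node_normals(self) -> np.ndarray:
        """Outward unit normals, area-weighted over incident triangles."""
        if self._normals is None:
            pts = self.points
            tri = self.triangles
            fn = np.cross(pts[tri[:, 1]] - pts[tri[:, 0]],
                          pts[tri[:, 2]] - pts[tri[:, 0]])
            acc = np.zeros_like(pts)
            for k in range(3):
                np.add.at(acc, tri[:, k], fn)
            norms = np.linalg.norm(acc, axis=1, keepdims=True)
            self._normals = acc / np.where(norms == 0.0, 1.0, norms)
        return self._normals

    def edge_graph(self) -> csr_matrix:
        """Sparse symmetric graph of mesh edges weighted by length (mm)."""
        if self._graph is None:
            tri = self.triangles
            i = np.concatenate([tri[:, 0], tri[:, 1], tri[:, 2]])
            j = np.concatenate([tri[:, 1], tri[:, 2], tri[:, 0]])
            w = np.linalg.norm(self.points[i] - self.points[j], axis=1)
            g = csr_matrix((w, (i, j)), shape=(self.n_nodes, self.n_nodes))
            self._graph = g.maximum(g.T)
        return self._graph

    def geodesic_distances(self, sources: np.ndarray) -> np.ndarray:
        """Shortest edge-path distance (mm) from the node set `sources`."""
        sources = np.atleast_1d(np.asarray(sources, dtype=int))
        d = dijkstra(self.edge_graph(), directed=False, indices=sources,
                     min_only=len(sources) > 1)
        return d if d.ndim == 1 else d[0]

    def validate(self) -> None:
        if not np.all(np.isfinite(self.points)):
            raise ValueError("mesh contains non-finite coordinates")
        if self.triangles.min() < 0 or self.triangles.max() >= self.n_nodes:
            raise ValueError("triangle index out of range")
        degrees = np.array([len(a) for a in self.adjacency])
        if degrees.min() < 3:
            raise ValueError("node with fewer than 3 neighbours")
        n_comp, _ = connected_components(self.edge_graph(), directed=False)
        if n_comp != 1:
            raise ValueError("mesh is not edge-connected")


def generate_aneurysm_mesh(
    dome_radius_mm: float = 2.5,
    vessel_radius_mm: float = 1.2,
    resolution: str | tuple[int, int, int] = "coarse",
    seed: int = 0,
    vessel_length_mm: float | None = None,
    jitter: float = 0.15,
) -> SurfaceMesh:
    """Build an idealised aneurysm surface: spherical dome + open vessel stub.

    The dome is the portion of a sphere of radius ``dome_radius_mm`` above the
    neck circle of radius ``vessel_radius_mm``; a cylinder of the same radius
    continues from the neck along -z and is left open at the far end.
    ``jitter`` perturbs interior nodes within the surface (as a fraction of
    the local node spacing) so triangles are irregular; ``jitter=0`` gives the
    structured lattice.  Deterministic for fixed arguments.
    """
    if dome_radius_mm <= 0 or vessel_radius_mm <= 0:
        raise ValueError("radii must be positive")
    if vessel_radius_mm >= dome_radius_mm:
        raise ValueError("vessel radius must be smaller than dome radius")
    n_theta, n_phi, n_cyl = _resolve_resolution(resolution)
    n_nodes = 1 + (n_theta + n_cyl) * n_phi
    if n_nodes < MIN_NODES:
        raise ValueError(
            f"resolution yields {n_nodes} nodes; at least {MIN_NODES} required"
        )
    if vessel_length_mm is None:
        vessel_length_mm = 4.0 * vessel_radius_mm

    R, r = float(dome_radius_mm), float(vessel_radius_mm)
    theta_max = np.pi - np.arcsin(r / R)  # neck sits below the equator
    z_neck = R * np.cos(theta_max)

    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0xA1E5]))
    dtheta = theta_max / n_theta
    dphi = 2 * np.pi / n_phi

    points = [np.array([0.0, 0.0, R])]
    region = [DOME]
    # dome rings (the last one is the neck circle, shared with the vessel)
    for i in range(1, n_theta + 1):
        theta = i * dtheta
        for k in range(n_phi):
            phi = k * dphi
            th, ph = theta, phi
            if 0 < i < n_theta and jitter > 0:
                th = theta + rng.uniform(-jitter, jitter) * dtheta
                ph = phi + rng.uniform(-jitter, jitter) * dphi
            points.append(R * np.array(
                [np.sin(th) * np.cos(ph), np.sin(th) * np.sin(ph), np.cos(th)]
            ))
            region.append(DOME)
    # vessel rings continuing down from the neck
    dz = vessel_length_mm / n_cyl
    for j in range(1, n_cyl + 1):
        z = z_neck - j * dz
        for k in range(n_phi):
            phi = k * dphi
            zz, ph = z, phi
            if j < n_cyl and jitter > 0:
                zz = z + rng.uniform(-jitter, jitter) * dz
                ph = phi + rng.uniform(-jitter, jitter) * dphi
            points.append(np.array([r * np.cos(ph), r * np.sin(ph), zz]))
            region.append(PARENT_VESSEL)

    points = np.asarray(points)

    def ring(i):  # node indices of ring i (1-based; ring 0 is the pole)
        return 1 + (i - 1) * n_phi + np.arange(n_phi)

    triangles = []
    r1 = ring(1)
    for k in range(n_phi):  # pole fan, outward winding (CCW seen from +z)
        triangles.append((0, r1[k], r1[(k + 1) % n_phi]))
    n_rings = n_theta + n_cyl
    for i in range(1, n_rings):
        a, b = ring(i), ring(i + 1)
        for k in range(n_phi):
            k1 = (k + 1) % n_phi
            triangles.append((a[k], b[k], b[k1]))
            triangles.append((a[k], b[k1], a[k1]))
    triangles = np.asarray(triangles, dtype=int)

    mesh = SurfaceMesh(points, triangles, np.asarray(region, dtype=object))
    mesh.validate()
    return mesh
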