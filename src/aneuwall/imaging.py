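"""Synthetic intraoperative-style images of the aneurysm wall.

A pinhole camera and a tiny software rasteriser turn the surface mesh into
an RGB image in which thin-patch wall is drawn from a red colour cluster,
the remaining wall from a pinkish-purple cluster, and the background is a
dark neutral — mimicking the colour contrast a surgeon sees, not the optics.
Pixels are coloured by the nearest visible vertex (z-buffered), which makes
the image <-> mesh correspondence exact: the returned ground-truth mask is
precisely the set of pixels owned by thin vertices, and projecting it back
recovers the thin node set when no noise is added.

Cluster centres are configured in CIELAB so the downstream Delta E distances
are known by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from skimage.color import lab2rgb

# default colour-cluster centres, CIELAB (L*, a*, b*)
RED_LAB = (42.0, 52.0, 26.0)         # thin, translucent-red wall
PINK_PURPLE_LAB = (62.0, 32.0, -8.0)  # normal arterial wall
BACKGROUND_LAB = (18.0, 2.0, 2.0)     # surgical field backdrop


@dataclass
class PinholeCamera:
    """Simple look-at pinhole camera; right-handed, looking along +view."""

    position: np.ndarray
    look_at: np.ndarray
    up: np.ndarray = field(default_factory=lambda: np.array([0.0, 0.0, 1.0]))
    fov_deg: float = 30.0

    def axes(self):
        fwd = np.asarray(self.look_at, float) - np.asarray(self.position, float)
        fwd = fwd / np.linalg.norm(fwd)
        right = np.cross(fwd, np.asarray(self.up, float))
        if np.linalg.norm(right) < 1e-9:  # up parallel to view direction
            right = np.cross(fwd, np.array([1.0, 0.0, 0.0]))
        right = right / np.linalg.norm(right)
        down = np.cross(fwd, right)
        return right, down, fwd

    def project(self, points: np.ndarray, image_size: tuple[int, int]):
        """Points (n,3) mm -> pixel columns/rows (n,2) and view depth (n,)."""
        h, w = image_size
        right, down, fwd = self.axes()
        rel = np.asarray(points, float) - np.asarray(self.position, float)
        x = rel @ right
        y = rel @ down
        z = rel @ fwd
        f = 0.5 * max(h, w) / np.tan(np.deg2rad(self.fov_deg) / 2.0)
        with np.errstate(divide="ignore", invalid="ignore"):
            u = f * x / z + (w - 1) / 2.0
            v = f * y / z + (h - 1) / 2.0
        return np.stack([u, v], axis=1), z

    def to_dict(self) -> dict:
        return {
            "position": list(map(float, self.position)),
            "look_at": list(map(float, self.look_at)),
            "up": list(map(float, self.up)),
            "fov_deg": float(self.fov_deg),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PinholeCamera":
        return cls(np.array(d["position"], float), np.array(d["look_at"], float),
                   np.array(d["up"], float), float(d["fov_deg"]))


def default_camera(mesh, thin_nodes=None, distance_factor: float = 6.0) -> PinholeCamera:
    """Camera centred on the thin patch (or dome apex), looking inward."""
    if thin_nodes is not None and len(thin_nodes):
        target = mesh.points[np.asarray(thin_nodes, int)].mean(axis=0)
    else:
        target = mesh.points[mesh.dome_nodes].mean(axis=0)
    centre = mesh.points.mean(axis=0)
    outward = target - centre
    outward = outward / max(np.linalg.norm(outward), 1e-12)
    extent = np.linalg.norm(mesh.points - centre, axis=1).max()
    pos = target + distance_factor * extent * outward
    up = np.array([0.0, 0.0, 1.0])
    if abs(np.dot(up, outward)) > 0.95:
        up = np.array([0.0, 1.0, 0.0])
    return PinholeCamera(position=pos, look_at=target, up=up)


def rasterize(mesh, camera: PinholeCamera, image_size: tuple[int, int]):
    """Z-buffered nearest-vertex rasterisation.

    Returns ``(owner, depth)``: per-pixel index of the closest visible vertex
    (-1 for background) and the interpolated view depth.  Only front-facing
    triangles (surface normal toward the camera) are drawn.
    """
    h, w = image_size
    uv, z = camera.project(mesh.points, image_size)
    if np.any(z <= 0):
        raise ValueError("mesh extends behind the camera")
    owner = np.full((h, w), -1, dtype=int)
    depth = np.full((h, w), np.inf)

    pts = mesh.points
    tri = mesh.triangles
    centroids = pts[tri].mean(axis=1)
    fn = np.cross(pts[tri[:, 1]] - pts[tri[:, 0]], pts[tri[:, 2]] - pts[tri[:, 0]])
    facing = np.einsum("ij,ij->i", fn, camera.position - centroids) > 0

    for t in np.flatnonzero(facing):
        ia, ib, ic = tri[t]
        pa, pb, pc = uv[ia], uv[ib], uv[ic]
        xmin = int(np.floor(min(pa[0], pb[0], pc[0])))
        xmax = int(np.ceil(max(pa[0], pb[0], pc[0])))
        ymin = int(np.floor(min(pa[1], pb[1], pc[1])))
        ymax = int(np.ceil(max(pa[1], pb[1], pc[1])))
        if xmax < 0 or ymax < 0 or xmin >= w or ymin >= h:
            continue
        xmin, xmax = max(xmin, 0), min(xmax, w - 1)
        ymin, ymax = max(ymin, 0), min(ymax, h - 1)
        xs = np.arange(xmin, xmax + 1)
        ys = np.arange(ymin, ymax + 1)
        gx, gy = np.meshgrid(xs, ys)
        det = ((pb[1] - pc[1]) * (pa[0] - pc[0])
               + (pc[0] - pb[0]) * (pa[1] - pc[1]))
        if abs(det) < 1e-12:
            continue
        l1 = ((pb[1] - pc[1]) * (gx - pc[0]) + (pc[0] - pb[0]) * (gy - pc[1])) / det
        l2 = ((pc[1] - pa[1]) * (gx - pc[0]) + (pa[0] - pc[0]) * (gy - pc[1])) / det
        l3 = 1.0 - l1 - l2
        inside = (l1 >= -1e-9) & (l2 >= -1e-9) & (l3 >= -1e-9)
        if not inside.any():
            continue
        zi = l1 * z[ia] + l2 * z[ib] + l3 * z[ic]
        sub_depth = depth[ymin:ymax + 1, xmin:xmax + 1]
        upd = inside & (zi < sub_depth)
        nearest = np.where(l1 >= np.maximum(l2, l3), ia,
                           np.where(l2 >= l3, ib, ic))
        sub_owner = owner[ymin:ymax + 1, xmin:xmax + 1]
        sub_depth[upd] = zi[upd]
        sub_owner[upd] = nearest[upd]
    return owner, depth


def render_intraop_image(
    mesh,
    thin_patch_nodes,
    camera: PinholeCamera | None = None,
    image_size: tuple[int, int] = (256, 256),
    seed: int = 0,
    noise_sd: float = 3.0,
    red_lab=RED_LAB,
    wall_lab=PINK_PURPLE_LAB,
    background_lab=BACKGROUND_LAB,
):
    """Render an intraoperative-style RGB image and its ground-truth mask.

    ``noise_sd`` is Gaussian pixel noise in 8-bit RGB units (0 disables it).
    Raises if the camera misses the mesh entirely.  Deterministic for a
    fixed seed.
    """
    if camera is None:
        camera = default_camera(mesh, thin_patch_nodes)
    owner, _ = rasterize(mesh, camera, image_size)
    if not (owner >= 0).any():
        raise ValueError("camera does not see the mesh: empty projection")

    thin = np.zeros(mesh.n_nodes, dtype=bool)
    thin[np.asarray(thin_patch_nodes, dtype=int)] = True

    def to_rgb8(lab):
        rgb = lab2rgb(np.asarray(lab, float).reshape(1, 1, 3))[0, 0]
        return np.clip(np.round(rgb * 255.0), 0, 255).astype(np.uint8)

    img = np.empty(image_size + (3,), dtype=np.uint8)
    img[:] = to_rgb8(background_lab)
    wall_px = owner >= 0
    thin_px = wall_px & thin[np.clip(owner, 0, None)]
    img[wall_px] = to_rgb8(wall_lab)
    img[thin_px] = to_rgb8(red_lab)

    if noise_sd > 0:
        rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0x1347]))
        noisy = img.astype(float) + rng.normal(0.0, noise_sd, img.shape)
        img = np.clip(np.round(noisy), 0, 255).astype(np.uint8)
    return img, thin_px
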