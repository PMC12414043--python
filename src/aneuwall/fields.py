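"""Synthetic pulsatile wall-shear and pressure fields.

Stands in for the transient CFD surface solution: each patient gets a
per-node tangential wall-shear-stress (WSS) vector time series and a pressure
time series over one cardiac cycle, with known, injectable region effects.

The construction is deliberately transparent so every downstream quantity has
a closed form.  The spatial WSS magnitude is a smooth profile with a high-
shear band near the neck (which sets the patient-specific maximum used for
normalisation) and a low-shear dome; one or two geodesic "thin" caps on the
dome receive a multiplicative shear elevation, an added radially divergent
tangential component (so the divergence of the time-averaged field has a
known positive sign inside the cap) and a pressure elevation.  Patient- and
region-level lognormal intercepts plus node-level lognormal noise give the
nested variance structure that the mixed model downstream assumes.

The time course factorises: every node shares one positive two-harmonic
waveform, plus an optional node-random oscillatory cross-component whose
cycle integral vanishes, so the oscillatory shear index is strictly positive
yet identically distributed in thin and normal wall (no injected OSI effect).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .mesh import SurfaceMesh, generate_aneurysm_mesh

MMHG_TO_PA = 133.322

DEFAULT_THIN_MULTIPLIERS = {
    "wss": 1.3,       # multiplies shear magnitude inside the cap
    "wssd": 6.0,      # scales the injected divergent component (1 = none)
    "pressure": 1.015,  # multiplies pressure inside the cap
}


@dataclass
class WSSFieldSeries:
    """Per-node tangential WSS vectors (Pa) and pressure (Pa) over one cycle.

    ``times`` is strictly increasing and spans ``[0, T]`` inclusive.
    ``wss`` has shape (n_times, n_nodes, 3); ``pressure`` (n_times, n_nodes).
    """

    times: np.ndarray
    cycle_duration: float
    wss: np.ndarray
    pressure: np.ndarray

    def __post_init__(self):
        t = np.asarray(self.times, dtype=float)
        if t[0] != 0.0 or not np.isclose(t[-1], self.cycle_duration):
            raise ValueError("times must span [0, T]")
        if np.any(np.diff(t) <= 0):
            raise ValueError("times must be strictly increasing")
        if self.wss.shape[0] != len(t) or self.pressure.shape[0] != len(t):
            raise ValueError("time axis mismatch")
        if not (np.all(np.isfinite(self.wss)) and np.all(np.isfinite(self.pressure))):
            raise ValueError("non-finite field values")

    @property
    def n_nodes(self) -> int:
        return self.wss.shape[1]


@dataclass
class CohortConfig:
    """Generator truth for a synthetic cohort.

    ``patient_sd`` / ``region_sd`` are the standard deviations of the nested
    lognormal intercepts (patient level, thin-cap level); ``noise_sd`` is
    node-level residual lognormal noise on the shear magnitude.
    ``waveform_mean_pa`` and ``waveform_amplitudes_pa`` define the shared
    pulse w(t) = mean + a1*sin(2*pi*t/T) + a2*sin(4*pi*t/T + phase); with the
    defaults w(t) > 0 for all t, i.e. no flow reversal.
    """

    n_patients: int = 16
    thin_effect_multipliers: dict = field(
        default_factory=lambda: dict(DEFAULT_THIN_MULTIPLIERS))
    patient_sd: float = 0.10
    region_sd: float = 0.08
    noise_sd: float = 0.12
    waveform_mean_pa: float = 8.0
    waveform_amplitudes_pa: tuple = (4.0, 1.5)
    waveform_phase2: float = 0.8
    cycle_duration_s: float = 1.0
    n_timesteps: int = 64
    oscillatory_sd: float = 0.15
    neck_shear_factor: float = 7.0
    n_thin_caps: int = 2
    cap_radius_mm: float = 1.0
    pressure_baseline_mmhg: float = 80.0
    pressure_pulse_fraction: float = 0.05
    pressure_spatial_fraction: float = 0.06
    dome_radius_mm: float = 2.5
    vessel_radius_mm: float = 1.2
    mesh_resolution: str = "fine"
    seed: int = 0

    def __post_init__(self):
        if self.n_patients < 1:
            raise ValueError("n_patients must be >= 1")
        if self.n_timesteps < 8:
            raise ValueError("n_timesteps must be >= 8")
        if min(self.patient_sd, self.region_sd, self.noise_sd) < 0:
            raise ValueError("standard deviations must be non-negative")


@dataclass
class GroundTruth:
    """What was injected for one patient: the answer key for recovery tests."""

    thin_nodes: np.ndarray             # union of cap node sets (dome subset)
    cap_nodes: list                    # per-cap node index arrays
    multipliers: dict                  # effect multipliers actually applied
    patient_intercept: float           # lognormal patient draw (log scale)
    region_intercepts: np.ndarray      # per-cap lognormal draws (log scale)
    systolic_index: int                # argmax of the shared waveform


def patient_rng(seed: int, patient_index: int) -> np.random.Generator:
    """Documented sub-seed scheme: patient i draws from spawn key (i,)."""
    return np.random.default_rng(
        np.random.SeedSequence(entropy=int(seed), spawn_key=(int(patient_index),)))


def waveform(config: CohortConfig, times: np.ndarray) -> np.ndarray:
    """Shared pulse w(t) in Pa; harmonics integrate to zero over a cycle."""
    T = config.cycle_duration_s
    a1, a2 = config.waveform_amplitudes_pa
    return (config.waveform_mean_pa
            + a1 * np.sin(2 * np.pi * times / T)
            + a2 * np.sin(4 * np.pi * times / T + config.waveform_phase2))


def _tangent_basis(mesh: SurfaceMesh) -> tuple[np.ndarray, np.ndarray]:
    """A smooth-enough unit tangent direction per node and its normal cross."""
    n = mesh.node_normals
    t = np.cross(np.array([0.0, 0.0, 1.0]), n)
    bad = np.linalg.norm(t, axis=1) < 0.2  # near the dome pole
    t[bad] = np.cross(np.array([1.0, 0.0, 0.0]), n[bad])
    t /= np.linalg.norm(t, axis=1, keepdims=True)
    return t, np.cross(n, t)


def _spatial_magnitude(mesh: SurfaceMesh, config: CohortConfig) -> np.ndarray:
    """Dimensionless spatial shear profile: ~1 on the dome, peak on the vessel.

    The parent vessel carries the high-shear band (it sets the
    patient-specific maximum used for normalisation, as in normalising
    against the whole vascular model); the slow recirculating dome sits
    near the profile floor.
    """
    z = mesh.points[:, 2]
    z_neck = z[mesh.vessel_nodes].max() if len(mesh.vessel_nodes) else z.min()
    centre = z_neck - 1.5 * config.vessel_radius_mm
    width = 0.5 * config.vessel_radius_mm
    return 1.0 + (config.neck_shear_factor - 1.0) * np.exp(
        -((z - centre) ** 2) / (2 * width ** 2))


def _choose_caps(mesh: SurfaceMesh, config: CohortConfig,
                 rng: np.random.Generator) -> list[np.ndarray]:
    """Geodesic caps on the upper dome, azimuthally separated."""
    pts = mesh.points
    dome = mesh.dome_nodes
    phi0 = rng.uniform(0, 2 * np.pi)
    centres = []
    for c in range(config.n_thin_caps):
        phi = phi0 + 2 * np.pi * c / max(config.n_thin_caps, 1)
        theta = np.deg2rad(rng.uniform(30, 55))
        target = config.dome_radius_mm * np.array(
            [np.sin(theta) * np.cos(phi), np.sin(theta) * np.sin(phi), np.cos(theta)])
        centres.append(dome[np.argmin(np.linalg.norm(pts[dome] - target, axis=1))])
    caps, taken = [], set()
    for c in centres:
        d = mesh.geodesic_distances(np.array([c]))
        nodes = [i for i in dome if d[i] <= config.cap_radius_mm and i not in taken]
        caps.append(np.array(sorted(nodes), dtype=int))
        taken.update(nodes)
    return caps


def generate_wss_series(
    mesh: SurfaceMesh,
    config: CohortConfig,
    patient_index: int,
    seed: int | None = None,
) -> tuple[WSSFieldSeries, GroundTruth]:
    """Synthesise one patient's pulsatile surface fields with known effects.

    Reproducible: the same (seed, patient_index) always yields bitwise-equal
    arrays.  All WSS vectors are tangential to the wall (orthogonal to the
    node normal to machine precision).
    """
    seed = config.seed if seed is None else seed
    rng = patient_rng(seed, patient_index)

    T = config.cycle_duration_s
    times = np.linspace(0.0, T, config.n_timesteps)
    w = waveform(config, times)                      # (t,) Pa
    w_mean = config.waveform_mean_pa

    e1, e2 = _tangent_basis(mesh)
    normals = mesh.node_normals
    m = _spatial_magnitude(mesh, config)             # (n,)

    b_p = rng.normal(0.0, config.patient_sd)
    caps = _choose_caps(mesh, config, rng)
    b_r = rng.normal(0.0, config.region_sd, size=len(caps))
    node_noise = rng.normal(0.0, config.noise_sd, size=mesh.n_nodes)

    mult = dict(DEFAULT_THIN_MULTIPLIERS)
    mult.update(config.thin_effect_multipliers)

    # spatial steady (time-mean) WSS vector field, Pa
    amp = m * np.exp(b_p + node_noise)
    cap_factor = np.ones(mesh.n_nodes)
    div_inj = np.zeros((mesh.n_nodes, 3))
    for cap, br in zip(caps, b_r):
        if len(cap) == 0:
            continue
        cap_factor[cap] *= mult["wss"] * np.exp(br)
        centre = mesh.points[cap].mean(axis=0)
        radial = mesh.points[cap] - centre
        radial -= np.einsum("ij,ij->i", radial, normals[cap])[:, None] * normals[cap]
        # (wssd multiplier - 1) Pa/mm of radially expanding tangential shear
        div_inj[cap] += (mult["wssd"] - 1.0) * np.exp(br) * radial
    wbar = (w_mean * amp * cap_factor)[:, None] * e1 + div_inj  # (n, 3) Pa

    # oscillatory cross-component: zero cycle integral, region-blind
    osc_amp = np.abs(rng.normal(0.0, config.oscillatory_sd, size=mesh.n_nodes))
    osc_phase = rng.uniform(0.0, 2 * np.pi, size=mesh.n_nodes)
    wbar_mag = np.linalg.norm(wbar, axis=1)
    e2_dir = np.cross(normals, _safe_unit(wbar, e1))
    osc = (osc_amp * wbar_mag)[:, None] * e2_dir      # (n, 3) Pa

    shape = w / w_mean                                 # (t,)
    osc_t = np.sin(2 * np.pi * times / T + osc_phase[:, None]).T  # (t, n)
    wss = shape[:, None, None] * wbar[None, :, :] + osc_t[:, :, None] * osc[None, :, :]

    # pressure: baseline * pulsatile * mild spatial gradient * thin elevation
    p0 = config.pressure_baseline_mmhg * MMHG_TO_PA
    pulse = 1.0 + config.pressure_pulse_fraction * (w - w_mean) / w_mean   # (t,)
    z = mesh.points[:, 2]
    zr = (z - z.min()) / max(z.max() - z.min(), 1e-12)
    spatial = 1.0 - config.pressure_spatial_fraction * (1.0 - zr)          # (n,)
    thin_p = np.ones(mesh.n_nodes)
    for cap in caps:
        thin_p[cap] *= mult["pressure"]
    pressure = p0 * np.exp(b_p * 0.1) * pulse[:, None] * (spatial * thin_p)[None, :]

    thin_nodes = (np.unique(np.concatenate(caps)) if caps and sum(map(len, caps))
                  else np.array([], dtype=int))
    series = WSSFieldSeries(times, T, wss, pressure)
    truth = GroundTruth(
        thin_nodes=thin_nodes,
        cap_nodes=caps,
        multipliers=mult,
        patient_intercept=b_p,
        region_intercepts=b_r,
        systolic_index=int(np.argmax(w)),
    )
    return series, truth


def _safe_unit(v: np.ndarray, fallback: np.ndarray) -> np.ndarray:
    n = np.linalg.norm(v, axis=1, keepdims=True)
    out = np.where(n > 1e-12, v / np.where(n == 0, 1, n), fallback)
    return out


def generate_patient_mesh(config: CohortConfig, patient_index: int,
                          seed: int | None = None) -> SurfaceMesh:
    """Per-patient geometry: radii vary mildly around the cohort defaults."""
    seed = config.seed if seed is None else seed
    rng = patient_rng(seed, patient_index)
    scale = rng.uniform(0.9, 1.1)
    return generate_aneurysm_mesh(
        dome_radius_mm=config.dome_radius_mm * scale,
        vessel_radius_mm=config.vessel_radius_mm * scale,
        resolution=config.mesh_resolution,
        seed=int(rng.integers(2 ** 31)),
    )


def simulate_lmm_table(
    n_patients: int = 16,
    beta0: float = 0.14,
    beta1: float = 0.03,
    patient_sd: float = 0.02,
    region_sd: float = 0.05,
    residual_sd: float = 0.07,
    k: int = 10,
    n_per_region: int = 2,
    rng: np.random.Generator | int = 0,
):
    """Draw a sample table directly from the nested two-level model.

    Y_ij = beta0 + beta1 * thin_ij + b_patient(i) + b_region(i, j) + eps,
    with b_patient ~ N(0, patient_sd^2), b_region ~ N(0, region_sd^2) for
    each sampled region (centre point) and iid residuals.  This is the
    calibration companion to the field-level generator: it exposes the exact
    statistical structure the mixed model assumes, at negligible cost, for
    bias / coverage / type-I studies.
    """
    import pandas as pd

    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    rows = []
    n_regions = 2 * n_per_region
    for i in range(n_patients):
        bp = rng.normal(0.0, patient_sd)
        for j in range(n_regions):
            thin = 1 if j < n_per_region else 0
            br = rng.normal(0.0, region_sd)
            y = (beta0 + beta1 * thin + bp + br
                 + rng.normal(0.0, residual_sd, size=k))
            for node, val in enumerate(y):
                rows.append((f"P{i:02d}", "thin" if thin else "normal",
                             j + 1, node, val))
    return pd.DataFrame(
        rows, columns=["patient_id", "region_type", "region_no", "node_id", "value"])
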