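"""Coil-configuration grids and |E| maps over the ROI.

A coil configuration is a tangent-plane position (x, y) relative to the
scalp projection of the ROI center plus an orientation angle α in
[0, 180) — induced field *magnitude* is 180°-periodic in coil rotation.
Candidate |E| maps normally come from FEM simulation; here a parametric
model provides a stand-in with the qualitative features that matter for
sampling: smooth decay with tangent distance, attenuation with cortical
depth (coil-to-cortex distance), and figure-of-eight-like orientation
sensitivity.  FEM-derived matrices can be imported through
:func:`load_candidates` and used everywhere a synthetic set can.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .geometry import ROIMesh

CONFIG_FIELDS = ("x", "y", "alpha", "standoff")


@dataclass(frozen=True)
class CoilConfig:
    """One coil placement θ = {x, y, α} (+ scalp-to-coil standoff)."""

    x: float
    y: float
    alpha: float
    standoff: float = 0.0

    def __post_init__(self):
        if not 0.0 <= self.alpha < 180.0:
            raise ValueError(f"alpha must be in [0, 180), got {self.alpha}")
        if self.standoff < 0:
            raise ValueError("standoff must be >= 0")

    def affine(self, z: float = 0.0) -> np.ndarray:
        """4x4 pose matrix: rotation about the surface normal by α, coil
        center at (x, y, z + standoff)."""
        a = np.deg2rad(self.alpha)
        m = np.eye(4)
        m[:2, :2] = [[np.cos(a), -np.sin(a)], [np.sin(a), np.cos(a)]]
        m[:3, 3] = [self.x, self.y, z + self.standoff]
        return m


@dataclass
class EFieldMap:
    """|E| magnitudes (V/m) over the K ROI compartments for one coil config."""

    values: np.ndarray
    config: CoilConfig | None = None
    intensity_scale: float = 1.0

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise ValueError("values must be a vector")
        if np.any(self.values < 0):
            raise ValueError("|E| values must be >= 0")


@dataclass
class CandidateSet:
    """The candidate dataset C: one |E| map per coil configuration."""

    maps: np.ndarray                     # (Nc, K)
    configs: list[CoilConfig]
    roi_indices: np.ndarray | None = None  # compartment ids in a parent mesh
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.maps = np.asarray(self.maps, dtype=float)
        if self.maps.ndim != 2:
            raise ValueError("maps must be (Nc, K)")
        if len(self.configs) != self.maps.shape[0]:
            raise ValueError(
                f"row count {self.maps.shape[0]} != config count {len(self.configs)}"
            )
        if self.maps.shape[0] < 1:
            raise ValueError("candidate set must not be empty")
        if np.any(~self.maps.any(axis=1)):
            raise ValueError("candidate set contains an all-zero |E| map")

    @property
    def n_candidates(self) -> int:
        return self.maps.shape[0]

    @property
    def n_compartments(self) -> int:
        return self.maps.shape[1]

    def config_frame(self):
        import pandas as pd

        return pd.DataFrame(
            [[getattr(c, f) for f in CONFIG_FIELDS] for c in self.configs],
            columns=list(CONFIG_FIELDS),
        )


def generate_coil_grid(
    search_radius: float = 30.0,
    spacing: float = 3.0,
    angle_step: float = 5.0,
    angle_max: float = 175.0,
    standoff: float = 0.0,
) -> list[CoilConfig]:
    """Candidate coil configurations on a square lattice × orientation fan.

    Positions are the axis-aligned lattice points with |(x, y)| ≤
    ``search_radius`` (origin included); orientations run 0, ``angle_step``,
    … up to ``angle_max`` < 180°, since magnitude maps repeat at 180°.

    Defaults (30 mm, 3 mm, 5°, 175°) give 317 × 36 = 11,412 configurations.
    """
    if search_radius < 0:
        raise ValueError("search_radius must be >= 0")
    if spacing <= 0:
        raise ValueError("spacing must be > 0")
    if not 0 < angle_step <= angle_max:
        raise ValueError("need 0 < angle_step <= angle_max")
    if angle_max >= 180.0:
        raise ValueError("orientations at and beyond 180 degrees are excluded")
    n = int(np.floor(search_radius / spacing))
    ii = np.arange(-n, n + 1)
    xx, yy = np.meshgrid(ii * spacing, ii * spacing)
    keep = np.hypot(xx, yy) <= search_radius
    positions = np.column_stack([xx[keep], yy[keep]])
    # deterministic ordering: by y then x
    order = np.lexsort((positions[:, 0], positions[:, 1]))
    positions = positions[order]
    angles = np.arange(0.0, angle_max + 0.5 * angle_step, angle_step)
    angles = angles[angles <= angle_max]
    return [
        CoilConfig(x=float(px), y=float(py), alpha=float(a), standoff=standoff)
        for px, py in positions
        for a in angles
    ]


@dataclass(frozen=True)
class FieldModel:
    """Parameters of the parametric |E| model.

    peak_amplitude : |E| (V/m) at the 1%-MSO reference directly under the
        coil at zero depth.
    focality : Gaussian tangent-plane spread λ (mm) of the local field
        footprint.
    depth_decay : exponential decay length δ (mm) of |E| with coil-to-cortex
        distance (compartment depth + standoff).
    anisotropy : modulation strength β of the 180°-periodic orientation term.
    shadowing_onset, shadowing_width, shadowing_max : sigmoidal collapse of
        the deep compartments' field *pattern* onto the global
        coil-proximity mode.  Superficial and mid-depth cortex sees focal
        fields that identify compartments individually; in the sulcal
        depths (beyond ``shadowing_onset`` mm) fields are volume-conducted
        and nearly co-linear across compartments, as in FEM simulations.
        ``shadowing_max = 0`` disables the effect (pure local model).
    global_spread : Gaussian width (mm) of the global coil-proximity mode.
    """

    peak_amplitude: float = 1.0
    focality: float = 14.0
    depth_decay: float = 15.0
    anisotropy: float = 0.3
    shadowing_onset: float = 8.0
    shadowing_width: float = 1.5
    shadowing_max: float = 0.9
    global_spread: float = 20.0


def preferred_directions(mesh: ROIMesh) -> np.ndarray:
    """Per-compartment preferred field direction φ_k (degrees, mod 180).

    Taken along the local fold contour: perpendicular to the in-plane
    gradient of the height field estimated from the triangle's vertical
    normal component.  Flat regions default to 0° (the fold axis).
    """
    v = mesh.vertices[mesh.triangles]
    n = np.cross(v[:, 1] - v[:, 0], v[:, 2] - v[:, 0])
    # in-plane height gradient is -(-nx/nz, -ny/nz); contour dir is its perp
    with np.errstate(divide="ignore", invalid="ignore"):
        gx = -n[:, 0] / n[:, 2]
        gy = -n[:, 1] / n[:, 2]
    phi = np.degrees(np.arctan2(gx, -gy)) % 180.0  # perp of (gx, gy)
    flat = np.hypot(gx, gy) < 1e-9
    phi[flat] = 0.0
    return phi


def _field_values(
    xy: np.ndarray,
    alpha: np.ndarray,
    standoff: np.ndarray,
    mesh: ROIMesh,
    model: FieldModel,
    indices: np.ndarray | None = None,
) -> np.ndarray:
    centers = mesh.compartment_centers
    depth = mesh.depth
    phi = preferred_directions(mesh)
    if indices is not None:
        centers, depth, phi = centers[indices], depth[indices], phi[indices]
    rho2 = (
        (centers[None, :, 0] - xy[:, None, 0]) ** 2
        + (centers[None, :, 1] - xy[:, None, 1]) ** 2
    )
    radial = np.exp(-rho2 / (2.0 * model.focality**2))
    ang = 1.0 + model.anisotropy * np.cos(
        2.0 * np.deg2rad(alpha[:, None] - phi[None, :])
    )
    local = np.clip(radial * ang, 0.0, None)
    if model.shadowing_max > 0:
        from scipy.special import expit

        # coil (x, y) is already relative to the ROI-center scalp projection,
        # so the global proximity mode is a kernel in |coil offset|; being
        # volume-conducted it carries no orientation sensitivity
        g = np.exp(
            -(xy[:, 0] ** 2 + xy[:, 1] ** 2) / (2.0 * model.global_spread**2)
        )[:, None]
        eta = model.shadowing_max * expit(
            (depth - model.shadowing_onset) / model.shadowing_width
        )
        local = (1.0 - eta[None, :]) * local + eta[None, :] * g
    attn = np.exp(-(depth[None, :] + standoff[:, None]) / model.depth_decay)
    return model.peak_amplitude * local * attn


def synthetic_efield(
    config: CoilConfig,
    mesh: ROIMesh,
    model: FieldModel = FieldModel(),
    indices: np.ndarray | None = None,
) -> EFieldMap:
    """|E| map of one coil configuration under the parametric field model.

    ``values_k = A · [(1-η_k) e^{-ρ_k²/2λ²} (1 + β cos 2(α - φ_k))
    + η_k g(x,y)] · e^{-(depth_k+standoff)/δ}`` clipped at 0,
    with ρ_k the tangent-plane coil-to-compartment distance, g the global
    (orientation-insensitive) coil-proximity kernel and η_k the sigmoidal
    share of the global mode beyond the shadowing onset depth.
    180°-periodic in α; with shadowing disabled (η ≡ 0) strictly
    decreasing in both ρ and depth.
    """
    values = _field_values(
        np.array([[config.x, config.y]]),
        np.array([config.alpha]),
        np.array([config.standoff]),
        mesh,
        model,
        indices,
    )[0]
    return EFieldMap(values=values, config=config)


def build_candidate_set(
    mesh: ROIMesh,
    configs: Sequence[CoilConfig],
    model: FieldModel = FieldModel(),
    roi_indices: np.ndarray | None = None,
) -> CandidateSet:
    """Vectorised synthetic |E| maps for a whole coil grid."""
    configs = list(configs)
    xy = np.array([[c.x, c.y] for c in configs])
    alpha = np.array([c.alpha for c in configs])
    standoff = np.array([c.standoff for c in configs])
    maps = _field_values(xy, alpha, standoff, mesh, model, roi_indices)
    return CandidateSet(maps=maps, configs=configs, roi_indices=roi_indices)


def scale_to_intensity(obj, percent_mso: float):
    """Scale |E| linearly from the 1%-MSO reference to ``percent_mso``.

    FEM |E| is linear in the coil-current rate of change, so maps simulated
    at the 1%-MSO reference are multiplied by the stimulation intensity.
    """
    if percent_mso < 0:
        raise ValueError("percent_mso must be >= 0")
    if isinstance(obj, EFieldMap):
        return EFieldMap(
            values=obj.values * percent_mso,
            config=obj.config,
            intensity_scale=obj.intensity_scale * percent_mso,
        )
    if isinstance(obj, CandidateSet):
        out = CandidateSet(
            maps=obj.maps * percent_mso,
            configs=list(obj.configs),
            roi_indices=obj.roi_indices,
            meta=dict(obj.meta),
        )
        out.meta["intensity_scale"] = out.meta.get("intensity_scale", 1.0) * percent_mso
        return out
    raise TypeError("expected EFieldMap or CandidateSet")


def cylindrical_roi_indices(
    mesh: ROIMesh, radius: float = 20.0, center: np.ndarray | None = None
) -> np.ndarray:
    """Compartments whose center lies within the vertical cylinder (closed
    boundary, ≤ radius) about the ROI-center axis; sorted index list."""
    if radius <= 0:
        raise ValueError("radius must be > 0")
    c = mesh.roi_center if center is None else np.asarray(center, dtype=float)
    d = np.hypot(
        mesh.compartment_centers[:, 0] - c[0],
        mesh.compartment_centers[:, 1] - c[1],
    )
    idx = np.flatnonzero(d <= radius)
    if idx.size == 0:
        raise ValueError("cylindrical ROI selects no compartments")
    return np.sort(idx)


def extract_cylindrical_roi(
    full_map: np.ndarray | EFieldMap,
    mesh: ROIMesh,
    radius: float = 20.0,
    center: np.ndarray | None = None,
) -> tuple[EFieldMap, np.ndarray]:
    """Restrict a per-compartment map to the cylindrical analysis ROI.

    Returns the restricted map and the (sorted, call-stable) kept indices.
    """
    idx = cylindrical_roi_indices(mesh, radius, center)
    if isinstance(full_map, EFieldMap):
        return (
            EFieldMap(
                values=full_map.values[idx],
                config=full_map.config,
                intensity_scale=full_map.intensity_scale,
            ),
            idx,
        )
    values = np.asarray(full_map, dtype=float)
    return EFieldMap(values=values[idx]), idx


SCHEMA_VERSION = 1


def save_candidates(cands: CandidateSet, path: str) -> None:
    """Persist a candidate set to HDF5 (``.h5``) or CSV (``.csv``).

    The CSV layout is one row per configuration: the config columns followed
    by ``E_0 … E_{K-1}``, written at full float precision (lossless
    round-trip for float64).
    """
    path = str(path)
    cfg = np.array(
        [[getattr(c, f) for f in CONFIG_FIELDS] for c in cands.configs]
    )
    if path.endswith((".h5", ".hdf5")):
        import h5py

        with h5py.File(path, "w") as f:
            f.attrs["schema_version"] = SCHEMA_VERSION
            f.create_dataset("maps", data=cands.maps)
            f.create_dataset("configs", data=cfg)
            f.attrs["config_fields"] = ",".join(CONFIG_FIELDS)
            if cands.roi_indices is not None:
                f.create_dataset("roi_indices", data=cands.roi_indices)
    elif path.endswith(".csv"):
        K = cands.n_compartments
        header = list(CONFIG_FIELDS) + [f"E_{k}" for k in range(K)]
        with open(path, "w", newline="") as f:
            w = csv.writer(f)
            w.writerow([f"# schema_version={SCHEMA_VERSION}"])
            w.writerow(header)
            for row_cfg, row_map in zip(cfg, cands.maps):
                w.writerow(
                    [format(v, ".17g") for v in row_cfg]
                    + [format(v, ".17g") for v in row_map]
                )
    else:
        raise ValueError(f"unsupported candidate file type: {path}")


def load_candidates(path: str) -> CandidateSet:
    """Load a candidate set written by :func:`save_candidates` (or an
    externally authored file in the same layout)."""
    path = str(path)
    if path.endswith((".h5", ".hdf5")):
        import h5py

        with h5py.File(path, "r") as f:
            maps = f["maps"][...]
            cfg = f["configs"][...]
            roi = f["roi_indices"][...] if "roi_indices" in f else None
        if maps.ndim != 2 or cfg.shape[0] != maps.shape[0]:
            raise ValueError("maps/configs shape mismatch in candidate file")
        configs = [CoilConfig(*row) for row in cfg]
        return CandidateSet(maps=maps, configs=configs, roi_indices=roi)
    if path.endswith(".csv"):
        with open(path, newline="") as f:
            rows = list(csv.reader(f))
        if rows and rows[0] and rows[0][0].startswith("#"):
            rows = rows[1:]
        header, data = rows[0], rows[1:]
        ncfg = len(CONFIG_FIELDS)
        if header[:ncfg] != list(CONFIG_FIELDS):
            raise ValueError("unexpected candidate CSV header")
        if not data:
            raise ValueError("candidate file contains no configurations")
        arr = np.array([[float(v) for v in r] for r in data])
        configs = [CoilConfig(*row) for row in arr[:, :ncfg]]
        return CandidateSet(maps=arr[:, ncfg:], configs=configs)
    raise ValueError(f"unsupported candidate file type: {path}")


def export_affines(cands: CandidateSet, path: str, z: float = 0.0) -> None:
    """Write the 4×4 pose matrix of every configuration as flat CSV rows
    (config index + 16 row-major entries) for neuronavigation hand-off."""
    with open(str(path), "w", newline="") as f:
        w = csv.writer(f)
        w.writerow(["config_id"] + [f"m{i}{j}" for i in range(4) for j in range(4)])
        for i, c in enumerate(cands.configs):
            w.writerow([i] + [format(v, ".17g") for v in c.affine(z).ravel()])
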