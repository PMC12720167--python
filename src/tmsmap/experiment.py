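"""End-to-end sampling-efficiency experiments on synthetic cortex.

Two studies mirror the method-evaluation protocol:

* Placement sweep — put the muscle representation at every ROI compartment,
  simulate one noisy MEP per candidate of a dense grid, fit the R² map and
  record its overlap score with the generating MGM.  Shows how mapping
  quality depends on the cortical location (crown vs. wall vs. fundus).
* Subsampling comparison — for each of several MGM placements and paired
  (sampling seed, noise seed) runs, draw FPS and random sample orders from
  the same candidate set, simulate MEPs with a shared per-candidate noise
  stream, evaluate the score curve every ``stride`` samples against a
  reference map, and derive n95 (censored at the budget).

All runs are deterministic given the config.  Noise streams attach to the
candidate index, so both samplers see identical noise for identical
configurations (paired-run variance reduction).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd

from .efield import (
    CandidateSet,
    FieldModel,
    build_candidate_set,
    cylindrical_roi_indices,
    generate_coil_grid,
    scale_to_intensity,
)
from .geometry import (
    GeodesicMatrix,
    ROIMesh,
    build_synthetic_roi,
    depth_bands,
    geodesic_distance_matrix,
)
from .mapping import (
    compute_r2_map,
    fitting_score,
    samples_to_criterion,
    score_curve,
)
from .mep import MEPModelParams, build_mgm, calibrate_params, candidate_strengths, sigmoid_response
from .mep import noise_std as _noise_std
from .sampling import fps_sample, random_sample

PLACEMENTS = ("crown-center", "wall-center", "crown-edge")


@dataclass
class ExperimentConfig:
    """Study conditions for the synthetic experiments.

    Geometry defaults give a 30 mm folded patch whose 20 mm analysis ROI
    holds ≈1,000 compartments; the default coil grid (30 mm search radius,
    5 mm spacing, 10° steps) yields ≈2,000 candidate configurations.
    """

    # geometry
    n_compartments: int = 2200
    fold_amplitude: float = 6.0
    fold_wavelength: float = 12.0
    patch_radius: float = 30.0
    roi_radius: float = 20.0
    mesh_seed: int = 0
    geodesic_ring: int = 2
    # candidate grid (coil search)
    search_radius: float = 30.0
    spacing: float = 5.0
    angle_step: float = 10.0
    angle_max: float = 175.0
    intensity_percent: float = 50.0
    field: FieldModel = field(default_factory=FieldModel)
    # MEP model
    sigma: float = 5.0
    ymax: float = 1.0
    slope: float | None = None
    x0: float | None = None
    noise_p: float = 0.1
    # placements
    placements: tuple[str, ...] = PLACEMENTS
    # sampling / evaluation
    budget: int = 150
    stride: int = 2
    n_min: int = 4
    threshold: float = 0.95
    sampling_seeds: tuple[int, ...] = tuple(range(10))
    noise_seeds: tuple[int, ...] = tuple(range(10))
    reference: str = "all-samples"  # or "mgm", "hr"

    def __post_init__(self):
        if not self.sampling_seeds or not self.noise_seeds:
            raise ValueError("seed lists must be non-empty")
        if not 0.0 < self.threshold < 1.0:
            raise ValueError("threshold must be in (0, 1)")
        if self.reference not in ("all-samples", "mgm", "hr"):
            raise ValueError(f"unknown reference mode {self.reference!r}")

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


def small_config(**overrides) -> ExperimentConfig:
    """A reduced configuration for quick runs and smoke tests."""
    defaults = dict(
        n_compartments=700,
        spacing=10.0,
        angle_step=15.0,
        budget=60,
        sampling_seeds=(0, 1),
        noise_seeds=(0, 1),
    )
    defaults.update(overrides)
    return ExperimentConfig(**defaults)


@dataclass
class ExperimentAssets:
    """Precomputed geometry + candidate matrices shared by all runs."""

    mesh: ROIMesh
    roi_indices: np.ndarray
    gd: GeodesicMatrix           # restricted to ROI compartments
    bands: np.ndarray            # per-ROI-compartment crown/wall/fundus
    candidates: CandidateSet     # maps over ROI compartments
    placements: dict[str, int]   # placement name -> ROI compartment index


def select_placement(
    mesh: ROIMesh, roi_indices: np.ndarray, bands: np.ndarray, which: str
) -> int:
    """Pick the ROI compartment for a named muscle-representation placement.

    crown-center / wall-center: the crown- or wall-band compartment closest
    to the ROI axis; crown-edge: the crown compartment farthest from it.
    An explicit integer is accepted verbatim.
    """
    if isinstance(which, (int, np.integer)):
        return int(which)
    centers = mesh.compartment_centers[roi_indices]
    r = np.hypot(
        centers[:, 0] - mesh.roi_center[0], centers[:, 1] - mesh.roi_center[1]
    )
    band = {"crown-center": "crown", "wall-center": "wall", "crown-edge": "crown"}.get(which)
    if band is None:
        raise ValueError(f"unknown placement {which!r}")
    mask = bands == band
    if not mask.any():
        raise ValueError(f"no compartments in band {band!r}")
    rr = np.where(mask, r, -np.inf if which == "crown-edge" else np.inf)
    return int(np.argmax(rr) if which == "crown-edge" else np.argmin(rr))


def build_assets(cfg: ExperimentConfig) -> ExperimentAssets:
    """Generate mesh, ROI geodesics and the candidate |E| matrix."""
    mesh = build_synthetic_roi(
        n_compartments=cfg.n_compartments,
        fold_amplitude=cfg.fold_amplitude,
        fold_wavelength=cfg.fold_wavelength,
        radius=cfg.patch_radius,
        seed=cfg.mesh_seed,
    )
    roi_idx = cylindrical_roi_indices(mesh, radius=cfg.roi_radius)
    gd_full = geodesic_distance_matrix(mesh, ring=cfg.geodesic_ring)
    gd = GeodesicMatrix(dist=gd_full.dist[np.ix_(roi_idx, roi_idx)])
    bands = depth_bands(mesh)[roi_idx]
    configs = generate_coil_grid(
        search_radius=cfg.search_radius,
        spacing=cfg.spacing,
        angle_step=cfg.angle_step,
        angle_max=cfg.angle_max,
    )
    cands = build_candidate_set(mesh, configs, cfg.field, roi_indices=roi_idx)
    cands = scale_to_intensity(cands, cfg.intensity_percent)
    placements = {
        p: select_placement(mesh, roi_idx, bands, p) for p in cfg.placements
    }
    return ExperimentAssets(
        mesh=mesh, roi_indices=roi_idx, gd=gd, bands=bands,
        candidates=cands, placements=placements,
    )


def _placement_model(cfg: ExperimentConfig, assets: ExperimentAssets, kmax: int):
    mgm = build_mgm(assets.gd, kmax, cfg.sigma)
    params = calibrate_params(
        mgm, assets.candidates, ymax=cfg.ymax, slope=cfg.slope,
        noise_p=cfg.noise_p, x0=cfg.x0,
    )
    return mgm, params


def _noisy_meps_all(mgm, candidates, params, noise_seed) -> np.ndarray:
    """Noisy MEP per candidate index (the shared paired-run noise stream)."""
    x = candidate_strengths(mgm, candidates)
    y = sigmoid_response(x, params)
    z = np.random.default_rng(noise_seed).standard_normal(len(x))
    return np.maximum(0.0, y + _noise_std(x, params) * z)


def run_placement_sweep(
    cfg: ExperimentConfig, assets: ExperimentAssets | None = None
) -> pd.DataFrame:
    """Mapping quality as a function of muscle-representation location.

    For every ROI compartment k: build the MGM at k, simulate one noisy MEP
    per candidate of the full grid, fit the R² map, and score it against
    the generating MGM.  Returns a tidy frame (compartment, depth, band,
    score, peak_distance).
    """
    assets = assets or build_assets(cfg)
    K = len(assets.roi_indices)
    noise_seed = cfg.noise_seeds[0]
    rows = []
    for k in range(K):
        mgm, params = _placement_model(cfg, assets, k)
        meps = _noisy_meps_all(mgm, assets.candidates, params, noise_seed)
        r2map = compute_r2_map(
            np.arange(assets.candidates.n_candidates), assets.candidates, meps
        )
        score = fitting_score(mgm, r2map.r2) if r2map.r2.any() else 0.0
        rows.append(
            {
                "compartment": k,
                "depth": assets.mesh.depth[assets.roi_indices[k]],
                "band": assets.bands[k],
                "score": score,
                "peak_distance": float(assets.gd.dist[k, r2map.peak]),
            }
        )
    out = pd.DataFrame(rows)
    out.attrs["config_hash"] = cfg.config_hash()
    return out


@dataclass
class ExperimentResult:
    """Per-run score curves, the n95 table, and the generating config."""

    records: pd.DataFrame   # method, placement, sampling_seed, noise_seed, n, score, peak_distance
    n95: pd.DataFrame       # method, placement, sampling_seed, noise_seed, n95, censored
    config: ExperimentConfig


def _reference_map(cfg, assets, mgm, meps_all):
    if cfg.reference == "mgm":
        return mgm.m
    # "all-samples": fit on every candidate of this grid with this noise
    # stream; "hr" differs only in the grid the config describes.
    r2 = compute_r2_map(
        np.arange(assets.candidates.n_candidates), assets.candidates, meps_all
    )
    return r2.r2


def run_subsampling_experiment(
    cfg: ExperimentConfig, assets: ExperimentAssets | None = None
) -> ExperimentResult:
    """FPS-vs-random sample-efficiency comparison.

    For each placement × (sampling seed × noise seed) pair, both samplers
    draw ``budget`` configurations from the shared candidate set.  Score
    (and peak-distance) curves are evaluated every ``stride`` samples
    against the configured reference map; evaluation stops once the score
    exceeds the threshold, which fixes n95.
    """
    assets = assets or build_assets(cfg)
    nc = assets.candidates.n_candidates
    if cfg.budget > nc:
        raise ValueError(f"budget {cfg.budget} exceeds Nc={nc}")

    # sample orders depend only on the candidate set -> shared across
    # placements and noise seeds
    orders = {}
    for ss in cfg.sampling_seeds:
        orders[("fps", ss)] = fps_sample(assets.candidates, cfg.budget, seed=ss).order
        orders[("random", ss)] = random_sample(assets.candidates, cfg.budget, seed=ss).order

    rec_rows, n95_rows = [], []
    for placement in cfg.placements:
        kmax = assets.placements[placement]
        mgm, params = _placement_model(cfg, assets, kmax)
        for ns in cfg.noise_seeds:
            meps_all = _noisy_meps_all(mgm, assets.candidates, params, ns)
            ref = _reference_map(cfg, assets, mgm, meps_all)
            for ss in cfg.sampling_seeds:
                for method in ("fps", "random"):
                    curve = score_curve(
                        orders[(method, ss)], assets.candidates, meps_all,
                        ref, gd=assets.gd, stride=cfg.stride,
                        threshold=cfg.threshold, n_min=cfg.n_min,
                        budget=cfg.budget,
                    )
                    for r in curve:
                        rec_rows.append(
                            dict(method=method, placement=placement,
                                 sampling_seed=ss, noise_seed=ns, **r)
                        )
                    n95 = samples_to_criterion(
                        [(r["n"], r["score"]) for r in curve],
                        threshold=cfg.threshold, budget=cfg.budget,
                    )
                    n95_rows.append(
                        dict(method=method, placement=placement,
                             sampling_seed=ss, noise_seed=ns,
                             n95=n95.n, censored=n95.censored)
                    )
    records = pd.DataFrame(rec_rows)
    n95_df = pd.DataFrame(n95_rows)
    records.attrs["config_hash"] = cfg.config_hash()
    n95_df.attrs["config_hash"] = cfg.config_hash()
    return ExperimentResult(records=records, n95=n95_df, config=cfg)


def summarize(result: ExperimentResult | pd.DataFrame) -> pd.DataFrame:
    """Per method × placement summary of n95.

    Censored runs are included at the budget value (and counted).
    Percentiles use linear interpolation between closest ranks.
    """
    n95 = result.n95 if isinstance(result, ExperimentResult) else result
    if len(n95) == 0:
        raise ValueError("empty experiment result")
    rows = []
    for (method, placement), g in n95.groupby(["method", "placement"], sort=True):
        v = g["n95"].to_numpy(dtype=float)
        rows.append(
            {
                "method": method,
                "placement": placement,
                "n_runs": len(v),
                "mean": v.mean(),
                "std": v.std(ddof=1) if len(v) > 1 else 0.0,
                "median": float(np.percentile(v, 50)),
                "p5": float(np.percentile(v, 5)),
                "p95": float(np.percentile(v, 95)),
                "censored": int(g["censored"].sum()),
            }
        )
    return pd.DataFrame(rows)


def paired_n95_ratios(n95: pd.DataFrame) -> pd.DataFrame:
    """Per paired run, the ratio n95(FPS) / n95(random)."""
    keys = ["placement", "sampling_seed", "noise_seed"]
    wide = n95.pivot_table(index=keys, columns="method", values="n95").reset_index()
    wide["ratio"] = wide["fps"] / wide["random"]
    return wide
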