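"""Synthetic motor evoked potential (MEP) generation.

The generative model assumes a spatially restricted muscle representation
in motor cortex, discretized over the ROI compartments:

1. Excitability of compartment k is a geodesic Gaussian centred on the most
   excitable compartment k_max:  m_k = (1/σ√2π) exp(-d(k, k_max)²/2σ²),
   with d the geodesic distance on the cortex.  The vector m is the MEP
   generation map (MGM).
2. Stimulation strength for a coil configuration is the inner product of
   the MGM with its |E| map:  x = ⟨M, E⟩.
3. The clean MEP amplitude follows a sigmoid input–output curve
   y = y_max / (1 + exp(-k(x - x0))) with ψ = {x0, y_max, k}.
4. Heteroscedastic Gaussian noise, modulated by the same sigmoid factor so
   its standard deviation grows with stimulation strength and saturates at
   P:  ε ~ P/(1 + exp(-k(x - x0))) · N(0, 1);  ỹ = max(0, y + ε).

MEP waveform morphology and latency are deliberately not modelled.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import expit

from .efield import CandidateSet, EFieldMap
from .geometry import GeodesicMatrix


@dataclass
class MuscleRepMap:
    """MEP generation map: per-compartment excitability m, centre k_max,
    geodesic Gaussian width sigma (mm)."""

    m: np.ndarray
    kmax: int
    sigma: float

    def __post_init__(self):
        self.m = np.asarray(self.m, dtype=float)
        if np.any(self.m < 0):
            raise ValueError("excitabilities must be >= 0")
        if int(np.argmax(self.m)) != self.kmax:
            raise ValueError("argmax(m) must be kmax")


@dataclass(frozen=True)
class MEPModelParams:
    """Sigmoid I/O parameters ψ = {x0, ymax, slope} and noise amplitude P.

    x0 : turning point on the stimulation-strength axis.
    ymax : saturation amplitude (mV).
    slope : sigmoid steepness (per stimulation-strength unit).
    noise_p : asymptotic noise standard deviation P (mV).
    """

    x0: float
    ymax: float
    slope: float
    noise_p: float = 0.0

    def __post_init__(self):
        if self.ymax <= 0:
            raise ValueError("ymax must be > 0")
        if self.slope <= 0:
            raise ValueError("slope must be > 0")
        if self.noise_p < 0:
            raise ValueError("noise_p must be >= 0")


def build_mgm(gd: GeodesicMatrix, kmax: int, sigma: float) -> MuscleRepMap:
    """Gaussian muscle representation centred at compartment ``kmax``.

    Applies the Gaussian density literally per compartment (no
    renormalisation after discretization); any mass deficit is absorbed by
    the x0 calibration of the MEP model.
    """
    if sigma <= 0:
        raise ValueError("sigma must be > 0")
    K = gd.n_compartments
    if not 0 <= kmax < K:
        raise ValueError("kmax out of range")
    d = gd.dist[kmax]
    m = np.exp(-0.5 * (d / sigma) ** 2) / (sigma * np.sqrt(2.0 * np.pi))
    return MuscleRepMap(m=m, kmax=int(kmax), sigma=float(sigma))


def stimulation_strength(mgm: MuscleRepMap, efield) -> float:
    """Effective stimulation strength x = ⟨M, E⟩ for one |E| map."""
    e = efield.values if isinstance(efield, EFieldMap) else np.asarray(efield, float)
    if e.shape != mgm.m.shape:
        raise ValueError(f"length mismatch: MGM {mgm.m.shape} vs |E| {e.shape}")
    return float(mgm.m @ e)


def sigmoid_response(x, params: MEPModelParams):
    """Clean MEP amplitude y(x) = ymax / (1 + exp(-slope (x - x0)))."""
    x = np.asarray(x, dtype=float)
    out = params.ymax * expit(params.slope * (x - params.x0))
    return float(out) if out.ndim == 0 else out


def noise_std(x, params: MEPModelParams):
    """Pre-clip noise standard deviation P / (1 + exp(-slope (x - x0)))."""
    x = np.asarray(x, dtype=float)
    out = params.noise_p * expit(params.slope * (x - params.x0))
    return float(out) if out.ndim == 0 else out


def noisy_mep(x, params: MEPModelParams, seed: int | None = None,
              rng: np.random.Generator | None = None):
    """Noisy MEP amplitude ỹ = max(0, y(x) + ε), ε ~ noise_std(x)·N(0,1).

    Zero-clamping happens after noise addition only; the clean response is
    already positive.  Deterministic given ``seed``.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    x = np.asarray(x, dtype=float)
    y = sigmoid_response(x, params)
    eps = noise_std(x, params) * rng.standard_normal(size=x.shape)
    out = np.maximum(0.0, y + eps)
    return float(out) if np.ndim(out) == 0 else out


def candidate_strengths(mgm: MuscleRepMap, candidates) -> np.ndarray:
    """x = ⟨M, E_c⟩ for every candidate |E| map (vectorised inner product)."""
    maps = candidates.maps if isinstance(candidates, CandidateSet) else np.asarray(candidates)
    if maps.shape[1] != mgm.m.shape[0]:
        raise ValueError(
            f"candidate maps have K={maps.shape[1]} but MGM has K={mgm.m.shape[0]}"
        )
    return maps @ mgm.m


def simulate_meps(
    mgm: MuscleRepMap,
    candidates,
    params: MEPModelParams,
    noise_seed: int | None = None,
    indices: np.ndarray | None = None,
):
    """One stimulation record per candidate (or per requested subset).

    Noise is drawn once per *candidate index* from ``noise_seed`` and then
    subset — so paired runs that share a noise seed see identical noise for
    identical configurations regardless of selection order or method.

    Returns a DataFrame with columns config_id, x, y_clean, y_noisy.
    """
    import pandas as pd

    x = candidate_strengths(mgm, candidates)
    y = sigmoid_response(x, params)
    rng = np.random.default_rng(noise_seed)
    eps = noise_std(x, params) * rng.standard_normal(size=x.shape)
    y_noisy = np.maximum(0.0, y + eps)
    ids = np.arange(len(x))
    if indices is not None:
        indices = np.asarray(indices, dtype=np.int64)
        ids, x, y, y_noisy = ids[indices], x[indices], y[indices], y_noisy[indices]
    return pd.DataFrame(
        {"config_id": ids, "x": x, "y_clean": y, "y_noisy": y_noisy}
    )


def calibrate_params(
    mgm: MuscleRepMap,
    candidates,
    ymax: float = 1.0,
    slope: float | None = None,
    noise_p: float = 0.0,
    x0: float | None = None,
) -> MEPModelParams:
    """Choose ψ so the sigmoid spans the dynamic range of the candidate set.

    x0 defaults to the median stimulation strength of a dense noise-free
    sweep over all candidates; the slope defaults to 6 / (q90 - q10) of the
    strength distribution, putting the central 80% of candidates across the
    rising phase of the sigmoid.
    """
    x = candidate_strengths(mgm, candidates)
    if x0 is None:
        x0 = float(np.median(x))
    if slope is None:
        q10, q90 = np.percentile(x, [10, 90])
        spread = max(q90 - q10, 1e-12)
        slope = 6.0 / spread
    return MEPModelParams(x0=x0, ymax=ymax, slope=float(slope), noise_p=noise_p)
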