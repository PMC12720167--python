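"""Trial-level EMG processing: MEP amplitude extraction and rejection rules.

MEP amplitude is the peak-to-peak voltage inside a post-stimulus window
(default 18–35 ms, boundaries inclusive).  Trials with pre-stimulus muscle
activity — peak-to-peak strictly exceeding 50 µV within the 100 ms before
the pulse — are rejected.  A synthetic trace generator produces test
fixtures with a controlled biphasic deflection.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

MEP_WINDOW_MS = (18.0, 35.0)
PREACTIVATION_THRESHOLD_UV = 50.0
PREACTIVATION_WINDOW_MS = 100.0


@dataclass
class EMGTrace:
    """Single-trial EMG voltage series (µV) with the TMS pulse position."""

    samples: np.ndarray
    sampling_rate: float          # Hz
    stimulus_index: int

    def __post_init__(self):
        self.samples = np.asarray(self.samples, dtype=float)
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be > 0")
        if not 0 <= self.stimulus_index < len(self.samples):
            raise ValueError("stimulus_index outside the trace")

    def _ms_to_samples(self, ms: float) -> int:
        return int(round(ms * self.sampling_rate / 1000.0))


def peak_to_peak_amplitude(
    trace: EMGTrace,
    window_start: float = MEP_WINDOW_MS[0],
    window_end: float = MEP_WINDOW_MS[1],
) -> float:
    """MEP peak-to-peak amplitude (µV) in [stim+start, stim+end] ms.

    Window boundaries are inclusive (timestamps rounded to the nearest
    sample).  Invariant to DC offset.
    """
    if window_start >= window_end:
        raise ValueError("window_start must be < window_end")
    i0 = trace.stimulus_index + trace._ms_to_samples(window_start)
    i1 = trace.stimulus_index + trace._ms_to_samples(window_end)
    if i0 < 0 or i1 >= len(trace.samples):
        raise ValueError("MEP window extends outside the trace")
    seg = trace.samples[i0 : i1 + 1]
    return float(seg.max() - seg.min())


def preactivation_check(
    trace: EMGTrace,
    threshold: float = PREACTIVATION_THRESHOLD_UV,
    pre_window: float = PREACTIVATION_WINDOW_MS,
) -> bool:
    """True if the trial is kept; False if rejected for pre-activation.

    Rejects iff the pre-stimulus peak-to-peak over [stim - pre_window, stim)
    strictly exceeds the threshold (a p2p of exactly the threshold is kept).
    Raising the threshold never converts a kept trial into a rejected one.
    """
    n_pre = trace._ms_to_samples(pre_window)
    i0 = trace.stimulus_index - n_pre
    if i0 < 0 or n_pre < 1:
        raise ValueError("insufficient pre-stimulus data for the check")
    seg = trace.samples[i0 : trace.stimulus_index]
    return float(seg.max() - seg.min()) <= threshold


def synth_emg_trace(
    mep_amplitude: float,
    latency: float = 25.0,
    pre_noise_p2p: float = 0.0,
    sampling_rate: float = 5000.0,
    seed: int | None = None,
    pre_ms: float = 120.0,
    post_ms: float = 80.0,
) -> EMGTrace:
    """Synthetic single-trial trace with one biphasic MEP deflection.

    The deflection is +A/2 at ``stimulus + latency`` and -A/2 two samples
    later, so noise-free extraction returns ``mep_amplitude`` exactly
    whenever the whole deflection lies inside the extraction window.
    Baseline Gaussian noise is rescaled so the pre-stimulus peak-to-peak
    equals ``pre_noise_p2p`` exactly.  Deterministic for a fixed seed.
    """
    if latency < 0:
        raise ValueError("latency must be >= 0")
    n_pre = int(round(pre_ms * sampling_rate / 1000.0))
    n_post = int(round(post_ms * sampling_rate / 1000.0))
    n = n_pre + n_post
    samples = np.zeros(n)
    stim = n_pre
    if pre_noise_p2p > 0:
        rng = np.random.default_rng(seed)
        noise = rng.standard_normal(n)
        span = noise[:stim].max() - noise[:stim].min()
        samples += noise * (pre_noise_p2p / span)
        samples[stim:] *= 0.05  # near-silent post-stimulus baseline
    i = stim + int(round(latency * sampling_rate / 1000.0))
    if i + 2 < n:
        samples[i] += mep_amplitude / 2.0
        samples[i + 2] -= mep_amplitude / 2.0
    return EMGTrace(samples=samples, sampling_rate=sampling_rate, stimulus_index=stim)


def extract_trials(traces, **kwargs):
    """Batch extraction: per-trial amplitude and pre-activation decision.

    Returns a DataFrame (trial_id, p2p_uv, rejected_preactivation).
    """
    import pandas as pd

    rows = []
    for i, tr in enumerate(traces):
        rows.append(
            {
                "trial_id": i,
                "p2p_uv": peak_to_peak_amplitude(tr, **kwargs),
                "rejected_preactivation": not preactivation_check(tr),
            }
        )
    return pd.DataFrame(rows)
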