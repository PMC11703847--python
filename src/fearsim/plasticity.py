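"""Pair-based STDP with soft weight bounds.

The weight update follows the classical exponential pairing rule with
soft bounds: for a presynaptic spike preceding a postsynaptic spike
(``dt = t_pre - t_post <= 0``) the weight is potentiated toward ``w_max``,

    dw = (w_max - w) * A_plus * exp(dt / tau_plus) / tau_w ,

and for a postsynaptic spike preceding a presynaptic one (``dt > 0``) it
is depressed toward ``w_min``,

    dw = (w_min - w) * |A_minus| * exp(-dt / tau_minus) / tau_w .

Both branches decay exponentially with the separation ``|dt|`` (measured
in integration steps) and vanish at the bounds, so weights can never
leave ``[w_min, w_max]``.  Pairing is nearest-neighbour: each spike is
paired only with the partner neuron's most recent spike.  By default the
potentiation amplitude is three times the depression amplitude.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ConfigError, DimensionError

__all__ = [
    "STDPParams",
    "SpikePairing",
    "NO_SPIKE",
    "PAIRING_CUTOFF_STEPS",
    "stdp_delta",
    "update_projection",
    "clip_weights",
]

#: Sentinel for "this neuron has never spiked" in last-spike-time vectors.
NO_SPIKE: int = -(2**31)

#: pairings separated by more than this many steps are treated as having
#: no partner: at the default time constants their window factor is
#: exp(-10) or smaller
PAIRING_CUTOFF_STEPS: int = 100


@dataclass(frozen=True)
class STDPParams:
    """Amplitudes, time constants (in steps) and weight bounds of the rule."""

    a_plus: float = 1.2
    a_minus: float = -0.4
    tau_w: float = 10.0
    tau_plus: float = 10.0
    tau_minus: float = 10.0
    w_min: float = 0.0
    w_max: float = 10.0

    def __post_init__(self) -> None:
        if self.w_min >= self.w_max:
            raise ConfigError("require w_min < w_max")
        if self.tau_w <= 0 or self.tau_plus <= 0:
            raise ConfigError("tau_w and tau_plus must be positive")
        if self.tau_minus <= 0:
            raise ConfigError(
                "tau_minus must be positive; a zero depression time constant "
                "makes the depression window degenerate (see docs/methods.md, "
                "plasticity parameters)"
            )


@dataclass(frozen=True)
class SpikePairing:
    """Relative spike timing ``delta_t = t_pre - t_post`` in steps."""

    delta_t: float

    def __post_init__(self) -> None:
        if not np.isfinite(self.delta_t):
            raise ValueError("delta_t must be finite")


def stdp_delta(
    w: float | np.ndarray,
    pairing: "SpikePairing | float",
    params: STDPParams,
) -> float | np.ndarray:
    """One-step weight increment for a single pre/post spike pairing.

    Accepts a scalar or an array of weights (with a matching scalar or
    array ``delta_t``); potentiation applies for ``delta_t <= 0``.
    """
    dt = pairing.delta_t if isinstance(pairing, SpikePairing) else pairing
    w = np.asarray(w, dtype=float)
    dt = np.asarray(dt, dtype=float)
    pot = (params.w_max - w) * params.a_plus * np.exp(
        np.minimum(dt, 0.0) / params.tau_plus
    )
    dep = (params.w_min - w) * abs(params.a_minus) * np.exp(
        -np.maximum(dt, 0.0) / params.tau_minus
    )
    out = np.where(dt <= 0, pot, dep) / params.tau_w
    return float(out) if out.ndim == 0 else out


def update_projection(
    weights: np.ndarray,
    pre_last_spike: np.ndarray,
    post_last_spike: np.ndarray,
    spiked_pre: np.ndarray,
    spiked_post: np.ndarray,
    params: STDPParams,
) -> np.ndarray:
    """Nearest-neighbour STDP update of one projection for one step.

    ``weights`` has shape ``(n_post, n_pre)``.  The last-spike vectors
    must already include spikes emitted this step (so a neuron spiking
    now carries the current step index; ``NO_SPIKE`` marks silence).

    For every postsynaptic spike, each presynaptic neuron's most recent
    spike forms a pre-before-post pairing (``dt <= 0``, potentiation).
    For every presynaptic spike, each postsynaptic neuron that did *not*
    spike this step forms a post-before-pre pairing (``dt > 0``,
    depression).  Entries without a partner spike are unchanged; the
    result is clipped to the dynamic range.
    """
    weights = np.asarray(weights, dtype=float)
    n_post, n_pre = weights.shape
    if pre_last_spike.shape[0] != n_pre or spiked_pre.shape[0] != n_pre:
        raise DimensionError("presynaptic vectors must have length n_pre")
    if post_last_spike.shape[0] != n_post or spiked_post.shape[0] != n_post:
        raise DimensionError("postsynaptic vectors must have length n_post")

    dt = pre_last_spike[None, :].astype(float) - post_last_spike[:, None]
    pre_has = pre_last_spike != NO_SPIKE
    post_has = post_last_spike != NO_SPIKE
    in_window = np.abs(dt) <= PAIRING_CUTOFF_STEPS

    pot_mask = spiked_post[:, None] & pre_has[None, :] & in_window
    dep_mask = (
        (~spiked_post)[:, None]
        & spiked_pre[None, :]
        & post_has[:, None]
        & in_window
    )

    out = weights.copy()
    if pot_mask.any() or dep_mask.any():
        inc = stdp_delta(weights, dt, params)
        out += np.where(pot_mask | dep_mask, inc, 0.0)
    return clip_weights(out, params)


def clip_weights(weights: np.ndarray, params: STDPParams) -> np.ndarray:
    """Elementwise clamp of a weight matrix to ``[w_min, w_max]``."""
    return np.clip(weights, params.w_min, params.w_max)
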