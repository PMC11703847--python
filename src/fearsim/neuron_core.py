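"""Conductance-based integrate-and-fire membrane dynamics for one population.

Each population (brain region) is a vector of leaky integrate-and-fire
neurons.  The membrane equation, normalised by the leak conductance, is

    tau dV/dt = (E - V) + (g_E/g_leak)(E_E - V) + (g_I/g_leak)(E_I - V) + eta

where ``E`` is the leak reversal (resting) potential, ``E_E``/``E_I`` the
excitatory and inhibitory synaptic reversal potentials and ``eta`` a
per-step Gaussian fluctuation.  One simulation iteration advances the
state by one membrane time constant ``tau`` (0.5 ms by default) using the
exponential (exact) integrator for conductance-based models: with the
conductances frozen over the step, the membrane relaxes toward the
balance potential

    V* = (E + g_E/g_leak * E_E + g_I/g_leak * E_I) / (1 + g_E/g_leak + g_I/g_leak)

with rate ``(1 + g_E/g_leak + g_I/g_leak) / tau``.  This update is exact
for the frozen-conductance equation and unconditionally stable, which
matters here because synaptic conductance ratios exceed one (a plain
tau-step Euler update overshoots past the reversal potentials and turns
strong shunting inhibition into a spurious two-step fire/floor
oscillation).  A neuron whose potential exceeds the threshold emits a
spike, is recorded at the peak potential, and is reset, staying clamped
for a configurable refractory number of steps.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import DimensionError, NumericError

__all__ = [
    "NeuronParams",
    "LayerState",
    "synaptic_drive",
    "integrate_step",
    "apply_spike_reset",
]


@dataclass(frozen=True)
class NeuronParams:
    """Membrane constants of one neuron population (SI units).

    ``capacitance`` and ``leak_conductance`` are retained as metadata; the
    integration step is governed directly by ``tau``, which is also the
    duration of one simulation iteration.  ``noise_mean`` / ``noise_sd``
    are the parameters of the per-step membrane fluctuation, expressed in
    volts per step.
    """

    capacitance: float = 5.5e-12          # F
    leak_conductance: float = 10e-9       # S
    leak_reversal: float = -70e-3         # E, V
    exc_reversal: float = 0.0             # E_E, V
    inh_reversal: float = -80e-3          # E_I, V
    threshold: float = -50e-3             # V_th, V
    reset: float = -70e-3                 # V_reset, V
    peak: float = 0.0                     # V_peak, V
    tau: float = 0.5e-3                   # s; membrane constant == step
    noise_mean: float = 0.0               # V per step
    noise_sd: float = 0.5e-3              # V per step
    refractory_steps: int = 1

    def __post_init__(self) -> None:
        if self.capacitance <= 0:
            raise ValueError("capacitance must be positive")
        if self.leak_conductance <= 0:
            raise ValueError("leak_conductance must be positive")
        if self.tau <= 0:
            raise ValueError("tau must be positive")
        if self.reset > self.threshold:
            raise ValueError("reset potential must not exceed threshold")
        if not (self.inh_reversal <= self.leak_reversal <= self.exc_reversal):
            raise ValueError("require E_I <= E <= E_E")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if self.refractory_steps < 0:
            raise ValueError("refractory_steps must be non-negative")

    @property
    def floor(self) -> float:
        """Lower clamp for the membrane potential."""
        return min(self.inh_reversal, self.reset)


@dataclass
class LayerState:
    """Per-neuron dynamic state of one population."""

    v: np.ndarray                         # membrane potential, V
    spiked: np.ndarray                    # bool, spikes emitted this step
    refractory_remaining: np.ndarray      # int, steps left clamped at reset
    step_index: int = 0

    def __post_init__(self) -> None:
        n = self.v.shape[0]
        if self.spiked.shape[0] != n or self.refractory_remaining.shape[0] != n:
            raise DimensionError("state vectors must have equal length")

    @classmethod
    def at_rest(cls, n: int, params: NeuronParams) -> "LayerState":
        return cls(
            v=np.full(n, params.leak_reversal, dtype=float),
            spiked=np.zeros(n, dtype=bool),
            refractory_remaining=np.zeros(n, dtype=np.int64),
        )

    @property
    def n(self) -> int:
        return self.v.shape[0]


def synaptic_drive(
    pre_activity: np.ndarray | float, v_post: np.ndarray, e_syn: float
) -> np.ndarray:
    """Ohmic synaptic current: conductance times driving force.

    ``pre_activity`` is the summed presynaptic conductance per postsynaptic
    neuron (siemens, or a dimensionless g/g_leak ratio — the caller decides
    the normalisation); the returned current is
    ``pre_activity * (e_syn - v_post)`` elementwise, so its units follow
    the input (amperes for siemens).
    """
    pre = np.asarray(pre_activity, dtype=float)
    v_post = np.asarray(v_post, dtype=float)
    if pre.ndim > 0 and pre.shape != v_post.shape:
        raise DimensionError(
            f"pre_activity shape {pre.shape} != v_post shape {v_post.shape}"
        )
    if not np.all(np.isfinite(pre)):
        raise NumericError("non-finite presynaptic activity")
    return pre * (e_syn - v_post)


def _check_finite(arr: np.ndarray, name: str) -> None:
    bad = ~np.isfinite(arr)
    if bad.any():
        idx = int(np.flatnonzero(bad)[0])
        raise NumericError(f"non-finite {name} at neuron index {idx}")


def integrate_step(
    state: LayerState,
    i_exc: np.ndarray,
    i_inh: np.ndarray,
    params: NeuronParams,
    rng: np.random.Generator,
) -> LayerState:
    """One exponential-integrator update of the membrane potentials.

    ``i_exc`` / ``i_inh`` are the excitatory and inhibitory synaptic
    currents in amperes, evaluated at the *current* membrane potential
    (i.e. ``g_syn * (E_syn - V)`` as produced by :func:`synaptic_drive`).
    The underlying conductances are recovered from the driving forces and
    the membrane relaxes toward the conductance-weighted balance
    potential with rate ``(1 + g_E/g_leak + g_I/g_leak)/tau`` over one
    step — the exact solution of the frozen-conductance membrane
    equation, stable for arbitrarily strong synaptic input.

    Neurons in their refractory period are clamped at the reset potential
    and receive no update (their counter decrements).  The potential is
    clamped to ``[min(E_I, V_reset), V_peak]``.
    """
    i_exc = np.asarray(i_exc, dtype=float)
    i_inh = np.asarray(i_inh, dtype=float)
    if i_exc.shape != state.v.shape or i_inh.shape != state.v.shape:
        raise DimensionError("current vectors must match the layer size")
    _check_finite(i_exc, "excitatory current")
    _check_finite(i_inh, "inhibitory current")
    _check_finite(state.v, "membrane potential")

    v = state.v.copy()
    refrac = state.refractory_remaining.copy()
    in_refrac = refrac > 0

    if params.noise_sd > 0:
        eta = rng.normal(params.noise_mean, params.noise_sd, size=v.shape)
    else:
        eta = np.full(v.shape, params.noise_mean)

    # conductance ratios recovered from the driving-force currents
    drive_e = params.exc_reversal - v
    drive_i = params.inh_reversal - v
    with np.errstate(divide="ignore", invalid="ignore"):
        g_e = np.where(drive_e != 0, i_exc / (params.leak_conductance * drive_e), 0.0)
        g_i = np.where(drive_i != 0, i_inh / (params.leak_conductance * drive_i), 0.0)
    g_e = np.maximum(g_e, 0.0)
    g_i = np.maximum(g_i, 0.0)
    tot = 1.0 + g_e + g_i
    v_balance = (
        params.leak_reversal
        + g_e * params.exc_reversal
        + g_i * params.inh_reversal
    ) / tot
    v_new = v_balance + (v - v_balance) * np.exp(-tot) + eta
    v = np.where(in_refrac, params.reset, v_new)
    np.clip(v, params.floor, params.peak, out=v)
    refrac[in_refrac] -= 1

    return LayerState(
        v=v,
        spiked=np.zeros_like(state.spiked),
        refractory_remaining=refrac,
        step_index=state.step_index + 1,
    )


def apply_spike_reset(
    state: LayerState, params: NeuronParams
) -> tuple[LayerState, np.ndarray]:
    """Detect threshold crossings, reset and start refractory periods.

    Neurons with ``V > V_th`` are flagged as spiking (their output value
    for traces is the peak potential) and are instantly reset, with
    ``refractory_remaining`` set to ``params.refractory_steps``.
    """
    fired = state.v > params.threshold
    v = np.where(fired, params.reset, state.v)
    refrac = state.refractory_remaining.copy()
    refrac[fired] = params.refractory_steps
    new_state = LayerState(
        v=v, spiked=fired.copy(), refractory_remaining=refrac,
        step_index=state.step_index,
    )
    return new_state, fired
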