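"""Stress-hormone neuromodulation and the behavioural clock.

A stressful event (a sufficient number of shock-paired episodes) triggers
two tonic hormone transients measured on a minute-scale behavioural
clock: a fast norepinephrine (NE) level that rises and decays within an
hour, and a slower corticosteroid (CORT) level spanning two hours.  Both
follow the same rectified-sine shape

    beta(t) = 0.3853 * sin(2*pi*t / T) + 0.7706 * |sin(2*pi*t / T)|

with period ``T`` of 60 min (NE) or 120 min (CORT), evaluated for a
single transient after the most recent onset and zero afterwards.  The
construction ``a*sin + 2a*|sin|`` is non-negative everywhere (it equals
``3a*sin`` on the rising half-period and ``a*|sin|`` on the falling one).

NE scales the external drive onto the prelimbic and infralimbic cortices
by ``(1 + beta_NE)``; CORT widens hippocampal CA1 sparsity from its 10 %
baseline up to a 50 % saturation reached 40 min after onset.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

from .errors import DomainError

__all__ = [
    "HormoneState",
    "beta_ne",
    "beta_cort",
    "ca1_sparsity",
    "modulated_input",
    "advance_clock",
    "stress_trigger",
    "t_since_onset",
]

_AMP = 0.3853
_NE_PERIOD_MIN = 60.0
_CORT_PERIOD_MIN = 120.0
CA1_BASELINE_FRACTION = 0.10
CA1_SATURATION_FRACTION = 0.50
CA1_SATURATION_MIN = 40.0


@dataclass(frozen=True)
class HormoneState:
    """Behavioural clock, stress onsets and current tonic hormone levels."""

    behavioral_clock: float = 0.0                 # minutes since run start
    stress_onsets: tuple[float, ...] = ()
    beta_ne: float = 0.0
    beta_cort: float = 0.0
    acquisition_shock_counter: int = 0
    stress_enabled: bool = True
    trigger_threshold: int = 15                   # shock-paired episodes


def _rectified_sine(t: float, period: float) -> float:
    if t < 0:
        raise DomainError("time since stress onset must be non-negative")
    if t > period:
        return 0.0
    s = math.sin(2.0 * math.pi * t / period)
    return _AMP * s + 2.0 * _AMP * abs(s)


def beta_ne(t_since_onset_min: float) -> float:
    """Norepinephrine tonic level at ``t`` minutes after a stress onset."""
    return _rectified_sine(t_since_onset_min, _NE_PERIOD_MIN)


def beta_cort(t_since_onset_min: float) -> float:
    """Corticosteroid tonic level at ``t`` minutes after a stress onset."""
    return _rectified_sine(t_since_onset_min, _CORT_PERIOD_MIN)


def ca1_sparsity(t_since_onset_min: float | None) -> float:
    """CA1 active fraction as a function of time since the stress onset.

    Baseline 10 %; linear ramp to the 50 % saturation at 40 min, held
    while the corticosteroid window (120 min) is open, baseline after.
    ``None`` means no stress event has occurred.
    """
    if t_since_onset_min is None:
        return CA1_BASELINE_FRACTION
    t = t_since_onset_min
    if t < 0 or t > _CORT_PERIOD_MIN:
        return CA1_BASELINE_FRACTION
    if t >= CA1_SATURATION_MIN:
        return CA1_SATURATION_FRACTION
    ramp = (CA1_SATURATION_FRACTION - CA1_BASELINE_FRACTION) * t / CA1_SATURATION_MIN
    return CA1_BASELINE_FRACTION + ramp


def modulated_input(
    i_inf: float, beta: float, exc_sum: float = 0.0, inhib_sum: float = 0.0
) -> float:
    """Hormonally gated input: ``(1 + beta) * i_inf + exc_sum - inhib_sum``.

    ``i_inf`` is the neuromodulated drive term (the locus-coeruleus input
    to PL/IL); the remaining synaptic input enters unscaled.
    """
    if beta < 0:
        raise DomainError("beta must be non-negative")
    return (1.0 + beta) * i_inf + exc_sum - inhib_sum


def t_since_onset(state: HormoneState) -> float | None:
    """Minutes since the most recent stress onset, or ``None`` if never."""
    if not state.stress_onsets:
        return None
    return state.behavioral_clock - max(state.stress_onsets)


def _with_levels(state: HormoneState) -> HormoneState:
    t = t_since_onset(state)
    if t is None:
        return replace(state, beta_ne=0.0, beta_cort=0.0)
    return replace(state, beta_ne=beta_ne(t), beta_cort=beta_cort(t))


def advance_clock(state: HormoneState, minutes: float) -> HormoneState:
    """Advance the behavioural clock and refresh the tonic levels."""
    if minutes < 0:
        raise DomainError("cannot advance the clock by a negative duration")
    return _with_levels(
        replace(state, behavioral_clock=state.behavioral_clock + minutes)
    )


def stress_trigger(state: HormoneState) -> HormoneState:
    """Count one shock-paired episode; record an onset at the threshold.

    Call after every episode that delivered a shock.  An onset is
    recorded exactly when the cumulative counter reaches the threshold
    (idempotent per crossing: later calls only increment the counter).
    """
    counter = state.acquisition_shock_counter + 1
    state = replace(state, acquisition_shock_counter=counter)
    if state.stress_enabled and counter == state.trigger_threshold:
        state = replace(
            state, stress_onsets=state.stress_onsets + (state.behavioral_clock,)
        )
    return _with_levels(state)
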