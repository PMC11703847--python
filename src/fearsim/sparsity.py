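"""k-winner-take-all (k-WTA) gating of layer input currents.

Sparse coding in the hippocampal layers (and single-winner behaviour in
the central-amygdala output populations) is enforced by selecting the k
most excited neurons of a layer each step and applying a global
inhibitory term to everyone else, so that only the winners receive
positive net drive.  The excitation score of a neuron is its summed
synaptic input current for the step.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import neuromodulation
from .errors import ConfigError

__all__ = ["KWTAParams", "select_winners", "apply_kwta", "layer_sparsity"]


@dataclass(frozen=True)
class KWTAParams:
    """Winner count and gain terms of the k-WTA gate."""

    k: int
    w_exc: float = 1.0
    w_inib: float = 1.0
    reversal_ref: float = -70e-3   # driving-force reference E, volts

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ConfigError("k must be at least 1")
        if self.w_exc < 0 or self.w_inib < 0:
            raise ConfigError("k-WTA gains must be non-negative")


def select_winners(excitation: np.ndarray, k: int) -> np.ndarray:
    """Indices of the ``k`` most excited neurons.

    Ties are broken deterministically in favour of the lowest index, so
    top-k sets are nested in ``k``.  Returned indices are sorted.
    """
    excitation = np.asarray(excitation, dtype=float)
    n = excitation.shape[0]
    if k > n:
        raise ConfigError(f"k={k} exceeds layer size {n}")
    order = np.argsort(-excitation, kind="stable")
    return np.sort(order[:k])


def apply_kwta(
    input_current: np.ndarray, winners: np.ndarray, params: KWTAParams
) -> np.ndarray:
    """Gate a layer's input currents around the selected winners.

    Winners keep their input scaled by ``w_exc``.  Every other neuron
    receives the pooled inhibitory term ``-w_inib * sum_{i != j}
    max(I_i, 0)`` and is floored at zero net drive, so at most the k
    winners can be driven above rest.
    """
    i = np.asarray(input_current, dtype=float)
    gated = np.full_like(i, 0.0)
    winner_mask = np.zeros(i.shape[0], dtype=bool)
    winner_mask[winners] = True
    gated[winner_mask] = params.w_exc * i[winner_mask]
    pos = np.maximum(i, 0.0)
    total_pos = pos.sum()
    inhib = params.w_inib * (total_pos - pos)
    loser = ~winner_mask
    gated[loser] = np.minimum(params.w_exc * i[loser] - inhib[loser], 0.0)
    return gated


def layer_sparsity(
    region_name: str,
    hormone_state: "neuromodulation.HormoneState",
    *,
    layer_size: int,
    fraction: float | None = None,
    k: int | None = None,
    dynamic: bool = False,
) -> int:
    """Winner count for a region, resolving the stress-dependent CA1 case.

    Static regions use either an explicit ``k`` or a configured fraction
    of the layer size; a ``dynamic`` region (CA1) derives its fraction
    from the corticosteroid schedule at the current behavioural clock.
    """
    if dynamic:
        fraction = neuromodulation.ca1_sparsity(
            neuromodulation.t_since_onset(hormone_state)
        )
    if k is None:
        if fraction is None:
            raise ConfigError(
                f"region {region_name!r} has no sparsity fraction or k configured"
            )
        k = int(round(fraction * layer_size))
    if not 1 <= k <= layer_size:
        k = min(max(k, 1), layer_size)
    return k
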