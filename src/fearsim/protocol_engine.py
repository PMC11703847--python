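"""Stimulus coding, episode execution and the behavioural protocol runner.

An *episode* is one 4-second trial of 8,000 integration steps during
which a context pattern, optionally a sound cue (CS) and optionally a
footshock (US) drive the network.  The US is delivered as a 1.00 nA
current into the sensory layers during a contiguous 2,000-iteration
window, decaying by 0.01 nA per synaptic layer of depth.  Protocols
(contextual fear conditioning, shock magnitude, stress-enhanced fear
learning, shock-stress ordering, immediate extinction deficit) are
ordered phases of episodes per group, separated by behavioural-clock
gaps; every run starts from a Home-context calibration that brings the
central-amygdala output below a 10 % freezing baseline.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, replace
from importlib import resources
from pathlib import Path

import numpy as np
import yaml

from . import neuromodulation, readout_stats
from ._kernel import episode_kernel, pack_network, unpack_weights
from .circuit_builder import Network, build_network, default_network_spec
from .errors import CalibrationError, ConfigError, ProtocolParseError
from .neuron_core import apply_spike_reset, integrate_step
from .plasticity import NO_SPIKE, update_projection
from .sparsity import select_winners

__all__ = [
    "StimulusFrame",
    "EpisodeSpec",
    "PhaseSpec",
    "ProtocolSpec",
    "EpisodeResult",
    "parse_expression",
    "encode_context",
    "shock_current",
    "run_episode",
    "calibrate_home",
    "run_group",
    "load_protocols",
    "list_protocols",
]

CONTEXT_IDS = ("Home", "A", "B", "C")
DEFAULT_ITERATIONS = 8000
DEFAULT_US_WINDOW = (2000, 4000)
DEFAULT_US_CURRENT = 1.0e-9       # A
DEFAULT_LAYER_DECAY = 0.01e-9     # A per synaptic layer
MINUTES_PER_EPISODE = 1.0

logger = logging.getLogger("fearsim")


@dataclass(frozen=True)
class StimulusFrame:
    """Decoded stimulus content of one episode expression."""

    context_id: str
    sound_on: bool = False
    shock_on: bool = False
    shock_gain: float = 1.0

    def __post_init__(self) -> None:
        if self.context_id not in CONTEXT_IDS:
            raise ProtocolParseError(f"unknown context {self.context_id!r}")
        if self.shock_gain < 0:
            raise ProtocolParseError("shock_gain must be non-negative")


@dataclass(frozen=True)
class EpisodeSpec:
    """One episode: stimulus frame, duration and US schedule."""

    frame: StimulusFrame
    expression: str = ""
    n_iterations: int = DEFAULT_ITERATIONS
    us_window: tuple[int, int] = DEFAULT_US_WINDOW
    us_current: float = DEFAULT_US_CURRENT
    layer_decay: float = DEFAULT_LAYER_DECAY

    def __post_init__(self) -> None:
        if (
            self.us_window == DEFAULT_US_WINDOW
            and self.n_iterations != DEFAULT_ITERATIONS
        ):
            # keep the default schedule's proportions (second quarter)
            object.__setattr__(
                self,
                "us_window",
                (self.n_iterations // 4, self.n_iterations // 2),
            )
        lo, hi = self.us_window
        if not (0 <= lo <= hi <= self.n_iterations):
            raise ConfigError("us_window must lie within the episode")
        if self.us_current < 0:
            raise ConfigError("us_current must be non-negative")


@dataclass(frozen=True)
class PhaseSpec:
    label: str
    count: int
    expression: str
    gap_minutes_after: float = 0.0

    def __post_init__(self) -> None:
        if self.count < 1:
            raise ConfigError("phase count must be >= 1")
        parse_expression(self.expression)  # fail fast on bad grammar


@dataclass(frozen=True)
class ProtocolSpec:
    name: str
    title: str
    groups: dict[str, tuple[PhaseSpec, ...]]

    def group(self, group_id: str | int) -> tuple[PhaseSpec, ...]:
        gid = str(group_id)
        if gid not in self.groups:
            raise ConfigError(
                f"protocol {self.name!r} has no group {gid!r}; "
                f"available: {sorted(self.groups)}"
            )
        return self.groups[gid]


@dataclass(frozen=True)
class EpisodeResult:
    """Per-episode freezing readout with a hormone snapshot."""

    group: str
    phase: str
    episode_index: int            # global index within the group run
    phase_episode: int            # index within the phase
    expression: str
    freezing_percent: float
    cem_spike_count: int
    beta_ne: float
    beta_cort: float
    ca1_fraction: float


_EXPR_RE = re.compile(r"^(Home|[ABC])(X?)([+−-]?)$")


def parse_expression(expr: str) -> StimulusFrame:
    """Decode a protocol expression such as ``AX+``, ``B`` or ``Home``.

    Grammar: a context token (``Home`` or a context letter A/B/C),
    an optional ``X`` (sound cue on) and an optional ``+``/``-``
    (shock on/off).
    """
    m = _EXPR_RE.match(expr.strip())
    if m is None:
        for pos, ch in enumerate(expr):
            if ch not in "ABCHomeX+-−":
                raise ProtocolParseError(
                    f"unknown token {ch!r} at position {pos} in {expr!r}"
                )
        raise ProtocolParseError(f"cannot parse expression {expr!r}")
    context, sound, shock = m.groups()
    return StimulusFrame(
        context_id=context,
        sound_on=sound == "X",
        shock_on=shock == "+",
    )


def encode_context(
    context_id: str,
    n_units: int,
    seed: int,
    *,
    active_units: int = 6,
    shared_units: int = 2,
) -> np.ndarray:
    """Fixed, seed-deterministic binary pattern for a context.

    The three experimental contexts A/B/C each activate ``active_units``
    channels, of which ``shared_units`` are common to all three (giving
    a Jaccard overlap of ``s / (2m - s)`` between any pair, 0.2 at the
    defaults).  ``Home`` is a distinct low-activity pattern disjoint
    from the experimental contexts.
    """
    if context_id not in CONTEXT_IDS:
        raise ProtocolParseError(f"unknown context {context_id!r}")
    if n_units < 4:
        raise ConfigError("need at least 4 context units")
    m, s = active_units, shared_units
    own = m - s
    n_home = 1
    if s + 3 * own + n_home > n_units:
        raise ConfigError(
            f"{n_units} context units cannot host 3 contexts of {m} active "
            f"units with {s} shared plus a Home pattern"
        )
    perm = np.random.default_rng(np.random.SeedSequence([seed, 0xC0DE])).permutation(
        n_units
    )
    pattern = np.zeros(n_units, dtype=float)
    if context_id == "Home":
        # low-activity pattern: one channel at half drive keeps the home
        # cage from recruiting the contextual pathway
        chosen = perm[s + 3 * own: s + 3 * own + n_home]
        pattern[chosen] = 0.5
        return pattern
    else:
        block = "ABC".index(context_id)
        chosen = np.concatenate(
            [perm[:s], perm[s + block * own: s + (block + 1) * own]]
        )
    pattern[chosen] = 1.0
    return pattern


def shock_current(layer_depth: int, episode: EpisodeSpec, iteration: int) -> float:
    """US current (amperes) reaching a layer at ``layer_depth`` this iteration.

    Inside the US window the sensory current starts at ``us_current``
    and loses ``layer_decay`` per synaptic layer (floored at zero); it is
    scaled by the frame's shock intensity and is zero outside the window
    or when the frame has no shock.
    """
    if layer_depth < 0:
        raise ConfigError("layer_depth must be non-negative")
    lo, hi = episode.us_window
    if not episode.frame.shock_on or not lo <= iteration < hi:
        return 0.0
    amp = max(0.0, episode.us_current - episode.layer_decay * layer_depth)
    return amp * episode.frame.shock_gain


# ---------------------------------------------------------------------------
# Episode execution


def _episode_kwta(network: Network, hormone_state) -> np.ndarray:
    """Per-region winner counts for this episode (-1 = ungated)."""
    ks = np.full(len(network.region_names), -1, dtype=np.int64)
    for i, name in enumerate(network.region_names):
        k = network.current_k(name, hormone_state)
        if k is not None:
            ks[i] = k
    return ks


def _context_pattern(network: Network, context_id: str) -> np.ndarray:
    spec = network.spec
    return encode_context(
        context_id,
        spec.context_units,
        network.seed,
        active_units=spec.context_active_units,
        shared_units=spec.context_shared_units,
    )


def _us_amplitudes(network: Network, episode: EpisodeSpec) -> np.ndarray:
    """Per-connection relative US amplitude (depth decay / reference current)."""
    depths = network.layer_depths("US")
    amps = np.zeros(len(network.spec.connections))
    for i, c in enumerate(network.spec.connections):
        if c.source == "US":
            d = depths.get(c.target, 0)
            amps[i] = (
                max(0.0, episode.us_current - episode.layer_decay * d)
                / DEFAULT_US_CURRENT
            )
    return amps


def run_episode(
    network: Network,
    episode: EpisodeSpec,
    hormone_state: neuromodulation.HormoneState,
    rng: np.random.Generator,
    *,
    group: str = "",
    phase: str = "",
    episode_index: int = 0,
    phase_episode: int = 0,
    fast: bool = True,
) -> tuple[neuromodulation.HormoneState, EpisodeResult]:
    """Run one episode, updating the network (weights) in place.

    Returns the advanced hormone state and the episode's freezing
    readout.  The behavioural clock advances by one minute per episode;
    a delivered shock counts toward the stress trigger.
    """
    network.reset_dynamic_state()
    frame = episode.frame
    k_arr = _episode_kwta(network, hormone_state)
    ctx = _context_pattern(network, frame.context_id)
    cs_on = 1.0 if frame.sound_on else 0.0
    us_gain = frame.shock_gain if frame.shock_on else 0.0

    if fast:
        cem_counts = _run_fast(
            network, episode, hormone_state, k_arr, ctx, cs_on, us_gain, rng
        )
    else:
        cem_counts = _run_reference(
            network, episode, hormone_state, k_arr, ctx, cs_on, us_gain, rng
        )

    freezing = readout_stats.freezing_percent(cem_counts)
    ca1_fraction = neuromodulation.ca1_sparsity(
        neuromodulation.t_since_onset(hormone_state)
    )
    result = EpisodeResult(
        group=group,
        phase=phase,
        episode_index=episode_index,
        phase_episode=phase_episode,
        expression=episode.expression or _render_expression(frame),
        freezing_percent=freezing,
        cem_spike_count=int(cem_counts.sum()),
        beta_ne=hormone_state.beta_ne,
        beta_cort=hormone_state.beta_cort,
        ca1_fraction=ca1_fraction,
    )
    logger.debug(
        "episode %s/%s #%d expr=%s freezing=%.1f%% cem=%d beta_ne=%.3f "
        "ca1=%.2f clock=%.0fmin",
        group,
        phase,
        episode_index,
        result.expression,
        result.freezing_percent,
        result.cem_spike_count,
        hormone_state.beta_ne,
        ca1_fraction,
        hormone_state.behavioral_clock,
    )
    hormone_state = neuromodulation.advance_clock(
        hormone_state, MINUTES_PER_EPISODE
    )
    if frame.shock_on and frame.shock_gain > 0:
        hormone_state = neuromodulation.stress_trigger(hormone_state)
    return hormone_state, result


def _render_expression(frame: StimulusFrame) -> str:
    """Inverse of :func:`parse_expression` (protocol-table notation)."""
    if frame.context_id == "Home":
        return "Home"
    out = frame.context_id
    if frame.sound_on:
        out += "X" + ("+" if frame.shock_on else "-")
    elif frame.shock_on:
        out += "+"
    return out


def _run_fast(network, episode, hormone_state, k_arr, ctx, cs_on, us_gain, rng):
    packed = pack_network(network, us_in_episode=us_gain > 0)
    names = network.region_names
    kw_exc = np.full(len(names), network.spec.kwta_defaults.w_exc)
    kw_inib = np.full(len(names), network.spec.kwta_defaults.w_inib)
    stdp = network.spec.stdp
    v = np.concatenate([network.states[n].v for n in names])
    refrac = np.concatenate(
        [network.states[n].refractory_remaining for n in names]
    )
    last = np.concatenate([network.last_spike[n] for n in names])
    noise_seed = int(rng.integers(0, 2**31 - 1))
    cem_counts = episode_kernel(
        episode.n_iterations,
        packed["offsets"],
        packed["region_of"],
        packed["e_leak"],
        packed["e_exc"],
        packed["e_inh"],
        packed["v_th"],
        packed["v_reset"],
        packed["v_peak"],
        packed["v_floor"],
        packed["noise_mu"],
        packed["noise_sd"],
        packed["refrac_steps"],
        k_arr,
        kw_exc,
        kw_inib,
        packed["c_src"],
        packed["c_tgt"],
        packed["c_exc"],
        packed["c_ne"],
        packed["c_plastic"],
        packed["c_lr"],
        packed["c_wmax"],
        packed["c_woff"],
        packed["c_nsrc"],
        packed["c_norm"],
        _us_amplitudes(network, episode),
        packed["w_flat"],
        ctx,
        cs_on,
        episode.us_window[0],
        episode.us_window[1],
        us_gain,
        hormone_state.beta_ne,
        stdp.a_plus,
        abs(stdp.a_minus),
        stdp.tau_w,
        stdp.tau_plus,
        stdp.tau_minus,
        stdp.w_min,
        stdp.w_max,
        v,
        refrac,
        last,
        network.external_last_spike["Context"],
        network.external_last_spike["CS"],
        network.external_last_spike["US"],
        network.region_index["CeM"],
        noise_seed,
    )
    unpack_weights(network, packed)
    offsets = packed["offsets"]
    for i, n in enumerate(names):
        sl = slice(offsets[i], offsets[i + 1])
        network.states[n].v[...] = v[sl]
        network.states[n].refractory_remaining[...] = refrac[sl]
        network.last_spike[n][...] = last[sl]
    return cem_counts


def _run_reference(
    network, episode, hormone_state, k_arr, ctx, cs_on, us_gain, rng
):
    """Pure-NumPy episode loop composed from the documented operations.

    Mirrors the compiled kernel step for step: per-region conductance
    sums, k-WTA gating, the exponential-integrator membrane update via
    :func:`~fearsim.neuron_core.integrate_step`, spike/reset and
    nearest-neighbour STDP.  With zero membrane noise its trajectory is
    bit-identical to the kernel's.
    """
    names = network.region_names
    stdp = network.spec.stdp
    kw = network.spec.kwta_defaults
    us_amp = _us_amplitudes(network, episode)
    conn_amp = {
        c.key: us_amp[i] for i, c in enumerate(network.spec.connections)
    }
    cem_counts = np.zeros(episode.n_iterations, dtype=np.int64)
    ext_last = network.external_last_spike

    for t in range(episode.n_iterations):
        lo, hi = episode.us_window
        us_act = us_gain if lo <= t < hi else 0.0
        cond: dict[str, tuple[np.ndarray, np.ndarray]] = {}
        for name in names:
            n = network.sizes[name]
            cond[name] = (np.zeros(n), np.zeros(n))
        for c in network.spec.connections:
            if c.source == "Context":
                act = ctx
            elif c.source == "CS":
                act = np.array([cs_on])
            elif c.source == "US":
                act = np.array([us_act * conn_amp[c.key]])
            elif c.source == "LC":
                act = np.array([1.0])
            else:
                act = network.states[c.source].spiked.astype(float)
            if not act.any():
                continue
            mult = (1.0 + hormone_state.beta_ne) if c.ne_modulated else 1.0
            g = mult * (network.weights[c.key] @ act) / network.source_norm(c.source)
            ge, gi = cond[c.target]
            if c.sign > 0:
                ge += g
            else:
                gi += g
        new_spikes: dict[str, np.ndarray] = {}
        for name in names:
            params = network.params[name]
            v = network.states[name].v
            ge, gi = cond[name]
            idx = network.region_index[name]
            if k_arr[idx] > 0:
                score = ge * (params.exc_reversal - v) + gi * (
                    params.inh_reversal - v
                )
                winners = select_winners(score, int(k_arr[idx]))
                mask = np.zeros(len(score), dtype=bool)
                mask[winners] = True
                g_pool = kw.w_inib * ge[mask].sum() / int(k_arr[idx])
                ge = np.where(mask, kw.w_exc * ge, 0.0)
                gi = gi + np.where(mask, 0.0, g_pool)
            i_exc = ge * params.leak_conductance * (params.exc_reversal - v)
            i_inh = gi * params.leak_conductance * (params.inh_reversal - v)
            state = integrate_step(
                network.states[name], i_exc, i_inh, params, rng
            )
            state, fired = apply_spike_reset(state, params)
            network.states[name] = state
            new_spikes[name] = fired
            network.last_spike[name][fired] = t
        ext_last["Context"][ctx > 0] = t
        if cs_on > 0:
            ext_last["CS"][0] = t
        if us_act > 0:
            ext_last["US"][0] = t
        for ci, c in enumerate(network.spec.connections):
            if not c.plastic or (c.us_gated and us_gain > 0):
                continue
            if c.source == "Context":
                pre_last = ext_last["Context"]
                pre_spiked = ctx > 0
            elif c.source == "CS":
                pre_last = ext_last["CS"]
                pre_spiked = np.array([cs_on > 0])
            elif c.source == "US":
                pre_last = ext_last["US"]
                pre_spiked = np.array([us_act * us_amp[ci] > 0])
            elif c.source == "LC":
                continue
            else:
                pre_last = network.last_spike[c.source]
                pre_spiked = new_spikes[c.source]
            eff = network.stdp_for(c)
            network.weights[c.key][...] = update_projection(
                network.weights[c.key],
                pre_last,
                network.last_spike[c.target],
                pre_spiked,
                new_spikes[c.target],
                eff,
            )
        cem_counts[t] = int(new_spikes["CeM"].sum())
    return cem_counts


# ---------------------------------------------------------------------------
# Calibration and protocol runs


def calibrate_home(
    network: Network,
    rng: np.random.Generator,
    max_episodes: int = 200,
    *,
    hormone_state: neuromodulation.HormoneState | None = None,
    criterion_percent: float = 10.0,
    consecutive: int = 10,
    n_iterations: int = DEFAULT_ITERATIONS,
    fast: bool = True,
) -> tuple[Network, neuromodulation.HormoneState, list[EpisodeResult]]:
    """Home-context baseline calibration (plasticity on).

    Repeats Home episodes until freezing stays below
    ``criterion_percent`` for ``consecutive`` consecutive episodes; the
    calibrated weight state is the baseline for every experimental
    group.  Raises :class:`CalibrationError` if the criterion is not met
    within ``max_episodes``.
    """
    if hormone_state is None:
        hormone_state = neuromodulation.HormoneState()
    frame = parse_expression("Home")
    results: list[EpisodeResult] = []
    streak = 0
    for i in range(max_episodes):
        episode = EpisodeSpec(
            frame=frame, expression="Home", n_iterations=n_iterations
        )
        hormone_state, res = run_episode(
            network,
            episode,
            hormone_state,
            rng,
            group="calibration",
            phase="Home",
            episode_index=i,
            phase_episode=i,
            fast=fast,
        )
        results.append(res)
        streak = streak + 1 if res.freezing_percent < criterion_percent else 0
        if streak >= consecutive:
            logger.info(
                "calibration converged after %d Home episodes", len(results)
            )
            return network, hormone_state, results
    trace = [round(r.freezing_percent, 1) for r in results[-consecutive:]]
    raise CalibrationError(
        f"CeM output did not stabilise below {criterion_percent}% for "
        f"{consecutive} consecutive Home episodes within {max_episodes} "
        f"episodes (last readings: {trace})"
    )


def load_protocols(source: str | Path | None = None) -> dict[str, ProtocolSpec]:
    """Load the protocol suite (packaged Tables when ``source`` is None)."""
    if source is None:
        text = resources.files("fearsim.data").joinpath("protocols.yaml").read_text()
    else:
        text = Path(source).read_text()
    raw = yaml.safe_load(text)
    out: dict[str, ProtocolSpec] = {}
    for name, body in raw.items():
        groups = {
            gid: tuple(
                PhaseSpec(
                    label=p["label"],
                    count=int(p["count"]),
                    expression=p["expr"],
                    gap_minutes_after=float(p.get("gap_min", 0.0)),
                )
                for p in phases
            )
            for gid, phases in body["groups"].items()
        }
        out[name] = ProtocolSpec(name=name, title=body.get("title", name), groups=groups)
    return out


def list_protocols() -> list[str]:
    return sorted(load_protocols())


def run_group(
    protocol: ProtocolSpec | str,
    group_id: str | int,
    seed: int,
    *,
    scale: str | int = "quarter",
    network_spec=None,
    n_iterations: int = DEFAULT_ITERATIONS,
    shock_gain: float = 1.0,
    stress_enabled: bool = True,
    calibrate: bool = True,
    max_calibration_episodes: int = 200,
    fast: bool = True,
) -> list[EpisodeResult]:
    """Build, calibrate and run one protocol group end to end.

    A fresh network is built from ``network_spec`` (default architecture
    at ``scale`` otherwise) with the given seed, Home-calibrated, and
    then run through the group's phases in order with the configured
    clock gaps.  ``shock_gain`` scales every US in the run (0 disables
    shocks, the null control).
    """
    if isinstance(protocol, str):
        protocol = load_protocols()[protocol]
    phases = protocol.group(group_id)
    spec = network_spec or default_network_spec(scale)
    network = build_network(spec, seed)
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0xEF1]))
    hormone_state = neuromodulation.HormoneState(stress_enabled=stress_enabled)
    if calibrate:
        network, hormone_state, _ = calibrate_home(
            network,
            rng,
            max_calibration_episodes,
            hormone_state=hormone_state,
            n_iterations=n_iterations,
            fast=fast,
        )
    results: list[EpisodeResult] = []
    episode_index = 0
    gid = str(group_id)
    for phase in phases:
        frame = replace(parse_expression(phase.expression), shock_gain=shock_gain)
        for j in range(phase.count):
            episode = EpisodeSpec(
                frame=frame,
                expression=phase.expression,
                n_iterations=n_iterations,
            )
            hormone_state, res = run_episode(
                network,
                episode,
                hormone_state,
                rng,
                group=gid,
                phase=phase.label,
                episode_index=episode_index,
                phase_episode=j,
                fast=fast,
            )
            results.append(res)
            episode_index += 1
        if phase.gap_minutes_after > 0:
            hormone_state = neuromodulation.advance_clock(
                hormone_state, phase.gap_minutes_after
            )
    return results
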