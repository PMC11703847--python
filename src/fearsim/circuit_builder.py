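"""Declarative network specification and runtime instantiation.

The architecture is described by a list of regions (population sizes,
sparsity settings) and signed connections (weight means, plasticity
flags), shipped as ``data/default_network.yaml``.  ``build_network``
draws every weight matrix from ``|N(mu, sd)|`` with a seeded generator,
applies optional random connectivity masks, and produces the runtime
``Network`` whose per-region input sums drive the integrate-and-fire
update.

Population terms in the input sums are normalised by the presynaptic
*nominal active pool* (the k-WTA winner count for gated layers, the
population size otherwise — see :meth:`Network.source_norm`), so the
weight means act on the source's relative activity level and per-step
drives stay on the tens-of-millivolts scale independent of layer size.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path

import numpy as np
import yaml

from . import neuromodulation
from .errors import ConfigError
from .neuron_core import LayerState, NeuronParams, synaptic_drive
from .plasticity import NO_SPIKE, STDPParams, clip_weights
from .sparsity import KWTAParams, layer_sparsity

__all__ = [
    "EXTERNAL_INPUTS",
    "RegionSpec",
    "ConnectionSpec",
    "NetworkSpec",
    "Network",
    "ValidationReport",
    "load_network_spec",
    "default_network_spec",
    "validate_spec",
    "init_weights",
    "build_network",
    "region_input",
]

#: Names usable as connection sources without being declared regions.
EXTERNAL_INPUTS = ("Context", "CS", "US", "LC")


@dataclass(frozen=True)
class RegionSpec:
    name: str
    n_neurons: int
    neuron_params: NeuronParams | None = None    # override of the defaults
    sparsity_fraction: float | None = None
    sparsity_dynamic: bool = False               # CA1 stress schedule
    k: int | None = None
    kwta: KWTAParams | None = None

    def __post_init__(self) -> None:
        if self.n_neurons < 1:
            raise ConfigError(f"region {self.name!r} must have >= 1 neuron")

    @property
    def gated(self) -> bool:
        return (
            self.sparsity_fraction is not None
            or self.sparsity_dynamic
            or self.k is not None
        )


@dataclass(frozen=True)
class ConnectionSpec:
    source: str
    target: str
    sign: int                                    # +1 excitatory, -1 inhibitory
    weight_mean: float
    weight_sd: float = 0.3
    plastic: bool = False
    lr: float = 1.0                              # learning-rate multiplier on 1/tau_w
    w_max: float | None = None                   # per-projection bound override
    us_gated: bool = False                       # plasticity paused in shock episodes
    connectivity: float = 1.0
    ne_modulated: bool = False                   # scaled by (1 + beta_NE)

    def __post_init__(self) -> None:
        if self.sign not in (1, -1):
            raise ConfigError(
                f"{self.source}->{self.target}: sign must be +1 or -1"
            )
        if self.weight_mean < 0 or self.weight_sd < 0:
            raise ConfigError(
                f"{self.source}->{self.target}: weight mean/sd must be >= 0"
            )
        if not 0.0 <= self.connectivity <= 1.0:
            raise ConfigError(
                f"{self.source}->{self.target}: connectivity must be in [0, 1]"
            )
        if self.lr < 0:
            raise ConfigError(f"{self.source}->{self.target}: lr must be >= 0")

    @property
    def key(self) -> tuple[str, str]:
        return (self.source, self.target)


@dataclass(frozen=True)
class NetworkSpec:
    name: str
    regions: tuple[RegionSpec, ...]
    connections: tuple[ConnectionSpec, ...]
    stdp: STDPParams = STDPParams()
    defaults: NeuronParams = NeuronParams()
    kwta_defaults: KWTAParams = KWTAParams(k=1)
    context_units: int = 16
    context_active_units: int = 6
    context_shared_units: int = 2

    def region(self, name: str) -> RegionSpec:
        for r in self.regions:
            if r.name == name:
                return r
        raise ConfigError(f"unknown region {name!r}")

    @property
    def region_names(self) -> list[str]:
        return [r.name for r in self.regions]


@dataclass
class ValidationReport:
    errors: list[str] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.errors


# ---------------------------------------------------------------------------
# Loading


def _params_from_yaml(d: dict) -> NeuronParams:
    return NeuronParams(
        capacitance=d["capacitance_pF"] * 1e-12,
        leak_conductance=d["leak_conductance_nS"] * 1e-9,
        leak_reversal=d["leak_reversal_mV"] * 1e-3,
        exc_reversal=d["exc_reversal_mV"] * 1e-3,
        inh_reversal=d["inh_reversal_mV"] * 1e-3,
        threshold=d["threshold_mV"] * 1e-3,
        reset=d["reset_mV"] * 1e-3,
        peak=d["peak_mV"] * 1e-3,
        tau=d["tau_ms"] * 1e-3,
        noise_mean=d["noise_mean_mV"] * 1e-3,
        noise_sd=d["noise_sd_mV"] * 1e-3,
        refractory_steps=int(d["refractory_steps"]),
    )


def load_network_spec(source: str | Path | None = None) -> NetworkSpec:
    """Load a network spec from YAML (packaged default when ``source`` is None)."""
    if source is None:
        text = (
            resources.files("fearsim.data")
            .joinpath("default_network.yaml")
            .read_text()
        )
    else:
        text = Path(source).read_text()
    raw = yaml.safe_load(text)

    defaults = _params_from_yaml(raw["neuron_defaults"])
    stdp = STDPParams(**raw["stdp"])
    kw = raw.get("kwta_defaults", {})
    kwta_defaults = KWTAParams(
        k=1, w_exc=kw.get("w_exc", 1.0), w_inib=kw.get("w_inib", 1.0),
        reversal_ref=defaults.leak_reversal,
    )

    def _region(r: dict) -> RegionSpec:
        overrides = {
            key[: -len("_mV")]: r[key] * 1e-3
            for key in ("noise_sd_mV", "noise_mean_mV", "threshold_mV")
            if key in r
        }
        params = replace(defaults, **overrides) if overrides else None
        return RegionSpec(
            name=r["name"],
            n_neurons=int(r["n"]),
            neuron_params=params,
            sparsity_fraction=r.get("sparsity_fraction"),
            sparsity_dynamic=bool(r.get("sparsity_dynamic", False)),
            k=r.get("k"),
        )

    regions = tuple(_region(r) for r in raw["regions"])
    connections = tuple(
        ConnectionSpec(
            source=c["source"],
            target=c["target"],
            sign=int(c["sign"]),
            weight_mean=float(c["mu"]),
            weight_sd=float(c.get("sd", 0.3)),
            plastic=bool(c.get("plastic", False)),
            lr=float(c.get("lr", 1.0)),
            w_max=c.get("w_max"),
            us_gated=bool(c.get("us_gated", False)),
            connectivity=float(c.get("connectivity", 1.0)),
            ne_modulated=bool(c.get("ne_modulated", False)),
        )
        for c in raw["connections"]
    )
    return NetworkSpec(
        name=raw.get("name", "unnamed"),
        regions=regions,
        connections=connections,
        stdp=stdp,
        defaults=defaults,
        kwta_defaults=kwta_defaults,
        context_units=int(raw.get("context_units", 16)),
        context_active_units=int(raw.get("context_active_units", 6)),
        context_shared_units=int(raw.get("context_shared_units", 2)),
    )


def default_network_spec(scale: str | int = "full") -> NetworkSpec:
    """The packaged architecture, optionally size-reduced.

    ``scale="quarter"`` divides every population by four (minimum two
    neurons per population), the configuration used by the fast test
    battery; an integer divides by that factor.
    """
    spec = load_network_spec(None)
    if scale == "full" or scale == 1:
        return spec
    divisor = 4 if scale == "quarter" else int(scale)
    if divisor < 1:
        raise ConfigError("scale divisor must be >= 1")
    regions = tuple(
        replace(r, n_neurons=max(2, round(r.n_neurons / divisor)))
        for r in spec.regions
    )
    return replace(spec, name=f"{spec.name}/{divisor}", regions=regions)


# ---------------------------------------------------------------------------
# Validation


def validate_spec(spec: NetworkSpec) -> ValidationReport:
    """Consistency checks; errors block the build, warnings are advisory."""
    rep = ValidationReport()
    names = [r.name for r in spec.regions]
    seen: set[str] = set()
    for n in names:
        if n in seen:
            rep.errors.append(f"duplicate region name {n!r}")
        seen.add(n)
    valid_sources = set(names) | set(EXTERNAL_INPUTS)
    conn_seen: set[tuple[str, str]] = set()
    for c in spec.connections:
        if c.source not in valid_sources:
            rep.errors.append(f"connection from undeclared source {c.source!r}")
        if c.target not in names:
            rep.errors.append(f"connection to undeclared region {c.target!r}")
        if c.key in conn_seen:
            rep.errors.append(f"duplicate connection {c.source}->{c.target}")
        conn_seen.add(c.key)
    try:
        template = load_network_spec(None)
    except Exception:  # pragma: no cover - packaged file always present
        template = None
    if template is not None and spec is not template:
        tmpl_signs = {c.key: c.sign for c in template.connections}
        for c in spec.connections:
            if c.key in tmpl_signs and tmpl_signs[c.key] != c.sign:
                rep.warnings.append(
                    f"{c.source}->{c.target}: sign {c.sign:+d} conflicts with "
                    f"the packaged template ({tmpl_signs[c.key]:+d})"
                )
    if spec.stdp.tau_minus <= 0:  # unreachable via STDPParams, kept for raw dicts
        rep.errors.append("stdp.tau_minus must be positive (see docs/methods.md)")
    for r in spec.regions:
        if r.k is not None and r.k > r.n_neurons:
            rep.errors.append(f"region {r.name!r}: k={r.k} > n={r.n_neurons}")
    for c in spec.connections:
        if not (spec.stdp.w_min <= c.weight_mean <= spec.stdp.w_max):
            rep.warnings.append(
                f"{c.source}->{c.target}: mean {c.weight_mean} outside the "
                f"STDP dynamic range"
            )
    return rep


# ---------------------------------------------------------------------------
# Instantiation


def init_weights(
    conn: ConnectionSpec, n_src: int, n_tgt: int, rng: np.random.Generator
) -> np.ndarray:
    """Seeded ``(n_tgt, n_src)`` weight matrix of clamped normal draws.

    Entries are ``max(N(mu, sd), 0)`` (negative draws clamp to zero);
    a connectivity fraction below one zeroes a random complement of the
    matrix.
    """
    w = rng.normal(conn.weight_mean, conn.weight_sd, size=(n_tgt, n_src))
    np.maximum(w, 0.0, out=w)
    if conn.connectivity < 1.0:
        mask = rng.random((n_tgt, n_src)) < conn.connectivity
        w *= mask
    return w


class Network:
    """Instantiated runtime network: layer states, weights, bookkeeping."""

    def __init__(self, spec: NetworkSpec, seed: int):
        report = validate_spec(spec)
        if not report.ok:
            raise ConfigError("invalid network spec: " + "; ".join(report.errors))
        self.spec = spec
        self.seed = seed
        self.validation = report
        self.region_names: list[str] = spec.region_names
        self.region_index = {n: i for i, n in enumerate(self.region_names)}
        self.sizes = {r.name: r.n_neurons for r in spec.regions}
        self.params: dict[str, NeuronParams] = {
            r.name: (r.neuron_params or spec.defaults) for r in spec.regions
        }
        rng = np.random.default_rng(seed)
        self.weights: dict[tuple[str, str], np.ndarray] = {}
        for c in spec.connections:
            n_src = self._source_size(c.source)
            w = init_weights(c, n_src, self.sizes[c.target], rng)
            # plastic projections live inside the STDP dynamic range;
            # static weights keep their configured scale untouched
            if c.plastic:
                w = clip_weights(w, self.stdp_for(c))
            self.weights[c.key] = w
        self.states: dict[str, LayerState] = {}
        self.last_spike: dict[str, np.ndarray] = {}
        self.external_last_spike: dict[str, np.ndarray] = {}
        self.reset_dynamic_state()

    # -- helpers ----------------------------------------------------------

    def _source_size(self, source: str) -> int:
        if source == "Context":
            return self.spec.context_units
        if source in EXTERNAL_INPUTS:
            return 1
        if source not in self.sizes:
            raise ConfigError(f"unknown source {source!r}")
        return self.sizes[source]

    def source_norm(self, source: str) -> int:
        """Nominal active pool of a source: the weighted sum's divisor.

        Population terms are read as weight times population activity
        *relative to the source's nominal active pool*: the k-WTA winner
        count for gated layers (CA1 uses its 10 % baseline), the full
        size for ungated layers, and the active pattern size for the
        Context channel.  Stress-widened CA1 sparsity therefore
        genuinely increases CA1's downstream drive.
        """
        if source == "Context":
            return self.spec.context_active_units
        if source in EXTERNAL_INPUTS:
            return 1
        r = self.spec.region(source)
        if r.k is not None:
            return max(1, r.k)
        if r.sparsity_dynamic:
            # normalised by the full population: the stress-widened winner
            # pool then genuinely raises CA1's downstream drive
            return r.n_neurons
        if r.sparsity_fraction is not None:
            return max(1, round(r.sparsity_fraction * r.n_neurons))
        return r.n_neurons

    def stdp_for(self, conn: ConnectionSpec) -> STDPParams:
        """Effective STDP parameters of one projection (rate and bound
        overrides applied)."""
        stdp = self.spec.stdp
        kwargs = {}
        if conn.lr != 1.0:
            kwargs["tau_w"] = stdp.tau_w / conn.lr if conn.lr > 0 else np.inf
        if conn.w_max is not None:
            kwargs["w_max"] = conn.w_max
        return replace(stdp, **kwargs) if kwargs else stdp

    def connections_to(self, region: str) -> list[ConnectionSpec]:
        return [c for c in self.spec.connections if c.target == region]

    def reset_dynamic_state(self) -> None:
        """Fresh membrane/spike state at rest; weights are untouched.

        Called at the start of every behavioural episode: episodes are
        separated by minutes of behavioural time, far beyond the STDP
        pairing window, so spike history does not carry across them.
        """
        for name in self.region_names:
            self.states[name] = LayerState.at_rest(
                self.sizes[name], self.params[name]
            )
            self.last_spike[name] = np.full(
                self.sizes[name], NO_SPIKE, dtype=np.int64
            )
        self.external_last_spike = {
            "Context": np.full(self.spec.context_units, NO_SPIKE, dtype=np.int64),
            "CS": np.full(1, NO_SPIKE, dtype=np.int64),
            "US": np.full(1, NO_SPIKE, dtype=np.int64),
            "LC": np.full(1, NO_SPIKE, dtype=np.int64),
        }

    def current_k(
        self, region: str, hormone_state: neuromodulation.HormoneState
    ) -> int | None:
        """Winner count for a gated region this episode, else ``None``."""
        r = self.spec.region(region)
        if not r.gated:
            return None
        return layer_sparsity(
            region,
            hormone_state,
            layer_size=r.n_neurons,
            fraction=r.sparsity_fraction,
            k=r.k,
            dynamic=r.sparsity_dynamic,
        )

    def layer_depths(self, stimulus: str = "US") -> dict[str, int]:
        """Shortest synaptic hop count from an external stimulus per region."""
        if stimulus not in EXTERNAL_INPUTS:
            raise ConfigError(f"unknown stimulus {stimulus!r}")
        depths: dict[str, int] = {}
        frontier = [
            c.target for c in self.spec.connections if c.source == stimulus
        ]
        d = 0
        while frontier:
            nxt: list[str] = []
            for name in frontier:
                if name not in depths:
                    depths[name] = d
                    nxt.extend(
                        c.target
                        for c in self.spec.connections
                        if c.source == name and c.target not in depths
                    )
            frontier = nxt
            d += 1
        return depths

    def state_hash(self) -> str:
        """Digest of weights and membrane state (reproducibility checks)."""
        h = hashlib.sha256()
        for c in self.spec.connections:
            h.update(np.ascontiguousarray(self.weights[c.key]).tobytes())
        for name in self.region_names:
            h.update(np.ascontiguousarray(self.states[name].v).tobytes())
        return h.hexdigest()

    @property
    def n_total(self) -> int:
        return sum(self.sizes.values())


def build_network(spec: NetworkSpec, seed: int) -> Network:
    """Validate and instantiate ``spec`` with seeded weight initialisation."""
    return Network(spec, seed)


def region_input(
    region_name: str,
    network: Network,
    external_drives: dict[str, np.ndarray | float],
    hormone_state: neuromodulation.HormoneState,
) -> np.ndarray:
    """Signed synaptic input current (amperes) for one region, one step.

    Sums every incoming connection's contribution using the previous
    step's presynaptic spike flags (or external drive activities), each
    through the driving-force current with ``E_E`` for excitatory and
    ``E_I`` for inhibitory terms.  Locus-coeruleus terms onto PL/IL are
    scaled by ``(1 + beta_NE)`` through the neuromodulation gate.
    """
    if region_name not in network.sizes:
        raise ConfigError(f"unknown region {region_name!r}")
    params = network.params[region_name]
    v = network.states[region_name].v
    plain = np.zeros_like(v)
    modulated = np.zeros_like(v)
    for c in network.connections_to(region_name):
        if c.source in EXTERNAL_INPUTS:
            act = np.atleast_1d(
                np.asarray(external_drives.get(c.source, 0.0), dtype=float)
            )
        else:
            act = network.states[c.source].spiked.astype(float)
        w = network.weights[c.key]
        g = (w @ act) / network.source_norm(c.source)
        e_rev = params.exc_reversal if c.sign > 0 else params.inh_reversal
        term = synaptic_drive(g, v, e_rev)
        if c.ne_modulated:
            modulated += term
        else:
            plain += term
    total = neuromodulation.modulated_input(
        modulated, hormone_state.beta_ne, exc_sum=plain
    )
    return total * params.leak_conductance
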