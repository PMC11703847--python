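"""Freezing readout, replicate batteries and summary statistics.

The network's behavioural prediction is read from the central medial
amygdala (CeM): an episode is divided into non-overlapping theta windows
(125 ms = 250 iterations, the ~8 Hz network rhythm) and the freezing
percentage is the fraction of windows containing at least one CeM
spike.  Replicate batteries rerun a protocol group from independent
seeds; distributions are summarised with Tukey boxplot statistics and a
running-mean confidence-interval convergence analysis.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import ConfigError, DimensionError

__all__ = [
    "DEFAULT_WINDOW",
    "FreezingReadout",
    "BoxplotSummary",
    "freezing_percent",
    "freezing_readout",
    "run_replicates",
    "replicate_seeds",
    "boxplot_summary",
    "convergence_analysis",
    "export_results",
]

#: iterations per theta window (125 ms at a 0.5 ms step)
DEFAULT_WINDOW = 250


@dataclass(frozen=True)
class FreezingReadout:
    window_length: int
    windows_active: int
    windows_total: int

    @property
    def freezing_percent(self) -> float:
        return 100.0 * self.windows_active / self.windows_total


@dataclass(frozen=True)
class BoxplotSummary:
    median: float
    q1: float
    q3: float
    whisker_low: float
    whisker_high: float
    outliers: tuple[float, ...] = ()


def freezing_readout(
    cem_spike_raster: np.ndarray, window_length: int = DEFAULT_WINDOW
) -> FreezingReadout:
    """Window-count readout over a per-iteration CeM spike-count raster."""
    raster = np.asarray(cem_spike_raster)
    if raster.ndim != 1:
        raise DimensionError("raster must be one-dimensional (counts per step)")
    n = raster.shape[0]
    if window_length < 1 or n < window_length:
        raise ConfigError(
            f"raster of {n} iterations is shorter than one window "
            f"({window_length})"
        )
    windows_total = n // window_length
    trimmed = raster[: windows_total * window_length]
    per_window = trimmed.reshape(windows_total, window_length).sum(axis=1)
    return FreezingReadout(
        window_length=window_length,
        windows_active=int((per_window > 0).sum()),
        windows_total=windows_total,
    )


def freezing_percent(
    cem_spike_raster: np.ndarray, window_length: int = DEFAULT_WINDOW
) -> float:
    """Percentage of theta windows with CeM output activity."""
    return freezing_readout(cem_spike_raster, window_length).freezing_percent


def replicate_seeds(master_seed: int, n_replicates: int) -> list[int]:
    """Distinct per-replicate seeds derived from the master seed."""
    state = np.random.SeedSequence(master_seed).generate_state(
        n_replicates, dtype=np.uint32
    )
    return [int(s % (2**31 - 1)) for s in state]


def run_replicates(
    protocol,
    group_id: str | int,
    n_replicates: int,
    master_seed: int,
    **run_kwargs,
) -> pd.DataFrame:
    """Replicate battery: independent full runs of one protocol group.

    Each replicate gets a fresh network build, Home calibration and a
    complete pass through the group's phases, from a seed derived
    deterministically from ``master_seed``.  Returns one row per
    episode.
    """
    from .protocol_engine import run_group  # local import to avoid a cycle

    if n_replicates < 1:
        raise ConfigError("n_replicates must be >= 1")
    rows = []
    for rep, seed in enumerate(replicate_seeds(master_seed, n_replicates)):
        for res in run_group(protocol, group_id, seed, **run_kwargs):
            rows.append(
                {
                    "replicate": rep,
                    "seed": seed,
                    "group": res.group,
                    "phase": res.phase,
                    "episode": res.episode_index,
                    "phase_episode": res.phase_episode,
                    "expression": res.expression,
                    "freezing_percent": res.freezing_percent,
                    "cem_spike_count": res.cem_spike_count,
                    "beta_ne": res.beta_ne,
                    "beta_cort": res.beta_cort,
                    "ca1_fraction": res.ca1_fraction,
                }
            )
    return pd.DataFrame(rows)


def boxplot_summary(values) -> BoxplotSummary:
    """Tukey five-number summary with 1.5*IQR whiskers and outliers.

    Quartiles use linear interpolation (the common default convention).
    """
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        raise ConfigError("cannot summarise an empty sample")
    q1, med, q3 = np.percentile(arr, [25, 50, 75])
    iqr = q3 - q1
    lo_fence = q1 - 1.5 * iqr
    hi_fence = q3 + 1.5 * iqr
    inside = arr[(arr >= lo_fence) & (arr <= hi_fence)]
    outliers = tuple(float(x) for x in np.sort(arr[(arr < lo_fence) | (arr > hi_fence)]))
    return BoxplotSummary(
        median=float(med),
        q1=float(q1),
        q3=float(q3),
        whisker_low=float(inside.min()),
        whisker_high=float(inside.max()),
        outliers=outliers,
    )


def convergence_analysis(
    per_replicate_means,
    ci_level: float = 0.95,
    tolerance: float = 5.0,
    min_n: int = 3,
) -> int | None:
    """Smallest replicate count with a stably narrow running-mean CI.

    Returns the smallest ``n >= min_n`` such that for every ``m >= n``
    the t-based confidence-interval half-width of the first ``m``
    replicate means is at most ``tolerance`` (percentage points), or
    ``None`` if the sequence never stabilises.
    """
    x = np.asarray(per_replicate_means, dtype=float)
    if x.size < min_n:
        raise ConfigError(f"need at least {min_n} replicate means")
    half_widths = np.empty(x.size + 1)
    half_widths[:min_n] = np.inf
    for m in range(min_n, x.size + 1):
        sem = x[:m].std(ddof=1) / np.sqrt(m)
        tcrit = sps.t.ppf(0.5 + ci_level / 2.0, df=m - 1)
        half_widths[m] = tcrit * sem
    ok = half_widths[min_n:] <= tolerance
    # smallest n such that every m >= n is within tolerance
    suffix_ok = np.flip(np.logical_and.accumulate(np.flip(ok)))
    hits = np.flatnonzero(suffix_ok)
    if hits.size == 0:
        return None
    return int(hits[0]) + min_n


def export_results(
    table: pd.DataFrame,
    summaries: dict,
    path: str | Path,
    *,
    master_seed: int | None = None,
    config_digest: str | None = None,
    figures: bool = False,
) -> dict[str, Path]:
    """Write the episode table (CSV), a run manifest and summaries (JSON).

    Optionally renders per-phase boxplot figures when matplotlib is
    available.  Returns the mapping of artefact names to paths.
    """
    out = Path(path)
    out.mkdir(parents=True, exist_ok=True)
    files: dict[str, Path] = {}

    csv_path = out / "episodes.csv"
    table.to_csv(csv_path, index=False)
    files["episodes"] = csv_path

    import fearsim

    manifest = {
        "fearsim_version": fearsim.__version__,
        "master_seed": master_seed,
        "config_digest": config_digest,
        "n_rows": int(len(table)),
        "table_digest": hashlib.sha256(
            table.to_csv(index=False).encode()
        ).hexdigest(),
    }
    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2))
    files["manifest"] = manifest_path

    summary_path = out / "summaries.json"
    summary_path.write_text(json.dumps(summaries, indent=2, default=_jsonify))
    files["summaries"] = summary_path

    if figures and len(table):
        try:
            import matplotlib

            matplotlib.use("Agg")
            import matplotlib.pyplot as plt
        except ImportError:  # pragma: no cover - plotting is optional
            return files
        fig, ax = plt.subplots(figsize=(8, 4))
        phases = list(dict.fromkeys(table["phase"]))
        data = [
            table.loc[table["phase"] == ph, "freezing_percent"] for ph in phases
        ]
        ax.boxplot(data, tick_labels=phases, sym="r+")
        ax.set_ylabel("freezing (%)")
        fig.tight_layout()
        fig_path = out / "boxplots.png"
        fig.savefig(fig_path, dpi=120)
        plt.close(fig)
        files["boxplots"] = fig_path
    return files


def _jsonify(obj):
    if isinstance(obj, BoxplotSummary):
        return obj.__dict__
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    raise TypeError(f"cannot serialise {type(obj)!r}")
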