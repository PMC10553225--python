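"""Sliding-window global network metrics: phase-lag index, modularity, power.

Window lengths are matched across frequency bands on temporal degrees of
freedom eta = 2 * bandwidth * length, holding the estimator uncertainty
1/sqrt(eta) constant (default 0.15), so that low- and high-frequency
estimates are equally reliable.  Metrics are evaluated on windows centred on
a 1 s observation grid, giving each recording one aligned T x 4 sequence per
metric (one column per band).

The phase-lag index (PLI) of a channel pair is the absolute mean sign of
their wrapped phase differences: 0 for symmetric (including zero-lag)
difference distributions, 1 for a consistent nonzero lag.  Modularity Q of
the PLI graph is Newman-Girvan weighted modularity under the
strength-preserving configuration null, maximised by a seeded two-phase
Louvain heuristic and averaged over repeated runs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .bands import BandDefinition
from .recording import Recording
from .spectral import analytic_signal, design_bandpass, zscore_channels

__all__ = [
    "WindowPlan",
    "plan_windows",
    "wrap_phase",
    "pli",
    "WeightedGraph",
    "global_pli",
    "modularity_q",
    "louvain",
    "consensus_q",
    "ObservationSeries",
    "metric_sequences",
    "METRICS",
]

METRICS = ("pli", "modularity", "power")


@dataclass(frozen=True)
class WindowPlan:
    """Band-specific sliding-window geometry with matched eta."""

    band: BandDefinition
    eta: float
    uncertainty: float
    length: float  # seconds
    step: float = 1.0  # seconds


def plan_windows(
    band: BandDefinition, uncertainty: float = 0.15, step: float = 1.0
) -> WindowPlan:
    """Window length from the matched temporal-degrees-of-freedom rule.

    eta = 1/uncertainty**2 and length = eta / (2 * bandwidth), with
    bandwidth = high - low, so every band carries the same number of
    independent temporal degrees of freedom per window.
    """
    if not (0 < uncertainty < 1):
        raise ValueError("uncertainty must be in (0, 1)")
    if step <= 0:
        raise ValueError("step must be positive")
    bw = band.bandwidth
    if bw <= 0:
        raise ValueError(f"band {band.name!r} has zero bandwidth")
    eta = 1.0 / uncertainty**2
    length = eta / (2.0 * bw)
    return WindowPlan(band, eta, uncertainty, length, step)


def wrap_phase(d: np.ndarray) -> np.ndarray:
    """Wrap angles into (-pi, pi]."""
    w = np.mod(np.asarray(d, dtype=float) + np.pi, 2 * np.pi) - np.pi
    return np.where(w == -np.pi, np.pi, w)


def pli(phase_a: np.ndarray, phase_b: np.ndarray, window: tuple[int, int]) -> float:
    """Phase-lag index of one channel pair over a half-open sample window.

    |mean of sign(wrapped(phase_a - phase_b))| with sign(0) contributing 0,
    so symmetric and zero-lag phase relations score 0 and a consistent
    nonzero lag scores 1.
    """
    start, stop = window
    a = np.asarray(phase_a, dtype=float)
    b = np.asarray(phase_b, dtype=float)
    if not (0 <= start < stop <= min(a.shape[-1], b.shape[-1])):
        raise ValueError(f"empty or out-of-bounds window [{start}, {stop})")
    d = wrap_phase(a[..., start:stop] - b[..., start:stop])
    return float(abs(np.sign(d).mean()))


@dataclass
class WeightedGraph:
    """Symmetric nonnegative weight matrix with zero diagonal."""

    weights: np.ndarray
    node_labels: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        if w.ndim != 2 or w.shape[0] != w.shape[1]:
            raise ValueError("weights must be a square matrix")
        if not np.allclose(w, w.T, atol=1e-12):
            raise ValueError("weights must be symmetric")
        if np.any(np.diag(w) != 0):
            raise ValueError("diagonal must be exactly zero")
        self.weights = w
        if not self.node_labels:
            self.node_labels = tuple(f"n{i}" for i in range(w.shape[0]))
        if len(self.node_labels) != w.shape[0]:
            raise ValueError("node_labels length must match matrix size")

    @property
    def n_nodes(self) -> int:
        return self.weights.shape[0]


def global_pli(
    phases: np.ndarray, window: tuple[int, int], node_labels: tuple[str, ...] = ()
) -> tuple[float, WeightedGraph]:
    """All-pair PLI graph and its global mean over the upper triangle.

    ``phases`` is channels x samples instantaneous phase.
    """
    phases = np.asarray(phases, dtype=float)
    n = phases.shape[0]
    if n < 2:
        raise ValueError("global PLI needs at least 2 channels")
    start, stop = window
    if not (0 <= start < stop <= phases.shape[1]):
        raise ValueError(f"empty or out-of-bounds window [{start}, {stop})")
    iu, ju = np.triu_indices(n, k=1)
    d = wrap_phase(phases[iu, start:stop] - phases[ju, start:stop])
    vals = np.abs(np.sign(d).mean(axis=1))
    w = np.zeros((n, n))
    w[iu, ju] = vals
    w[ju, iu] = vals
    graph = WeightedGraph(w, node_labels)
    return float(vals.mean()), graph


# ---------------------------------------------------------------------------
# modularity and Louvain
# ---------------------------------------------------------------------------

def _q_of_matrix(w: np.ndarray, labels: np.ndarray) -> float:
    """Q over all ordered node pairs with the configuration null.

    ``w`` may carry self-loops (used internally for aggregated graphs); the
    total-weight normaliser is the full-matrix sum.
    """
    total = w.sum()
    if total == 0:
        return 0.0
    k = w.sum(axis=1)
    q = 0.0
    for c in np.unique(labels):
        idx = labels == c
        q += w[np.ix_(idx, idx)].sum() - k[idx].sum() ** 2 / total
    return float(q / total)


def modularity_q(graph: WeightedGraph, partition) -> float:
    """Newman-Girvan weighted modularity of a labelled partition.

    Q = (1/W) * sum_ij (A_ij - s_i s_j / W) delta(m_i, m_j) over ordered
    pairs, where s_i is node strength and W the full-matrix weight total.
    """
    if np.any(graph.weights < 0):
        raise ValueError("modularity is defined for nonnegative weights only")
    labels = np.asarray(partition)
    if labels.shape != (graph.n_nodes,):
        raise ValueError("partition must label every node exactly once")
    return _q_of_matrix(graph.weights, labels)


def _louvain_one_level(w: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Greedy local-move phase: returns a community label per node."""
    n = w.shape[0]
    total = w.sum()
    comm = np.arange(n)
    k = w.sum(axis=1)
    sigma = k.copy()  # strength totals per community label
    improved = True
    while improved:
        improved = False
        for i in rng.permutation(n):
            ci = comm[i]
            sigma[ci] -= k[i]
            # weight from i to each community (excluding the self entry)
            wrow = w[i].copy()
            wrow[i] = 0.0
            w_to = np.bincount(comm, weights=wrow, minlength=n)
            gains = w_to - k[i] * sigma / total
            best = int(np.argmax(gains))
            if gains[best] <= gains[ci] + 1e-12:
                best = ci
            if best != ci:
                improved = True
            comm[i] = best
            sigma[best] += k[i]
    # compact labels
    _, compact = np.unique(comm, return_inverse=True)
    return compact


def _aggregate(w: np.ndarray, comm: np.ndarray) -> np.ndarray:
    n_comm = comm.max() + 1
    onehot = np.zeros((w.shape[0], n_comm))
    onehot[np.arange(w.shape[0]), comm] = 1.0
    return onehot.T @ w @ onehot


def louvain(graph: WeightedGraph, seed: int = 0) -> tuple[np.ndarray, float]:
    """Two-phase Louvain maximisation of weighted modularity.

    Local moves (each node to the neighbouring community with maximal Q
    gain, visiting order randomised by ``seed``) alternate with community
    aggregation until no move improves Q.  Returns (labels, Q); Q never
    decreases across passes.
    """
    if np.any(graph.weights < 0):
        raise ValueError("Louvain is defined for nonnegative weights only")
    rng = np.random.default_rng(seed)
    w = graph.weights.copy()
    n = graph.n_nodes
    membership = np.arange(n)
    if n == 1 or w.sum() == 0:
        return np.zeros(n, dtype=int), 0.0
    while True:
        level_comm = _louvain_one_level(w, rng)
        membership = level_comm[membership]
        if level_comm.max() + 1 == w.shape[0]:
            break
        w = _aggregate(w, level_comm)
    return membership, _q_of_matrix(graph.weights, membership)


def consensus_q(graph: WeightedGraph, runs: int = 100, seed: int = 0) -> float:
    """Mean Q over repeated seeded Louvain runs (default 100).

    Louvain's outcome depends on the node visiting order; averaging over
    randomised orders stabilises the modularity estimate.
    """
    if runs < 1:
        raise ValueError("runs must be >= 1")
    seeds = np.random.SeedSequence(seed).generate_state(runs)
    return float(np.mean([louvain(graph, int(s))[1] for s in seeds]))


# ---------------------------------------------------------------------------
# aligned observation sequences
# ---------------------------------------------------------------------------

@dataclass
class ObservationSeries:
    """T x n_bands metric sequence on the 1 s observation grid."""

    values: np.ndarray
    times: np.ndarray  # seconds at window centres
    condition: np.ndarray  # 'EO'/'EC' per observation
    metric: str
    band_names: tuple[str, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be T x n_bands")
        if len(self.times) != len(self.values) or len(self.condition) != len(self.values):
            raise ValueError("times/condition must match values length")
        if np.isnan(self.values).any():
            raise ValueError("observation sequence contains missing values")
        if not self.band_names:
            self.band_names = tuple(f"b{i}" for i in range(self.values.shape[1]))

    def __len__(self) -> int:
        return len(self.values)

    def to_frame(self):
        import pandas as pd

        df = pd.DataFrame(self.values, columns=list(self.band_names))
        df.insert(0, "condition", self.condition)
        df.insert(0, "time", self.times)
        return df

    @classmethod
    def from_frame(cls, df, metric: str) -> "ObservationSeries":
        bands = [c for c in df.columns if c not in ("time", "condition")]
        return cls(
            df[bands].to_numpy(float),
            df["time"].to_numpy(float),
            df["condition"].to_numpy(str),
            metric,
            tuple(bands),
        )


def _window_bounds(
    centre: float, length: float, rate: float, n_samples: int, edge: int
) -> tuple[int, int]:
    """Sample bounds of a centred window, truncated at the recording edges.

    Filter-transient samples at the ends are excluded when possible; windows
    that would vanish entirely fall back to plain edge truncation.
    """
    start = int(math.ceil((centre - length / 2.0) * rate))
    stop = int(math.floor((centre + length / 2.0) * rate))
    lo, hi = max(start, edge), min(stop, n_samples - edge)
    if hi - lo < 2:
        lo, hi = max(start, 0), min(stop, n_samples)
    if hi - lo < 2:
        raise ValueError(f"window at {centre} s has fewer than 2 samples")
    return lo, hi


def metric_sequences(
    recording: Recording,
    bands: tuple[BandDefinition, ...],
    uncertainty: float = 0.15,
    step: float = 1.0,
    metrics: tuple[str, ...] = METRICS,
    ripple_pct: float = 10.0,
    consensus_runs: int = 100,
    seed: int = 0,
    window_lengths: dict[str, float] | None = None,
) -> dict[str, ObservationSeries]:
    """Compute aligned per-band metric sequences on the 1 s observation grid.

    For each grid point t = 0, step, 2*step, ... and each band, a window of
    the planned (eta-matched) length centred on t — truncated at the
    recording edges — yields the global PLI, the consensus modularity of the
    PLI graph, and the channel-mean band power.  Each observation carries
    the EO/EC condition at its window centre.  ``window_lengths`` overrides
    planned lengths per band name.
    """
    unknown = set(metrics) - set(METRICS)
    if unknown:
        raise ValueError(f"unknown metrics: {sorted(unknown)}")
    if recording.duration < 1.0:
        raise ValueError("recording must be at least 1 s long")
    rec = zscore_channels(recording)
    n_samples = rec.n_samples
    T = int(math.floor(recording.duration / step + 1e-9))
    times = np.arange(T) * step
    condition = np.array(
        [recording.condition_at(t) if recording.schedule else "EO" for t in times]
    )

    plans = [plan_windows(b, uncertainty, step) for b in bands]
    lengths = [
        window_lengths.get(p.band.name, p.length) if window_lengths else p.length
        for p in plans
    ]
    longest = max(lengths)
    if recording.duration <= min(lengths) / 2:
        raise ValueError(
            f"recording ({recording.duration:g} s) shorter than half the "
            f"shortest window ({min(lengths):g} s)"
        )
    del longest

    need_phase = "pli" in metrics or "modularity" in metrics
    n_bands = len(bands)
    out_vals = {m: np.empty((T, n_bands)) for m in metrics}
    mod_seed_root = np.random.SeedSequence(seed)
    band_seeds = mod_seed_root.spawn(n_bands)

    for bi, (band, length) in enumerate(zip(bands, lengths)):
        filt = design_bandpass(band, rec.rate, ripple_pct)
        xf = filt.apply(rec.data)
        series = analytic_signal(xf, rec.rate, filt.edge_samples)
        edge = min(filt.edge_samples, (n_samples - 2) // 2)

        bounds = [
            _window_bounds(t, length, rec.rate, n_samples, edge) for t in times
        ]

        if "power" in metrics:
            p_mean = series.power.mean(axis=0)
            csum = np.concatenate([[0.0], np.cumsum(p_mean)])
            out_vals["power"][:, bi] = [
                (csum[hi] - csum[lo]) / (hi - lo) for lo, hi in bounds
            ]

        if need_phase:
            n = rec.n_channels
            iu, ju = np.triu_indices(n, k=1)
            d = wrap_phase(series.phase[iu] - series.phase[ju])
            signs = np.sign(d).astype(np.int8)
            del d
            csgn = np.concatenate(
                [np.zeros((len(iu), 1), np.int32), np.cumsum(signs, axis=1, dtype=np.int32)],
                axis=1,
            )
            del signs
            pair_pli = np.empty((T, len(iu)))
            for wi, (lo, hi) in enumerate(bounds):
                pair_pli[wi] = np.abs(csgn[:, hi] - csgn[:, lo]) / (hi - lo)
            del csgn
            if "pli" in metrics:
                out_vals["pli"][:, bi] = pair_pli.mean(axis=1)
            if "modularity" in metrics:
                win_seeds = band_seeds[bi].generate_state(T)
                for wi in range(T):
                    w = np.zeros((n, n))
                    w[iu, ju] = pair_pli[wi]
                    w[ju, iu] = pair_pli[wi]
                    graph = WeightedGraph(w, rec.channel_names)
                    out_vals["modularity"][wi, bi] = consensus_q(
                        graph, consensus_runs, int(win_seeds[wi])
                    )
            del pair_pli

    band_names = tuple(b.name for b in bands)
    return {
        m: ObservationSeries(out_vals[m], times, condition, m, band_names)
        for m in metrics
    }
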