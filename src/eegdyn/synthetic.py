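"""Ground-truth generators: state-switching recordings and phenotype cohorts.

Every downstream stage is verified against data built here.  Recordings are
sums of band-limited noise (white noise passed through the same band-pass
filters as the analysis path, so generator and analyser agree on band
definitions) whose per-band amplitudes follow a hidden state path switching
on whole-second boundaries.  Cohorts simulate per-participant hidden-state
paths on the alternating 20 s eyes-open / 40 s eyes-closed schedule, with an
eyes-closed-boosted state emulating the posterior alpha rise with eye
closure, and link behavioural phenotypes linearly to the true dwell-times.

The generators deliberately do not mimic 1/f spectra, ocular artifacts or
volume conduction; they provide the statistical structure the analysis
assumes, with known ground truth.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .bands import BandDefinition, default_bands
from .recording import Recording, eo_ec_schedule
from .spectral import design_bandpass
from .state_model import DwellProfile

__all__ = [
    "StateProfile",
    "GroundTruth",
    "make_state_sequence",
    "make_recording",
    "make_cohort",
    "write_ground_truth",
]


@dataclass(frozen=True)
class StateProfile:
    """Emission profile of one hidden state.

    ``band_gains`` are nonnegative amplitude multipliers for the four bands
    (delta, theta, alpha, beta).  If ``coupling_lag`` is set, the channels
    in ``coupling_channels`` share a common band-limited driver in
    ``coupling_band`` with that constant phase offset (radians, in
    (-pi, pi]) between consecutive channels — giving an analytically known
    pairwise PLI of 1 in the noise-free limit.  ``community_spec``
    optionally partitions channels into driver groups that each share a
    group driver with small constant intra-group lags, producing a modular
    connectivity topology.
    """

    band_gains: tuple[float, ...]
    coupling_lag: float | None = None
    coupling_channels: tuple[int, ...] = ()
    coupling_band: str = "alpha"
    community_spec: tuple[tuple[int, ...], ...] = ()

    def __post_init__(self) -> None:
        g = np.asarray(self.band_gains, float)
        if not np.all(np.isfinite(g)) or np.any(g < 0):
            raise ValueError("band_gains must be finite and nonnegative")
        if self.coupling_lag is not None:
            if not (-np.pi < self.coupling_lag <= np.pi):
                raise ValueError("coupling_lag must lie in (-pi, pi]")
            if len(self.coupling_channels) < 2:
                raise ValueError("coupling requires at least 2 channels")
        if self.community_spec and self.coupling_lag is not None:
            raise ValueError("use either pairwise coupling or community_spec, not both")


@dataclass
class GroundTruth:
    """Ground truth attached to generated data (recovery oracle)."""

    hidden_path: np.ndarray
    true_dwell: np.ndarray
    phenotype_betas: dict | None
    seed: int

    def __post_init__(self) -> None:
        self.hidden_path = np.asarray(self.hidden_path, int)
        self.true_dwell = np.asarray(self.true_dwell, float)
        sums = np.atleast_2d(self.true_dwell).sum(axis=1)
        if not np.allclose(sums, 1.0, atol=1e-9):
            raise ValueError("true_dwell rows must sum to 1")


def write_ground_truth(gt: GroundTruth, path: str | Path) -> None:
    """Serialise ground truth to JSON."""
    payload = {
        "hidden_path": gt.hidden_path.tolist(),
        "true_dwell": gt.true_dwell.tolist(),
        "phenotype_betas": {
            k: np.asarray(v, float).tolist() for k, v in gt.phenotype_betas.items()
        }
        if gt.phenotype_betas
        else None,
        "seed": gt.seed,
    }
    Path(path).write_text(json.dumps(payload, indent=1))


def make_state_sequence(
    transition_matrix: np.ndarray,
    initial: np.ndarray,
    T: int,
    seed: int = 0,
) -> np.ndarray:
    """Simulate a hidden state path from a Markov chain.

    Empirical transition frequencies converge to ``transition_matrix`` as T
    grows.  States are 0-based.
    """
    P = np.asarray(transition_matrix, float)
    pi = np.asarray(initial, float)
    if P.ndim != 2 or P.shape[0] != P.shape[1]:
        raise ValueError("transition_matrix must be square")
    if np.any(P < 0) or not np.allclose(P.sum(axis=1), 1.0, atol=1e-9):
        raise ValueError("transition_matrix rows must sum to 1")
    if np.any(pi < 0) or abs(pi.sum() - 1.0) > 1e-9:
        raise ValueError("initial must lie on the probability simplex")
    if T < 1:
        raise ValueError("T must be >= 1")
    rng = np.random.default_rng(seed)
    n = P.shape[0]
    path = np.empty(T, dtype=int)
    path[0] = rng.choice(n, p=pi)
    for t in range(1, T):
        path[t] = rng.choice(n, p=P[path[t - 1]])
    return path


def _phase_shift(x: np.ndarray, lag: float) -> np.ndarray:
    """Constant phase delay of a band-limited signal via its analytic extension."""
    from scipy.signal import hilbert

    return np.real(hilbert(x) * np.exp(-1j * lag))


def make_recording(
    path: np.ndarray,
    profiles: tuple[StateProfile, ...],
    n_channels: int = 32,
    rate: float = 250.0,
    noise_sd: float = 0.1,
    seed: int = 0,
    bands: tuple[BandDefinition, ...] | None = None,
    eo_seconds: float = 20.0,
    ec_seconds: float = 40.0,
) -> tuple[Recording, GroundTruth]:
    """Render a hidden state path as an N-channel band-limited recording.

    Each channel is a sum over bands of filtered white noise scaled by the
    active state's band gain (states switch on whole-second boundaries,
    aligned with the 1 s observation grid), plus white sensor noise of SD
    ``noise_sd``.  States may route designated channels through shared
    phase-lagged drivers (see :class:`StateProfile`).  The EO/EC schedule is
    attached as alternating ``eo_seconds``/``ec_seconds`` blocks.
    """
    path = np.asarray(path, int)
    bands = bands if bands is not None else default_bands()
    n_states = len(profiles)
    if path.min() < 0 or path.max() >= n_states:
        raise ValueError("path indexes a state with no profile")
    for pr in profiles:
        if len(pr.band_gains) != len(bands):
            raise ValueError("each profile needs one gain per band")
    top = max(b.high + b.transition_width for b in bands)
    if rate < 2 * top:
        raise ValueError(
            f"rate {rate:g} Hz is below twice the highest band edge ({top:g} Hz)"
        )

    T = len(path)
    n_samples = int(round(T * rate))
    rng = np.random.default_rng(seed)
    data = np.zeros((n_channels, n_samples))
    spp = int(round(rate))  # samples per path step (1 s grid)
    state_mask = {
        s: np.repeat(path == s, spp) for s in np.unique(path)
    }

    for bi, band in enumerate(bands):
        filt = design_bandpass(band, rate)
        needed = any(pr.band_gains[bi] > 0 for pr in profiles)
        if not needed:
            continue
        noise = filt.apply(rng.standard_normal((n_channels, n_samples)))
        # normalise band noise to unit RMS so gains are comparable across bands
        rms = noise.std(axis=1, keepdims=True)
        noise /= np.where(rms == 0, 1.0, rms)
        drivers: dict[tuple, np.ndarray] = {}

        gain_per_sample = np.zeros(n_samples)
        for s, pr in enumerate(profiles):
            if s in state_mask:
                gain_per_sample[state_mask[s]] = pr.band_gains[bi]
        band_contrib = noise * gain_per_sample

        for s, pr in enumerate(profiles):
            if s not in state_mask or pr.band_gains[bi] == 0:
                continue
            groups: list[tuple[tuple[int, ...], float]] = []
            if pr.coupling_lag is not None and pr.coupling_band == band.name:
                groups.append((pr.coupling_channels, pr.coupling_lag))
            for grp in pr.community_spec:
                groups.append((grp, 0.3))  # small fixed intra-group lag step
            for chans, lag_step in groups:
                key = (band.name, chans)
                if key not in drivers:
                    d = filt.apply(rng.standard_normal(n_samples))
                    d /= d.std() or 1.0
                    drivers[key] = d
                d = drivers[key]
                mask = state_mask[s]
                for rank, ch in enumerate(chans):
                    shifted = d if rank == 0 else _phase_shift(d, rank * lag_step)
                    band_contrib[ch, mask] = shifted[mask] * pr.band_gains[bi]

        data += band_contrib

    if noise_sd > 0:
        data += noise_sd * rng.standard_normal(data.shape)

    rec = Recording(
        data, rate, schedule=eo_ec_schedule(T, eo_seconds, ec_seconds)
    )
    dwell = np.bincount(path, minlength=n_states) / T
    return rec, GroundTruth(path, dwell, None, seed)


# ---------------------------------------------------------------------------
# cohorts
# ---------------------------------------------------------------------------

CELLS = (("ADHD", "F"), ("ADHD", "M"), ("Control", "F"), ("Control", "M"))

_RESERVED = ("rt_mean", "rt_sd", "p_correct")


def _condition_chain(
    occupancy: np.ndarray, stickiness: float
) -> np.ndarray:
    """Markov matrix with stationary distribution ``occupancy``."""
    n = len(occupancy)
    return stickiness * np.eye(n) + (1 - stickiness) * np.tile(occupancy, (n, 1))


def make_cohort(
    n_per_cell: int = 28,
    group_effects: dict | None = None,
    phenotype_betas: dict | None = None,
    noise_sd: float = 0.05,
    seed: int = 0,
    n_states: int = 4,
    base_occupancy: np.ndarray | None = None,
    ec_boost_state: int = 1,
    ec_boost_factor: float = 3.0,
    stickiness: float = 0.8,
    duration: float = 300.0,
    n_trials: int = 72,
) -> tuple[pd.DataFrame, GroundTruth]:
    """Generate a balanced 2 x 2 (diagnosis x sex) cohort with known linkage.

    Each participant's hidden state path is simulated on the EO/EC block
    schedule; during eyes-closed blocks the occupancy of ``ec_boost_state``
    is multiplied by ``ec_boost_factor`` (renormalised), emulating the alpha
    rise with eye closure.  ``group_effects`` maps (group, sex) cells to
    additive occupancy shifts.  ``phenotype_betas`` maps score names to
    length-``n_states`` coefficient vectors; scores are
    ``intercept + beta . dwell + N(0, noise_sd)``.  The reserved names
    ``rt_mean``/``rt_sd``/``p_correct`` set participant-level trial
    parameters instead: a synthetic trial table is drawn and the response
    control columns (rt_mean, rt_sd, prop_correct) are computed from it.

    Returns the cohort table (one row per participant: ids, group, sex,
    age, scores, response control, overall and per-condition dwell columns)
    and a :class:`GroundTruth` holding all hidden paths and the betas.
    """
    if n_per_cell < 2:
        raise ValueError("n_per_cell must be >= 2")
    if base_occupancy is None:
        base_occupancy = np.full(n_states, 1.0 / n_states)
    base_occupancy = np.asarray(base_occupancy, float)
    if len(base_occupancy) != n_states:
        raise ValueError("base_occupancy length must equal n_states")
    if phenotype_betas is None:
        v = np.zeros(n_states)
        v[ec_boost_state] = -0.3
        phenotype_betas = {"rt_sd": v}
    phenotype_betas = {
        k: np.asarray(v, float) * np.ones(n_states) for k, v in phenotype_betas.items()
    }
    intercepts = {"rt_mean": 1.6, "rt_sd": 0.35, "p_correct": 0.8}

    rng = np.random.default_rng(seed)
    schedule = eo_ec_schedule(duration)
    T = int(round(duration))
    sec_labels = np.array(
        [next(iv.label for iv in schedule if iv.start <= t < iv.end) for t in range(T)]
    )

    rows = []
    paths = np.empty((4 * n_per_cell, T), dtype=int)
    dwells = np.empty((4 * n_per_cell, n_states))
    pid = 0
    for group, sex in CELLS:
        occ = base_occupancy.copy()
        if group_effects and (group, sex) in group_effects:
            occ = occ + np.asarray(group_effects[(group, sex)], float)
            if np.any(occ <= 0):
                raise ValueError("group_effects push occupancy below zero")
        occ = occ / occ.sum()
        boost = np.ones(n_states)
        boost[ec_boost_state] = ec_boost_factor
        occ_ec = occ * boost
        occ_ec /= occ_ec.sum()
        P = {"EO": _condition_chain(occ, stickiness),
             "EC": _condition_chain(occ_ec, stickiness)}
        pi0 = {"EO": occ, "EC": occ_ec}

        # simulate all paths in this cell at once (inverse-CDF per step)
        cell_paths = np.empty((n_per_cell, T), dtype=int)
        cum0 = np.cumsum(pi0[sec_labels[0]])
        cumP = {lab: np.cumsum(P[lab], axis=1) for lab in ("EO", "EC")}
        cell_paths[:, 0] = np.searchsorted(cum0, rng.random(n_per_cell))
        for t in range(1, T):
            u = rng.random(n_per_cell)
            rowcum = cumP[sec_labels[t]][cell_paths[:, t - 1]]
            cell_paths[:, t] = (u[:, None] > rowcum).sum(axis=1)
        for ci in range(n_per_cell):
            path = cell_paths[ci]
            paths[pid] = path
            dwell = np.bincount(path, minlength=n_states) / T
            dwells[pid] = dwell
            row = {
                "participant_id": f"p{pid + 1:03d}",
                "group": group,
                "sex": sex,
                "age": float(rng.uniform(8.0, 17.0)),
            }
            # participant-level trial parameters, linearly linked to dwell
            trial_par = {}
            for name in _RESERVED:
                val = intercepts[name]
                if name in phenotype_betas:
                    val = val + float(phenotype_betas[name] @ dwell)
                val += rng.normal(0.0, noise_sd) if noise_sd > 0 else 0.0
                trial_par[name] = val
            trial_par["rt_sd"] = max(trial_par["rt_sd"], 1e-6)
            trial_par["p_correct"] = float(np.clip(trial_par["p_correct"], 0.0, 1.0))
            rts = rng.normal(trial_par["rt_mean"], trial_par["rt_sd"], size=n_trials)
            rts = np.clip(rts, 0.2, None)
            correct = rng.random(n_trials) < trial_par["p_correct"]
            if correct.any():
                row["rt_mean"] = float(rts[correct].mean())
                row["rt_sd"] = float(rts[correct].std(ddof=1)) if correct.sum() > 1 else 0.0
            else:
                row["rt_mean"] = np.nan
                row["rt_sd"] = np.nan
            row["prop_correct"] = float(correct.mean())
            # direct behavioural scores
            for name, beta in phenotype_betas.items():
                if name in _RESERVED:
                    continue
                val = float(beta @ dwell)
                if noise_sd > 0:
                    val += rng.normal(0.0, noise_sd)
                row[name] = val
            for s in range(n_states):
                row[f"dwell_s{s + 1}"] = dwell[s]
            for lab in ("EO", "EC"):
                sel = path[sec_labels == lab]
                if sel.size == 0:  # schedule too short to reach this condition
                    d = np.full(n_states, np.nan)
                else:
                    d = np.bincount(sel, minlength=n_states) / sel.size
                for s in range(n_states):
                    row[f"dwell_s{s + 1}_{lab}"] = d[s]
            rows.append(row)
            pid += 1

    table = pd.DataFrame(rows)
    gt = GroundTruth(paths, dwells, phenotype_betas, seed)
    return table, gt


def cohort_dwell_profiles(table: pd.DataFrame, n_states: int) -> list[DwellProfile]:
    """Reconstruct per-participant dwell profiles from a cohort table."""
    profiles = []
    for _, row in table.iterrows():
        overall = np.array([row[f"dwell_s{s + 1}"] for s in range(n_states)])
        by_cond = {
            lab: np.array([row[f"dwell_s{s + 1}_{lab}"] for s in range(n_states)])
            for lab in ("EO", "EC")
        }
        profiles.append(DwellProfile(overall, by_cond))
    return profiles
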