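"""Evoked-EPSC detection from paired whole-cell recordings.

A presynaptic cell is driven to spike while a putative postsynaptic cell is
held in voltage clamp at -70 mV, so a monosynaptic excitatory response is an
inward (negative-going) current deflection time-locked to the stimulus. The
calling rule: baseline mean and SD are measured over the 1 s preceding the
stimulus; a deflection within 3 ms after the stimulus exceeding 3x the
baseline SD, with trial-to-trial onset jitter below 0.2 ms, over at least
10 trials, counts as a meaningful EPSC. Pairwise calls over a recording
session (up to 6 simultaneously patched cells) assemble into a directed
adjacency matrix.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np


@dataclass
class SweepSet:
    """Repeated trials of one ordered (pre, post) pair.

    ``traces`` holds postsynaptic currents in pA, shape (n_trials, n_samples),
    all trials aligned on the same stimulus time.
    """

    traces: np.ndarray
    stim_time: float
    presynaptic_cell: str
    postsynaptic_cell: str
    sampling_rate: float = 20_000.0

    def __post_init__(self) -> None:
        try:
            self.traces = np.atleast_2d(np.asarray(self.traces, dtype=float))
        except ValueError as err:
            raise ValueError("all trials must have the same length") from err
        if self.traces.ndim != 2:
            raise ValueError("traces must be 2-D (trials x samples)")
        if self.stim_time < 1.0:
            raise ValueError("stimulus must be at least 1 s into the trace "
                             "so the baseline window fits")

    @property
    def n_trials(self) -> int:
        return self.traces.shape[0]

    @property
    def n_samples(self) -> int:
        return self.traces.shape[1]


@dataclass(frozen=True)
class DetectionParams:
    """Constants of the EPSC criterion.

    baseline_window : s, pre-stimulus span for baseline mean/SD (1.0)
    response_window : s, post-stimulus detection window (0.003)
    threshold_sd    : baseline-SD multiplier for the amplitude criterion (3)
    max_jitter      : s, upper bound on trial-to-trial onset jitter (0.0002)
    min_trials      : minimum trial count per ordered pair (10)
    min_trial_fraction : fraction of trials that must individually cross
        threshold for a call (artifact guard; 0.5)
    jitter_stat     : "sd" (SD of per-trial onsets) or "range" (max - min)
    baseline_sd_mode: "mean" (mean of per-trial SDs) or "pooled"
    min_crossing_samples : consecutive supra-threshold samples required for
        an onset; rejects single-sample noise spikes that would otherwise
        produce spurious early onsets and inflate the jitter estimate (2)
    """

    baseline_window: float = 1.0
    response_window: float = 0.003
    threshold_sd: float = 3.0
    max_jitter: float = 0.0002
    min_trials: int = 10
    min_trial_fraction: float = 0.5
    jitter_stat: str = "sd"
    baseline_sd_mode: str = "mean"
    min_crossing_samples: int = 2

    def __post_init__(self) -> None:
        for name in ("baseline_window", "response_window", "threshold_sd",
                     "max_jitter", "min_trials", "min_trial_fraction"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class EPSCCall:
    connected: bool
    mean_latency: float | None
    jitter: float | None
    amplitude: float | None
    per_trial_latencies: np.ndarray
    reason: str  # "ok" or a rejection code


@dataclass
class DirectedAdjacency:
    """Directed connectivity over a recording session."""

    cell_ids: list[str]
    connected: np.ndarray  # bool (n, n); diagonal always False
    tested: np.ndarray     # bool (n, n); False for missing ordered pairs
    calls: dict[tuple[str, str], EPSCCall]

    def n_connected(self) -> int:
        return int(self.connected.sum())

    def pair_summary(self) -> dict[str, int]:
        """Unordered-pair view: counts of unidirectional and bidirectional pairs."""
        n = len(self.cell_ids)
        uni = bi = 0
        for i in range(n):
            for j in range(i + 1, n):
                fwd, rev = self.connected[i, j], self.connected[j, i]
                if fwd and rev:
                    bi += 1
                elif fwd or rev:
                    uni += 1
        return {"unidirectional": uni, "bidirectional": bi,
                "possible_pairs": n * (n - 1) // 2}


def _first_crossing(trace: np.ndarray, baseline_mean: float, threshold: float,
                    start: int, stop: int, sustained: int = 1) -> int | None:
    """Index of the first sample in [start, stop) opening a run of at least
    ``sustained`` consecutive samples whose inward deflection
    (baseline_mean - trace) exceeds threshold, or None."""
    above = (baseline_mean - trace[start:stop]) > threshold
    if sustained > 1:
        run = above.copy()
        for shift in range(1, sustained):
            shifted = np.zeros_like(above)
            shifted[:-shift or None] = above[shift:]
            run &= shifted
        above = run
    hits = np.nonzero(above)[0]
    return int(start + hits[0]) if hits.size else None


def detect_epsc(sweeps: SweepSet, params: DetectionParams = DetectionParams()) -> EPSCCall:
    """Apply the EPSC criterion to one ordered pair's sweep set.

    Baseline statistics come from the window ending at the stimulus; the
    amplitude criterion is evaluated on the trial-averaged trace (recordings
    are conventionally displayed and measured as averages), onsets are also
    measured per trial, and the call requires (i) an average-trace
    threshold crossing inside the response window, (ii) individual
    crossings in at least ``min_trial_fraction`` of trials, and (iii)
    onset jitter below ``max_jitter``.
    """
    if sweeps.n_trials < params.min_trials:
        raise ValueError(
            f"need at least min_trials={params.min_trials} trials, "
            f"got {sweeps.n_trials}")
    fs = sweeps.sampling_rate
    stim = int(round(sweeps.stim_time * fs))
    base_start = stim - int(round(params.baseline_window * fs))
    if base_start < 0:
        raise ValueError("baseline window does not fit before the stimulus")
    win_stop = min(stim + int(round(params.response_window * fs)) + 1,
                   sweeps.n_samples)

    baseline = sweeps.traces[:, base_start:stim]
    trial_means = baseline.mean(axis=1)
    trial_sds = baseline.std(axis=1, ddof=0)
    if params.baseline_sd_mode == "mean":
        sd = float(trial_sds.mean())
    elif params.baseline_sd_mode == "pooled":
        sd = float(np.sqrt(np.mean((baseline - trial_means[:, None]) ** 2)))
    else:
        raise ValueError(f"unknown baseline_sd_mode: {params.baseline_sd_mode!r}")
    threshold = params.threshold_sd * sd

    avg = sweeps.traces.mean(axis=0)
    avg_onset = _first_crossing(avg, float(trial_means.mean()), threshold,
                                stim + 1, win_stop,
                                sustained=params.min_crossing_samples)

    onsets = []
    for t in range(sweeps.n_trials):
        idx = _first_crossing(sweeps.traces[t], float(trial_means[t]), threshold,
                              stim + 1, win_stop,
                              sustained=params.min_crossing_samples)
        if idx is not None:
            onsets.append((idx - stim) / fs)
    latencies = np.asarray(onsets)

    if avg_onset is None:
        return EPSCCall(False, None, None, None, latencies, "no_average_crossing")
    frac = len(onsets) / sweeps.n_trials
    mean_latency = float(latencies.mean()) if latencies.size else None
    window = avg[stim + 1:win_stop]
    amplitude = float(np.max(trial_means.mean() - window))
    if frac < params.min_trial_fraction:
        return EPSCCall(False, mean_latency, None, amplitude, latencies,
                        "too_few_trial_crossings")
    if params.jitter_stat == "sd":
        jitter = float(latencies.std(ddof=0))
    elif params.jitter_stat == "range":
        jitter = float(latencies.max() - latencies.min())
    else:
        raise ValueError(f"unknown jitter_stat: {params.jitter_stat!r}")
    if jitter >= params.max_jitter:
        return EPSCCall(False, mean_latency, jitter, amplitude, latencies,
                        "jitter_too_large")
    return EPSCCall(True, mean_latency, jitter, amplitude, latencies, "ok")


def build_adjacency(session, params: DetectionParams = DetectionParams()) -> DirectedAdjacency:
    """Call every ordered pair of a session and assemble the directed matrix.

    ``session`` is a collection of SweepSet, one per tested ordered pair;
    each ordered pair may appear at most once and the session may involve at
    most 6 cells. Untested ordered pairs are marked in ``tested`` and carry
    no call.
    """
    cells: list[str] = []
    for sw in session:
        for c in (sw.presynaptic_cell, sw.postsynaptic_cell):
            if c not in cells:
                cells.append(c)
    if len(cells) > 6:
        raise ValueError("a session involves at most 6 simultaneously patched cells")
    idx = {c: i for i, c in enumerate(cells)}
    n = len(cells)
    connected = np.zeros((n, n), dtype=bool)
    tested = np.zeros((n, n), dtype=bool)
    calls: dict[tuple[str, str], EPSCCall] = {}
    for sw in session:
        key = (sw.presynaptic_cell, sw.postsynaptic_cell)
        if key in calls:
            raise ValueError(f"duplicate ordered pair: {key[0]} -> {key[1]}")
        call = detect_epsc(sw, params)
        calls[key] = call
        i, j = idx[key[0]], idx[key[1]]
        tested[i, j] = True
        connected[i, j] = call.connected
    return DirectedAdjacency(cell_ids=cells, connected=connected,
                             tested=tested, calls=calls)


# ---------------------------------------------------------------------------
# Sweep I/O: plain text with a metadata header, or HDF5.

def write_sweeps_text(sweeps: SweepSet, path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(f"# sampling_rate: {sweeps.sampling_rate}\n")
        fh.write(f"# stim_time: {sweeps.stim_time}\n")
        fh.write(f"# presynaptic_cell: {sweeps.presynaptic_cell}\n")
        fh.write(f"# postsynaptic_cell: {sweeps.postsynaptic_cell}\n")
        np.savetxt(fh, sweeps.traces, fmt="%.6g", delimiter="\t")
    return path


def read_sweeps_text(path: str | Path) -> SweepSet:
    meta: dict[str, str] = {}
    rows = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#"):
                key, _, value = line[1:].partition(":")
                meta[key.strip()] = value.strip()
            elif line.strip():
                rows.append(np.fromstring(line, sep="\t"))
    return SweepSet(traces=np.vstack(rows),
                    stim_time=float(meta["stim_time"]),
                    presynaptic_cell=meta["presynaptic_cell"],
                    postsynaptic_cell=meta["postsynaptic_cell"],
                    sampling_rate=float(meta.get("sampling_rate", 20_000)))


def write_sweeps_hdf5(session, path: str | Path) -> Path:
    import h5py

    path = Path(path)
    with h5py.File(path, "w") as f:
        for k, sw in enumerate(session):
            g = f.create_group(f"pair_{k:03d}")
            g.create_dataset("traces", data=sw.traces, compression="gzip")
            g.attrs.update({"sampling_rate": sw.sampling_rate,
                            "stim_time": sw.stim_time,
                            "presynaptic_cell": sw.presynaptic_cell,
                            "postsynaptic_cell": sw.postsynaptic_cell})
    return path


def read_sweeps_hdf5(path: str | Path) -> list[SweepSet]:
    import h5py

    out = []
    with h5py.File(path, "r") as f:
        for name in sorted(f):
            g = f[name]
            out.append(SweepSet(traces=g["traces"][()],
                                stim_time=float(g.attrs["stim_time"]),
                                presynaptic_cell=str(g.attrs["presynaptic_cell"]),
                                postsynaptic_cell=str(g.attrs["postsynaptic_cell"]),
                                sampling_rate=float(g.attrs["sampling_rate"])))
    return out
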