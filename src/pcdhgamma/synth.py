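"""Synthetic data generators with the statistical structure the analyses assume.

Three generators cover the three experimental data modalities:

* ``gen_expression_matrix`` -- cell x isoform UMI counts with near-ubiquitous
  C-type expression (p ~ 0.9), sparse variable-isoform expression
  (p in [0.05, 0.4]), and tunable co-occurrence via a shared per-cell
  propensity scaling all expression probabilities.
* ``gen_session`` -- multi-electrode patch-clamp sweep sets with planted
  EPSCs (difference-of-exponentials kernel, configurable amplitude, latency,
  jitter) on a ground-truth directed adjacency, plus Gaussian noise.
* ``gen_pair_table`` -- Bernoulli pair-outcome tables at stated group
  probabilities, with an exact-count mode for encoding published
  connected/tested tallies.

All generators are deterministic given their seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .connectivity import PairRecord, PairTable
from .epsc import SweepSet
from .matrix import IsoformCountMatrix
from .registry import DEFAULT_REGISTRY, IsoformRegistry

#: Default coupling strength: a subtle shared-propensity effect, strong
#: enough to be detected reliably at ~2000 cells but far from saturating.
DEFAULT_COUPLING = 0.1


def default_frequencies(registry: IsoformRegistry = DEFAULT_REGISTRY) -> np.ndarray:
    """Target expression probabilities: variable isoforms spread over
    [0.05, 0.4], C-type isoforms at 0.9."""
    p_var = np.linspace(0.05, 0.4, registry.n_variable)
    p_cty = np.full(registry.n_ctype, 0.9)
    return np.concatenate([p_var, p_cty])


@dataclass
class ExpressionGenParams:
    n_cells: int = 2000
    freqs: np.ndarray | None = None  # default: default_frequencies(registry)
    coupling: float = DEFAULT_COUPLING  # rho >= 0; 0 = independent columns
    depth: float = 8.0  # mean UMI per expressed isoform (shifted Poisson)
    background_p: float = 0.02  # chance an unexpressed entry shows 1 stray UMI
    seed: int | None = None
    registry: IsoformRegistry = field(default_factory=lambda: DEFAULT_REGISTRY)

    def __post_init__(self) -> None:
        if self.freqs is None:
            self.freqs = default_frequencies(self.registry)
        self.freqs = np.asarray(self.freqs, dtype=float)
        if self.freqs.shape != (self.registry.n_isoforms,):
            raise ValueError("freqs must have one entry per registry isoform")
        if np.any((self.freqs < 0) | (self.freqs > 1)):
            raise ValueError("freqs must lie in [0, 1]")
        if self.coupling < 0:
            raise ValueError("coupling must be >= 0")
        if self.depth < 2:
            raise ValueError("depth must be >= 2 so expressed entries exceed the "
                             ">1 UMI cutoff")


def gen_expression_matrix(params: ExpressionGenParams) -> IsoformCountMatrix:
    """Simulate a UMI count matrix with optional cross-isoform coupling.

    Per cell c a latent propensity a_c with unit mean and variance equal to
    ``coupling`` (lognormal) scales every expression probability to
    min(1, a_c * p_i); expression is Bernoulli at that scaled probability.
    Expressed entries receive 2 + Poisson(depth - 2) UMIs (guaranteed to
    survive the >1 UMI binarization cutoff); unexpressed entries are 0, or 1
    with probability ``background_p`` (sub-threshold ambient counts). With
    ``coupling=0`` all columns are independent Bernoulli(p_i).
    """
    rng = np.random.default_rng(params.seed)
    n, p = params.n_cells, params.freqs
    if params.coupling > 0:
        sigma2 = np.log1p(params.coupling)
        a = rng.lognormal(mean=-sigma2 / 2, sigma=np.sqrt(sigma2), size=n)
    else:
        a = np.ones(n)
    p_cell = np.minimum(a[:, None] * p[None, :], 1.0)
    expressed = rng.random((n, p.size)) < p_cell
    counts = np.zeros((n, p.size), dtype=np.int64)
    counts[expressed] = 2 + rng.poisson(params.depth - 2, size=int(expressed.sum()))
    stray = (~expressed) & (rng.random((n, p.size)) < params.background_p)
    counts[stray] = 1
    cell_ids = [f"cell{i:05d}" for i in range(n)]
    return IsoformCountMatrix(cell_ids=cell_ids, registry=params.registry,
                              counts=counts)


@dataclass
class SessionGenParams:
    n_cells: int = 4
    adjacency: list[tuple[int, int]] = field(default_factory=list)  # (pre, post)
    epsc_amplitude: float = 50.0   # pA, peak of the planted kernel
    epsc_latency: float = 0.0015   # s after the stimulus
    latency_jitter_sd: float = 5e-5  # s, per-trial Gaussian jitter
    noise_sd: float = 5.0          # pA white noise
    n_trials: int = 10
    sampling_rate: float = 20_000.0
    stim_time: float = 1.0
    trace_duration: float = 1.05
    rise_tau: float = 0.0005       # s, kernel rise time constant
    decay_tau: float = 0.005       # s, kernel decay time constant
    seed: int | None = None

    def __post_init__(self) -> None:
        if not 1 <= self.n_cells <= 6:
            raise ValueError("n_cells must be between 1 and 6")
        for pre, post in self.adjacency:
            if not (0 <= pre < self.n_cells and 0 <= post < self.n_cells
                    and pre != post):
                raise ValueError(f"invalid adjacency entry ({pre}, {post})")
        if self.epsc_amplitude < 0 or self.noise_sd < 0:
            raise ValueError("amplitudes must be non-negative")
        if self.n_trials < 1:
            raise ValueError("n_trials must be >= 1")


def _epsc_kernel(t: np.ndarray, rise: float, decay: float) -> np.ndarray:
    """Difference-of-exponentials synaptic waveform, normalized to unit peak."""
    k = np.exp(-t / decay) - np.exp(-t / rise)
    peak = k.max()
    return k / peak if peak > 0 else k


def gen_sweepset(
    connected: bool,
    params: SessionGenParams,
    rng: np.random.Generator,
    pre: str = "cell0",
    post: str = "cell1",
) -> SweepSet:
    """One ordered pair's sweep set: noise, plus a planted EPSC if connected."""
    fs = params.sampling_rate
    n_samples = int(round(params.trace_duration * fs))
    traces = rng.normal(0.0, params.noise_sd, size=(params.n_trials, n_samples))
    if connected and params.epsc_amplitude > 0:
        stim = int(round(params.stim_time * fs))
        tail = np.arange(n_samples) / fs
        kernel = _epsc_kernel(tail, params.rise_tau, params.decay_tau)
        for trial in range(params.n_trials):
            lat = params.epsc_latency + rng.normal(0.0, params.latency_jitter_sd)
            onset = stim + max(int(round(lat * fs)), 1)
            span = n_samples - onset
            if span > 0:
                traces[trial, onset:] -= params.epsc_amplitude * kernel[:span]
    return SweepSet(traces=traces, stim_time=params.stim_time,
                    presynaptic_cell=pre, postsynaptic_cell=post,
                    sampling_rate=fs)


def gen_session(params: SessionGenParams) -> list[SweepSet]:
    """Sweep sets for every ordered pair of a simulated recording session."""
    rng = np.random.default_rng(params.seed)
    adjacency = set(params.adjacency)
    session = []
    for pre in range(params.n_cells):
        for post in range(params.n_cells):
            if pre == post:
                continue
            session.append(gen_sweepset((pre, post) in adjacency, params, rng,
                                        pre=f"cell{pre}", post=f"cell{post}"))
    return session


@dataclass
class GroupSpec:
    label: str
    probability: float
    n_pairs: int

    def __post_init__(self) -> None:
        if not 0 <= self.probability <= 1:
            raise ValueError("probability must lie in [0, 1]")
        if self.n_pairs < 1:
            raise ValueError("n_pairs must be >= 1")


@dataclass
class PairGenParams:
    groups: list[GroupSpec]
    seed: int | None = None


def gen_pair_table(params: PairGenParams) -> PairTable:
    """Bernoulli pair outcomes at each group's stated connection probability."""
    rng = np.random.default_rng(params.seed)
    records = []
    for spec in params.groups:
        outcomes = rng.random(spec.n_pairs) < spec.probability
        for i, hit in enumerate(outcomes):
            records.append(PairRecord(
                pair_id=f"{spec.label}_{i:05d}", group=spec.label,
                connected_ab=bool(hit), connected_ba=False))
    return PairTable(records=records)


def exact_count_pair_table(counts: dict[str, tuple[int, int]]) -> PairTable:
    """Pair table with exactly the requested (connected, tested) per group.

    Encodes published tallies -- e.g. ``{"cKO": (103, 511)}`` yields a group
    whose connection probability is exactly 103/511.
    """
    records = []
    for label, (connected, tested) in counts.items():
        if not 0 <= connected <= tested:
            raise ValueError(f"{label}: need 0 <= connected <= tested")
        for i in range(tested):
            records.append(PairRecord(
                pair_id=f"{label}_{i:05d}", group=label,
                connected_ab=i < connected, connected_ba=False))
    return PairTable(records=records)
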