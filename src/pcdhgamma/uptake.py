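"""Plasmid co-electroporation uptake model.

When a mixture of plasmids carrying different fluorescent tags is
electroporated, the color composition of the transfected population
constrains how many plasmid copies n each cell took up. With a fraction
q_green of the mixture tagged green (by molar weight) and a cell drawing n
plasmids independently:

    R_GFP-only     = q_green^n
    R_RFP-only     = (1 - q_green)^n
    R_co           = 1 - q_green^n - (1 - q_green)^n
    R_RedInTotal   = R_co + R_RFP-only = 1 - q_green^n

For the six-plasmid equimolar design (five green, one red), q_green = 5/6.
A fixed n does not fit observed color fractions well; instead n is modeled
as Normal(mu, sigma^2), rounded to the nearest integer and truncated at 1,
and the fractions above are averaged over k cells drawn from that
distribution. The same per-cell draws also yield the number of distinct
plasmid species per cell ("isoform types"), which at the fitted
(mu, sigma) = (18, 6) averages about 5.6 of 6.

Note: one published form of the cell-averaged R_RFP-only reads as an
average of 1 - (1/6)^n, which contradicts the fixed-n expression
R_RFP-only = (1/6)^n; this module averages (1/6)^n (generalized through
q_green), keeping all identities among the fractions exact.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass(frozen=True)
class Plasmid:
    isoform: str
    tag: str  # "green" | "red"
    molar_weight: float = 1.0

    def __post_init__(self) -> None:
        if self.tag not in ("green", "red"):
            raise ValueError(f"tag must be 'green' or 'red', got {self.tag!r}")
        if self.molar_weight <= 0:
            raise ValueError("molar weight must be positive")


@dataclass(frozen=True)
class UptakeDesign:
    """A plasmid mixture: species, color tags, and molar weights."""

    plasmids: tuple[Plasmid, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "plasmids", tuple(self.plasmids))
        if len(self.plasmids) < 2:
            raise ValueError("a design needs at least 2 plasmids")
        tags = {p.tag for p in self.plasmids}
        if tags != {"green", "red"}:
            raise ValueError("design needs at least one green and one red plasmid")

    @property
    def n_species(self) -> int:
        return len(self.plasmids)

    @property
    def weights(self) -> np.ndarray:
        """Draw probabilities, proportional to molar weights."""
        w = np.array([p.molar_weight for p in self.plasmids], dtype=float)
        return w / w.sum()

    @property
    def q_green(self) -> float:
        """Molar fraction of green-tagged plasmid in the mixture."""
        w = self.weights
        green = np.array([p.tag == "green" for p in self.plasmids])
        return float(w[green].sum())

    @property
    def green_mask(self) -> np.ndarray:
        return np.array([p.tag == "green" for p in self.plasmids])


def six_plasmid_design() -> UptakeDesign:
    """The equimolar 5-green + 1-red overexpression mixture (q_green = 5/6)."""
    greens = ("Pcdhga2", "Pcdhga8", "Pcdhga10", "Pcdhgb1", "Pcdhgb2")
    return UptakeDesign(
        plasmids=tuple(Plasmid(g, "green") for g in greens)
        + (Plasmid("Pcdhga6", "red"),))


def two_plasmid_design() -> UptakeDesign:
    """A 1:1 two-plasmid mixture, one green and one red (q_green = 1/2)."""
    return UptakeDesign(plasmids=(Plasmid("green_reporter", "green"),
                                  Plasmid("red_reporter", "red")))


@dataclass
class ColorFractions:
    """Fractions of transfected cells by fluorescent color class."""

    r_gfp_only: float
    r_rfp_only: float
    r_co: float

    @property
    def r_red_in_total(self) -> float:
        """Fraction of cells containing red at all (red-only plus co-labeled)."""
        return self.r_co + self.r_rfp_only

    def as_dict(self) -> dict[str, float]:
        return {"r_gfp_only": self.r_gfp_only, "r_rfp_only": self.r_rfp_only,
                "r_co": self.r_co, "r_red_in_total": self.r_red_in_total}


@dataclass(frozen=True)
class UptakeParams:
    """Per-cell plasmid count distribution: n ~ Normal(mu, sigma^2), n >= 1.

    ``truncation`` selects how sub-1 draws are handled: "clip" (round, then
    clamp to 1; the default, since n is a physical plasmid count) or
    "resample" (redraw until the rounded value is >= 1).
    """

    mu: float
    sigma: float
    k: int = 10_000
    truncation: str = "clip"

    def __post_init__(self) -> None:
        if self.mu < 1:
            raise ValueError("mu must be >= 1")
        if self.sigma < 0:
            raise ValueError("sigma must be >= 0")
        if self.k < 1:
            raise ValueError("k must be >= 1")
        if self.truncation not in ("clip", "resample"):
            raise ValueError(f"unknown truncation mode: {self.truncation!r}")


@dataclass
class UptakeSimResult:
    per_cell_n: np.ndarray
    per_cell_types: np.ndarray
    fractions: ColorFractions
    mean_types: float
    seed: int | None


@dataclass
class UptakeFit:
    mu: int
    sigma: int
    objective: np.ndarray  # (len(mu_values), len(sigma_values)) squared errors
    mu_values: np.ndarray
    sigma_values: np.ndarray


def fixed_n_fractions(design: UptakeDesign, n: int) -> ColorFractions:
    """Color-class fractions when every cell receives exactly n plasmids."""
    if n < 1:
        raise ValueError("n must be >= 1")
    q = design.q_green
    g_only = q ** n
    r_only = (1.0 - q) ** n
    return ColorFractions(r_gfp_only=g_only, r_rfp_only=r_only,
                          r_co=1.0 - g_only - r_only)


def expected_mean_types(design: UptakeDesign, n: int) -> float:
    """Closed-form expected number of distinct species among n weighted draws."""
    w = design.weights
    return float(np.sum(1.0 - (1.0 - w) ** n))


def _draw_n(params: UptakeParams, z: np.ndarray,
            rng: np.random.Generator | None = None) -> np.ndarray:
    """Integer plasmid counts from standard-normal draws z.

    Rounds mu + sigma*z to the nearest integer. Sub-1 values are clamped to
    1 ("clip") or redrawn ("resample"; needs ``rng`` for the redraws --
    without one, clipping is used as the fallback so that common-random-
    number callers stay deterministic in z alone).
    """
    n = np.rint(params.mu + params.sigma * z).astype(np.int64)
    if params.truncation == "resample" and rng is not None:
        bad = n < 1
        while np.any(bad):
            n[bad] = np.rint(
                params.mu + params.sigma * rng.standard_normal(int(bad.sum()))
            ).astype(np.int64)
            bad = n < 1
        return n
    return np.maximum(n, 1)


def simulate_uptake(design: UptakeDesign, params: UptakeParams,
                    seed: int | None = None) -> UptakeSimResult:
    """Monte-Carlo simulation of k cells under the truncated-normal uptake model.

    Per cell: draw n ~ Normal(mu, sigma^2) rounded and truncated at 1, then
    make n draws with replacement over the plasmid species (probabilities
    proportional to molar weights). Every species drawn at least once is
    expressed. Reports per-cell distinct-species counts, their mean, and the
    color-class fractions.
    """
    rng = np.random.default_rng(seed)
    n = _draw_n(params, rng.standard_normal(params.k), rng=rng)
    total = int(n.sum())
    draws = rng.choice(design.n_species, size=total, p=design.weights)
    cell_idx = np.repeat(np.arange(params.k), n)
    # species-presence matrix (k x n_species) via flat bincount
    flat = cell_idx * design.n_species + draws
    present = np.bincount(flat, minlength=params.k * design.n_species)
    present = present.reshape(params.k, design.n_species) > 0

    types = present.sum(axis=1)
    has_green = present[:, design.green_mask].any(axis=1)
    has_red = present[:, ~design.green_mask].any(axis=1)
    fractions = ColorFractions(
        r_gfp_only=float(np.mean(has_green & ~has_red)),
        r_rfp_only=float(np.mean(has_red & ~has_green)),
        r_co=float(np.mean(has_green & has_red)),
    )
    return UptakeSimResult(per_cell_n=n, per_cell_types=types,
                           fractions=fractions,
                           mean_types=float(types.mean()), seed=seed)


def normal_n_fractions(design: UptakeDesign, params: UptakeParams,
                       seed: int | None = None,
                       z: np.ndarray | None = None) -> ColorFractions:
    """Cell-averaged color fractions under the truncated-normal n.

    Averages the fixed-n expressions q_green^n, (1-q_green)^n over k cells
    whose n is drawn from the truncated normal. ``z`` may supply the
    standard-normal draws directly (one per cell), enabling common random
    numbers across parameter settings; otherwise they come from ``seed``.
    With sigma = 0 this reduces exactly to :func:`fixed_n_fractions` at
    n = round(mu).
    """
    if z is None:
        z = np.random.default_rng(seed).standard_normal(params.k)
    elif len(z) != params.k:
        raise ValueError("z must supply one draw per cell (length k)")
    n = _draw_n(params, z)
    q = design.q_green
    g_only = float(np.mean(q ** n.astype(float)))
    r_only = float(np.mean((1.0 - q) ** n.astype(float)))
    return ColorFractions(r_gfp_only=g_only, r_rfp_only=r_only,
                          r_co=1.0 - g_only - r_only)


def fit_mu_sigma(
    observed: ColorFractions,
    design: UptakeDesign,
    mu_grid=range(1, 41),
    sigma_grid=range(0, 21),
    k: int = 50_000,
    seed: int | None = None,
) -> UptakeFit:
    """Integer grid search for (mu, sigma) matching observed color fractions.

    Minimizes the squared error between model-predicted and observed
    (R_RFP-only, R_RedInTotal) over the integer grid. The model prediction
    at every grid point reuses a single vector of k standard-normal draws
    derived from ``seed`` (common random numbers), which makes the
    objective surface smooth in (mu, sigma) and lets observations generated
    by :func:`normal_n_fractions` with the same seed and k be recovered
    exactly. Ties break toward smaller mu, then smaller sigma.
    """
    mu_values = np.array(list(mu_grid), dtype=int)
    sigma_values = np.array(list(sigma_grid), dtype=int)
    if mu_values.size == 0 or sigma_values.size == 0:
        raise ValueError("mu and sigma grids must be non-empty")
    z = np.random.default_rng(seed).standard_normal(k)
    objective = np.empty((mu_values.size, sigma_values.size))
    for i, mu in enumerate(mu_values):
        for j, sigma in enumerate(sigma_values):
            pred = normal_n_fractions(
                design, UptakeParams(mu=float(mu), sigma=float(sigma), k=k), z=z)
            objective[i, j] = ((pred.r_rfp_only - observed.r_rfp_only) ** 2
                               + (pred.r_red_in_total - observed.r_red_in_total) ** 2)
    # argmin with ties broken by smaller mu then smaller sigma: np.argmin on
    # the row-major flattened array already returns the first minimum.
    i, j = np.unravel_index(int(np.argmin(objective)), objective.shape)
    return UptakeFit(mu=int(mu_values[i]), sigma=int(sigma_values[j]),
                     objective=objective, mu_values=mu_values,
                     sigma_values=sigma_values)
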