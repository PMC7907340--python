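"""Synthetic consumption trials and quadrat surveys.

Two stochastic generators back the analysis pipeline when no laboratory or
field data are at hand:

* depletion-style predation trials — a single predator, a fixed initial
  prey density, no prey replacement — with the statistical structure the
  Rogers random-predator model assumes, and
* quadrat count surveys with negative-binomial overdispersion, emulating
  clumped field abundances of the predators.

Trial tables use one row per trial with the columns of :class:`FRTrial`;
quadrat tables use the columns of :class:`QuadratSample`.  All generators
are deterministic under a fixed seed.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from .rogers import rogers_expected_consumption

__all__ = [
    "EMBRYO_DENSITIES",
    "LARVA_DENSITIES",
    "SimulationConfig",
    "FRTrial",
    "QuadratSample",
    "simulate_random_predator",
    "generate_trials",
    "generate_quadrat_survey",
]

#: prey density design used for small (embryo-sized) prey, 24 h trials
EMBRYO_DENSITIES = (2, 4, 6, 8, 10, 15, 20, 40, 70)
#: prey density design used for larval prey, 48 h trials
LARVA_DENSITIES = (1, 2, 3, 5, 8, 10, 15)

TRIAL_COLUMNS = [
    "predator_group",
    "prey_type",
    "density_offered",
    "consumed",
    "dead_unconsumed",
    "duration_days",
    "replicate_id",
    "excluded",
]

QUADRAT_COLUMNS = ["site", "group", "count", "area_m2", "source"]


@dataclass(frozen=True)
class FRTrial:
    """One depletion predation trial."""

    predator_group: str
    prey_type: str
    density_offered: int
    consumed: int
    dead_unconsumed: int
    duration_days: float
    replicate_id: str
    excluded: bool = False

    def __post_init__(self):
        if self.density_offered < 0:
            raise ValueError("density_offered must be >= 0")
        if self.consumed < 0 or self.dead_unconsumed < 0:
            raise ValueError("consumed and dead_unconsumed must be >= 0")
        if self.consumed + self.dead_unconsumed > self.density_offered:
            raise ValueError("consumed + dead_unconsumed cannot exceed density_offered")
        if not self.duration_days > 0:
            raise ValueError("duration_days must be positive")


@dataclass(frozen=True)
class QuadratSample:
    """One fixed-area quadrat count (default frame 0.25 m^2)."""

    site: str
    group: str
    count: int
    area_m2: float = 0.25
    source: str = "field"

    def __post_init__(self):
        if self.count < 0:
            raise ValueError("count must be >= 0")
        if not self.area_m2 > 0:
            raise ValueError("area_m2 must be positive")
        if self.source not in ("field", "literature"):
            raise ValueError("source must be 'field' or 'literature'")


@dataclass
class SimulationConfig:
    """Design of a simulated consumption-trial experiment.

    ``attack_coefficient`` and ``handling_time`` are the generating model
    parameters (per day, and days per prey item); ``duration`` the trial
    length in days; ``densities`` the initial prey densities offered;
    ``replicates_per_density`` the number of trials at each density.
    ``background_mortality`` is an optional per-prey probability that a
    surviving prey dies of causes other than predation.  ``method``
    selects the within-trial noise law: ``"binomial"`` draws consumption
    from a binomial around the Rogers mean proportion (matching the
    likelihood used for fitting), ``"renewal"`` runs the mechanistic
    search/handling renewal process of :func:`simulate_random_predator`.
    """

    attack_coefficient: float
    handling_time: float
    duration: float = 1.0
    densities: tuple = EMBRYO_DENSITIES
    replicates_per_density: int = 5
    seed: int | None = None
    prey_label: str = "prey"
    predator_label: str = "predator"
    background_mortality: float = 0.0
    method: str = "binomial"

    def __post_init__(self):
        if not self.attack_coefficient > 0:
            raise ValueError("attack_coefficient must be > 0")
        if self.handling_time < 0:
            raise ValueError("handling_time must be >= 0")
        if not self.duration > 0:
            raise ValueError("duration must be > 0")
        self.densities = tuple(int(d) for d in self.densities)
        if len(self.densities) == 0 or any(d <= 0 for d in self.densities):
            raise ValueError("densities must be a non-empty list of positive integers")
        if self.replicates_per_density < 1:
            raise ValueError("replicates_per_density must be >= 1")
        if not 0 <= self.background_mortality < 1:
            raise ValueError("background_mortality must be in [0, 1)")
        if self.method not in ("binomial", "renewal"):
            raise ValueError("method must be 'binomial' or 'renewal'")

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        return cls(**d)

    @classmethod
    def from_file(cls, path) -> "SimulationConfig":
        """Load from a YAML or JSON document mirroring the field names."""
        with open(path) as fh:
            text = fh.read()
        doc = json.loads(text) if str(path).endswith(".json") else yaml.safe_load(text)
        return cls.from_dict(doc)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["densities"] = list(self.densities)
        return d


def simulate_random_predator(a, h, T, n_offered, rng):
    """Simulate one depletion trial as a search/handling renewal process.

    Starting with ``N = n_offered`` prey, search times are exponential
    with rate ``a * N``; each capture removes one prey and occupies the
    predator for a fixed handling time ``h``.  A capture whose handling
    straddles the horizon ``T`` is credited with probability equal to the
    fraction of its handling completed by ``T``, which keeps the process
    mean aligned with the deterministic random-predator solution despite
    integer accounting.

    Returns an integer in ``[0, n_offered]``.
    """
    if a < 0 or h < 0:
        raise ValueError("attack coefficient and handling time must be non-negative")
    if not T > 0:
        raise ValueError("trial duration T must be positive")
    if n_offered < 0:
        raise ValueError("prey density must be non-negative")
    if a == 0 or n_offered == 0:
        return 0
    n = int(n_offered)
    clock = 0.0
    eaten = 0
    while n > 0:
        seize = clock + rng.exponential(1.0 / (a * n))
        if seize > T:
            break
        if h > 0 and seize + h > T:
            # pro-rata credit for the capture whose handling is cut short
            if rng.random() < (T - seize) / h:
                eaten += 1
            break
        clock = seize + h
        n -= 1
        eaten += 1
    return eaten


def generate_trials(config: SimulationConfig, rng=None) -> pd.DataFrame:
    """Simulate a full trial table under ``config``.

    Returns a DataFrame with ``replicates_per_density * len(densities)``
    rows and the :data:`TRIAL_COLUMNS` schema, reproducible under the
    config seed.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    a, h, T = config.attack_coefficient, config.handling_time, config.duration
    rows = []
    for d in config.densities:
        if config.method == "binomial":
            p = rogers_expected_consumption(a, h, T, d) / d
            consumed = rng.binomial(d, min(max(p, 0.0), 1.0), size=config.replicates_per_density)
        else:
            consumed = [
                simulate_random_predator(a, h, T, d, rng)
                for _ in range(config.replicates_per_density)
            ]
        for i, c in enumerate(consumed, start=1):
            c = int(c)
            dead = 0
            if config.background_mortality > 0 and d - c > 0:
                dead = int(rng.binomial(d - c, config.background_mortality))
            rows.append(
                FRTrial(
                    predator_group=config.predator_label,
                    prey_type=config.prey_label,
                    density_offered=d,
                    consumed=c,
                    dead_unconsumed=dead,
                    duration_days=T,
                    replicate_id=f"{config.predator_label}-{config.prey_label}-d{d}-r{i}",
                )
            )
    return pd.DataFrame([dataclasses.asdict(t) for t in rows], columns=TRIAL_COLUMNS)


def generate_quadrat_survey(
    mean_density_per_m2,
    dispersion,
    n_sites,
    area_m2=0.25,
    seed=None,
    rng=None,
    group="predator",
    source="field",
    site_prefix="site",
) -> pd.DataFrame:
    """Simulate quadrat counts with negative-binomial overdispersion.

    Counts have mean ``mean_density_per_m2 * area_m2`` and variance
    ``mu + mu^2 / dispersion`` (smaller ``dispersion`` means clumpier);
    ``dispersion = math.inf`` gives Poisson counts.
    """
    if mean_density_per_m2 < 0:
        raise ValueError("mean_density_per_m2 must be >= 0")
    if not dispersion > 0:
        raise ValueError("dispersion must be > 0")
    if n_sites < 1:
        raise ValueError("n_sites must be >= 1")
    if not area_m2 > 0:
        raise ValueError("area_m2 must be positive")
    if rng is None:
        rng = np.random.default_rng(seed)
    mu = mean_density_per_m2 * area_m2
    if mu == 0:
        counts = np.zeros(n_sites, dtype=int)
    elif math.isinf(dispersion):
        counts = rng.poisson(mu, size=n_sites)
    else:
        k = float(dispersion)
        counts = rng.negative_binomial(k, k / (k + mu), size=n_sites)
    samples = [
        QuadratSample(
            site=f"{site_prefix}-{i + 1}",
            group=group,
            count=int(c),
            area_m2=float(area_m2),
            source=source,
        )
        for i, c in enumerate(counts)
    ]
    return pd.DataFrame([dataclasses.asdict(s) for s in samples], columns=QUADRAT_COLUMNS)
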