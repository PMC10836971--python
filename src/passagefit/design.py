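"""Experimental designs for serial-transfer competition assays.

A competition experiment mixes two genotypes (a transposon-free "Tf-null"
strain and its wild-type progenitor) at roughly equal frequency and
serially dilutes the co-culture into fresh medium on a fixed schedule.
Each passage contributes ``log2(harvest_od / seed_od)`` generations of
growth; samples frozen along the way are genotyped by amplicon sequencing
of a diagnostic SNP.

This module holds the declarative description of such an experiment
(passage schedule, covariate settings, sequencing depth, bottleneck size)
and the ground-truth fitness parameters used by the simulator.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

from .errors import InvalidInputError

__all__ = [
    "CovariateSetting",
    "TrueParameters",
    "SimulationDesign",
    "generations_per_passage",
    "exponential_schedule",
    "saturation_schedule",
    "exponential_design",
    "saturation_design",
]


@dataclass(frozen=True)
class CovariateSetting:
    """Condition covariates for one culture.

    Parameters
    ----------
    mat
        Mating type indicator: 0 for h+, 1 for h-.
    cocl2
        CoCl2 treatment indicator: 0 untreated, 1 for 250 uM CoCl2.
    glucose_pct
        Glucose concentration in g/100 mL (percent); the model codes the
        glucose effect as an offset per unit above 2%.
    is_tf_null
        Indicator for the focal strain lacking all Tf2 insertions, used by
        the cys12-comparison design in place of mat/CoCl2 terms.
    """

    mat: int = 0
    cocl2: int = 0
    glucose_pct: float = 2.0
    is_tf_null: int = 0

    def __post_init__(self):
        if self.mat not in (0, 1) or self.cocl2 not in (0, 1):
            raise InvalidInputError("mat and cocl2 must be 0 or 1")
        if self.is_tf_null not in (0, 1):
            raise InvalidInputError("is_tf_null must be 0 or 1")
        if self.glucose_pct <= 0:
            raise InvalidInputError("glucose_pct must be positive")

    def value(self, name: str) -> float:
        if name == "mat":
            return float(self.mat)
        if name == "cocl2":
            return float(self.cocl2)
        if name == "glucose":
            return self.glucose_pct - 2.0
        if name == "tf_null":
            return float(self.is_tf_null)
        raise InvalidInputError(f"unknown covariate {name!r}")


@dataclass(frozen=True)
class TrueParameters:
    """Ground-truth fitness parameters for a simulated competition.

    ``w_base`` is the relative fitness of the focal (Tf-null) genotype over
    the reference per generation; the betas are additive offsets to it.
    ``beta_glucose`` applies per g/100 mL of glucose above 2%.
    """

    w_base: float = 0.998
    beta_mat: float = 0.0
    beta_cocl2: float = 0.0
    beta_glucose: float = 0.0
    beta_tf_null: float = 0.0
    p0: float = 0.5

    def __post_init__(self):
        if not 0.0 <= self.p0 <= 1.0:
            raise InvalidInputError("p0 must lie in [0, 1]")
        if self.w_base <= 0:
            raise InvalidInputError("w_base must be positive")

    def betas(self) -> dict[str, float]:
        return {
            "mat": self.beta_mat,
            "cocl2": self.beta_cocl2,
            "glucose": self.beta_glucose,
            "tf_null": self.beta_tf_null,
        }


def generations_per_passage(seed_od: float, harvest_od: float) -> float:
    """Number of doublings in one passage, from optical densities.

    OD is treated as proportional to cell number, so a culture seeded at
    ``seed_od`` and harvested at ``harvest_od`` has undergone
    ``log2(harvest_od / seed_od)`` generations.

    >>> generations_per_passage(0.025, 0.1)
    2.0
    """
    if seed_od <= 0 or harvest_od <= 0:
        raise InvalidInputError("optical densities must be positive")
    if harvest_od < seed_od:
        raise InvalidInputError("harvest_od must be >= seed_od")
    return math.log2(harvest_od / seed_od)


def exponential_schedule(days: int = 14) -> list[tuple[float, float]]:
    """Twice-daily passage schedule that keeps cultures exponential.

    Overnight growth from OD 0.025 up to OD 3.0 followed by a daytime
    passage seeded at OD 0.1; the pair contributes ~9.74 generations per
    day, ~136.4 over 14 days, matching the bookkeeping of the exponential
    competition assays.
    """
    passages = []
    for _ in range(days):
        passages.append((0.025, 3.0))     # overnight: ~6.907 doublings
        passages.append((0.1, 0.714))     # daytime: ~2.836 doublings
    return passages


def saturation_schedule(days: int = 14) -> list[tuple[float, float]]:
    """48-hour passages that let cultures saturate at OD 10 (~60 generations)."""
    return [(0.025, 10.0)] * (days // 2)


@dataclass(frozen=True)
class SimulationDesign:
    """Full specification of a synthetic competition experiment.

    Parameters
    ----------
    n_replicates
        Independent cultures per condition.
    conditions
        One :class:`CovariateSetting` per experimental condition.
    passages
        Ordered ``(seed_od, harvest_od)`` pairs; passage ``i`` (1-based)
        moves the culture from timepoint ``i - 1`` to timepoint ``i``.
    sampling_timepoints
        Indices into the passage list at which samples are frozen and
        sequenced. Index 0 is the initial mix (generation 0) and must be
        included.
    read_depth
        Amplicon reads per sample per timepoint.
    bottleneck_cells
        Effective number of cells transferred at each dilution;
        ``math.inf`` makes the transfer deterministic (no drift).
    seed
        Base RNG seed for all stochastic steps.
    """

    n_replicates: int = 3
    conditions: tuple[CovariateSetting, ...] = (CovariateSetting(),)
    passages: tuple[tuple[float, float], ...] = field(
        default_factory=lambda: tuple(exponential_schedule())
    )
    sampling_timepoints: tuple[int, ...] = (0, 4, 8, 12, 16, 20, 24, 28)
    read_depth: int = 100_000
    bottleneck_cells: float = 5e6
    seed: int = 0

    def __post_init__(self):
        if self.n_replicates < 1:
            raise InvalidInputError("n_replicates must be >= 1")
        if self.read_depth <= 0:
            raise InvalidInputError("read_depth must be positive")
        for seed_od, harvest_od in self.passages:
            if seed_od <= 0 or harvest_od < seed_od:
                raise InvalidInputError(
                    "each passage needs harvest_od >= seed_od > 0"
                )
        tps = self.sampling_timepoints
        if not tps or tps[0] != 0:
            raise InvalidInputError("sampling_timepoints must start at 0")
        if any(b <= a for a, b in zip(tps, tps[1:])):
            raise InvalidInputError("sampling_timepoints must be strictly increasing")
        if tps[-1] > len(self.passages):
            raise InvalidInputError("sampling timepoint beyond the passage list")
        if self.bottleneck_cells <= 0:
            raise InvalidInputError("bottleneck_cells must be positive (inf allowed)")

    @property
    def passage_generations(self) -> list[float]:
        """Generations contributed by each passage, in order."""
        return [generations_per_passage(s, h) for s, h in self.passages]

    @property
    def cumulative_generations(self) -> list[float]:
        """Cumulative generations at each sampling timepoint (first is 0)."""
        per_passage = self.passage_generations
        cum = [0.0]
        total = 0.0
        for g in per_passage:
            total += g
            cum.append(total)
        return [cum[i] for i in self.sampling_timepoints]

    def with_seed(self, seed: int) -> "SimulationDesign":
        return replace(self, seed=seed)


def exponential_design(**kwargs) -> SimulationDesign:
    """Full-scale exponential-phase design: 3 replicates x (h+/h-) x (0/250 uM CoCl2)."""
    defaults = dict(
        n_replicates=3,
        conditions=(
            CovariateSetting(mat=0, cocl2=0),
            CovariateSetting(mat=1, cocl2=0),
            CovariateSetting(mat=0, cocl2=1),
            CovariateSetting(mat=1, cocl2=1),
        ),
        passages=tuple(exponential_schedule()),
        sampling_timepoints=(0, 4, 8, 12, 16, 20, 24, 28),
    )
    defaults.update(kwargs)
    return SimulationDesign(**defaults)


def saturation_design(**kwargs) -> SimulationDesign:
    """Saturation design: 48-h passages, 8 timepoints, ~60 generations."""
    defaults = dict(
        n_replicates=3,
        conditions=(CovariateSetting(),),
        passages=tuple(saturation_schedule()),
        sampling_timepoints=(0, 1, 2, 3, 4, 5, 6, 7),
    )
    defaults.update(kwargs)
    return SimulationDesign(**defaults)
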