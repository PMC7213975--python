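"""Synthetic cohorts: grouped animals with planted group-level effects.

A :class:`CohortSpec` names the genotype-like groups, their sizes, and a
:class:`GroupEffect` of planted effect parameters per group. Generators
return (data, ground-truth table) pairs; the truth sidecar exists for
tests and is never read by the analysis pipeline.

Default effect sizes for the mutant-like preset mirror the phenotypes the
pipeline is built to detect: a 0.7x gamma LFP amplitude (0.49x power),
loss of locomotion-onset modulation, a three-fold firing-rate increase,
reversed social preference, reduced marble burying, and elevated
mortality/seizure hazards.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from ..stats import (
    TRACKING_END_D,
    WEANING_AGE_D,
    AnimalRecord,
    SeizureEvent,
)
from . import behavior as simbehav
from . import ephys as simephys

__all__ = [
    "GroupEffect",
    "CohortSpec",
    "BehaviorSession",
    "default_cohort_spec",
    "gen_outcome_cohort",
    "gen_behavior_cohort",
    "gen_ephys_cohort",
]

#: Baseline planted modulation index for healthy units
#: (rate_L / rate_Q = 2 -> index = 1/3).
BASE_RATE_Q_HZ = 5.0
BASE_MODULATION_INDEX = 1.0 / 3.0


@dataclass(frozen=True)
class GroupEffect:
    """Planted effect parameters for one group (all multipliers >= 0)."""

    gamma_gain: float = 1.0  # multiplies gamma LFP amplitude
    rate_gain: float = 1.0  # multiplies quiescent firing rate
    modulation_gain: float = 1.0  # multiplies the planted modulation index
    sociability_index: float = 0.4  # planted chamber-time preference
    marble_buried_frac: float = 0.6  # expected fraction of marbles buried
    epm_open_frac: float = 0.2  # planted open-arm occupancy
    mortality_hazard_per_d: float = 1e-4
    seizure_hazard_per_d: float = 4e-4

    def __post_init__(self) -> None:
        for name in ("gamma_gain", "rate_gain", "modulation_gain",
                     "mortality_hazard_per_d", "seizure_hazard_per_d"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if not 0 <= self.marble_buried_frac <= 1:
            raise ValueError("marble_buried_frac must lie in [0, 1]")


@dataclass(frozen=True)
class CohortSpec:
    groups: tuple[tuple[str, int], ...]
    effects: dict[str, GroupEffect]
    control_label: str
    seed: int = 0

    def __post_init__(self) -> None:
        for label, n in self.groups:
            if n < 1:
                raise ValueError(f"group {label!r} needs n >= 1")
            if label not in self.effects:
                raise ValueError(f"no effect parameters for group {label!r}")
        if self.control_label not in dict(self.groups):
            raise ValueError("control group missing from groups")

    def animals(self) -> list[tuple[str, str]]:
        """(animal_id, group) pairs in a stable order."""
        out = []
        for label, n in self.groups:
            out.extend((f"{label}_{i:02d}", label) for i in range(n))
        return out


def default_cohort_spec(
    seed: int = 0,
    n_per_group: int = 8,
    mutant_label: str = "VIP_mut",
) -> CohortSpec:
    """Three-group cohort: control, a null mutant, and a VIP-like mutant.

    The VIP-like group carries the full planted phenotype; the null
    mutant group is drawn from the control distribution, giving the
    pipeline a specificity check.
    """
    control = GroupEffect()
    mutant = GroupEffect(
        gamma_gain=0.7,
        rate_gain=3.0,
        modulation_gain=0.0,
        sociability_index=-0.4,
        marble_buried_frac=0.15,
        mortality_hazard_per_d=1e-4,
        seizure_hazard_per_d=1e-3,
    )
    return CohortSpec(
        groups=(("CON", n_per_group), ("PV_mut", n_per_group), (mutant_label, n_per_group)),
        effects={"CON": control, "PV_mut": control, mutant_label: mutant},
        control_label="CON",
        seed=seed,
    )


def gen_outcome_cohort(spec: CohortSpec) -> tuple[list[AnimalRecord], pd.DataFrame]:
    """Mortality and seizure outcomes under per-group exponential hazards.

    Death and first-qualifying-seizure ages are exponential from weaning
    (P21); animals alive at P500 are censored there. Qualifying events
    get Racine level 4 or 5; a few sub-threshold (level 1-3) events are
    sprinkled in as scoring noise.
    """
    rng = np.random.default_rng(spec.seed)
    records, truth = [], []
    for animal_id, group in spec.animals():
        eff = spec.effects[group]
        span = TRACKING_END_D - WEANING_AGE_D
        death = (
            WEANING_AGE_D + rng.exponential(1.0 / eff.mortality_hazard_per_d)
            if eff.mortality_hazard_per_d > 0
            else np.inf
        )
        censored = death > TRACKING_END_D
        death_age = TRACKING_END_D if censored else float(death)
        events: list[SeizureEvent] = []
        if eff.seizure_hazard_per_d > 0:
            first = WEANING_AGE_D + rng.exponential(1.0 / eff.seizure_hazard_per_d)
            if first <= death_age:
                events.append(
                    SeizureEvent(age_d=float(first), racine_level=int(rng.integers(4, 6)))
                )
        n_minor = rng.poisson(0.5)
        for _ in range(n_minor):
            events.append(
                SeizureEvent(
                    age_d=float(WEANING_AGE_D + rng.uniform(0, death_age - WEANING_AGE_D)),
                    racine_level=int(rng.integers(1, 4)),
                )
            )
        records.append(
            AnimalRecord(
                animal_id=animal_id,
                group=group,
                death_age_d=death_age,
                censored=censored,
                seizure_events=tuple(sorted(events, key=lambda e: e.age_d)),
            )
        )
        truth.append(
            {
                "animal_id": animal_id,
                "group": group,
                "mortality_hazard_per_d": eff.mortality_hazard_per_d,
                "seizure_hazard_per_d": eff.seizure_hazard_per_d,
            }
        )
    return records, pd.DataFrame(truth)


@dataclass(frozen=True)
class BehaviorSession:
    """All behavioral raw data for one animal."""

    animal_id: str
    group: str
    epm: tuple  # (Trajectory, ArenaGeometry)
    open_field: tuple
    sociability: tuple
    marble_masks: tuple[np.ndarray, np.ndarray]


def gen_behavior_cohort(
    spec: CohortSpec,
    index_jitter_sd: float = 0.1,
) -> tuple[list[BehaviorSession], pd.DataFrame]:
    """Behavioral sessions for every animal, with per-animal jitter.

    The planted sociability index and marble-burial fraction vary around
    the group mean from animal to animal (truncated to their valid
    ranges), mimicking biological scatter.
    """
    rng = np.random.default_rng(spec.seed + 1)
    sessions, truth = [], []
    for animal_id, group in spec.animals():
        eff = spec.effects[group]
        soc_idx = float(
            np.clip(eff.sociability_index + rng.normal(0, index_jitter_sd), -1, 1)
        )
        n_marbles = 12
        buried = rng.uniform(size=n_marbles) < eff.marble_buried_frac
        coverage = np.where(buried, rng.uniform(0.75, 1.0, n_marbles), rng.uniform(0.0, 0.4, n_marbles))
        seeds = rng.integers(0, 2**31 - 1, size=4)
        epm = simbehav.gen_epm_trajectory(eff.epm_open_frac, seed=int(seeds[0]))
        of = simbehav.gen_open_field_trajectory(seed=int(seeds[1]))
        soc = simbehav.gen_three_chamber_trajectory(soc_idx, seed=int(seeds[2]))
        masks = simbehav.gen_marble_masks(coverage, seed=int(seeds[3]))
        sessions.append(
            BehaviorSession(
                animal_id=animal_id,
                group=group,
                epm=epm,
                open_field=of,
                sociability=soc,
                marble_masks=masks,
            )
        )
        truth.append(
            {
                "animal_id": animal_id,
                "group": group,
                "sociability_index": soc_idx,
                "percent_buried": 100.0 * buried.mean(),
                "epm_open_frac": eff.epm_open_frac,
            }
        )
    return sessions, pd.DataFrame(truth)


def gen_ephys_cohort(
    spec: CohortSpec,
    duration_s: float = 300.0,
    n_bouts: int = 8,
    n_units: int = 4,
    **session_kwargs,
) -> tuple[list[simephys.GroundTruthSession], pd.DataFrame]:
    """One recording session per animal with planted group effects.

    The quiescent rate is ``BASE_RATE_Q_HZ * rate_gain`` and the
    locomotion rate follows from the planted modulation index
    m = BASE_MODULATION_INDEX * modulation_gain via
    rate_L = rate_Q * (1 + m)/(1 - m).
    """
    rng = np.random.default_rng(spec.seed + 2)
    sessions, truth = [], []
    for animal_id, group in spec.animals():
        eff = spec.effects[group]
        m = BASE_MODULATION_INDEX * eff.modulation_gain
        rate_q = BASE_RATE_Q_HZ * eff.rate_gain
        rate_l = rate_q * (1.0 + m) / (1.0 - m)
        sess = simephys.gen_session(
            duration_s=duration_s,
            n_bouts=n_bouts,
            n_units=n_units,
            rate_q_hz=rate_q,
            rate_l_hz=rate_l,
            gamma_gain=eff.gamma_gain,
            seed=int(rng.integers(0, 2**31 - 1)),
            **session_kwargs,
        )
        sessions.append(sess)
        truth.append(
            {
                "animal_id": animal_id,
                "group": group,
                "gamma_gain": eff.gamma_gain,
                "rate_q_hz": rate_q,
                "rate_l_hz": rate_l,
                "modulation_index": m,
            }
        )
    return sessions, pd.DataFrame(truth)
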