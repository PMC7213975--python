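"""Cohort outcome summaries and nonparametric group comparisons.

The statistical unit is the animal: per-unit metrics are averaged within
animal before any group test. Group comparisons use the Kruskal-Wallis
rank test (tie-corrected) followed by Dunn's post-test of each mutant
group against the control, Bonferroni-adjusted over that family — the
convention GraphPad Prism applies under "Dunn's multiple comparisons".

Survival is tabulated as the empirical fraction of each group alive at
each day from weaning (P21) to the end of tracking (P500); animals alive
at P500 are censored there and excluded from mean death age. A seizure is
an event reaching Racine level 4 or 5.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import chi2, norm, rankdata

__all__ = [
    "SeizureEvent",
    "AnimalRecord",
    "SurvivalCurve",
    "DunnResult",
    "GroupComparison",
    "survival_curve",
    "mean_death_age",
    "seizure_summary",
    "kruskal_wallis",
    "dunn_posthoc",
    "compare_groups",
]

WEANING_AGE_D = 21.0
TRACKING_END_D = 500.0
SEIZURE_RACINE_MIN = 4


@dataclass(frozen=True)
class SeizureEvent:
    age_d: float
    racine_level: int

    def __post_init__(self) -> None:
        if not 1 <= int(self.racine_level) <= 5:
            raise ValueError("Racine level must be an integer in [1, 5]")

    @property
    def qualifying(self) -> bool:
        return self.racine_level >= SEIZURE_RACINE_MIN


@dataclass(frozen=True)
class AnimalRecord:
    animal_id: str
    group: str
    death_age_d: float  # == TRACKING_END_D when censored
    censored: bool = False
    seizure_events: tuple[SeizureEvent, ...] = ()

    def __post_init__(self) -> None:
        if not WEANING_AGE_D <= self.death_age_d <= TRACKING_END_D:
            raise ValueError(
                f"death/censoring age must lie in [{WEANING_AGE_D}, {TRACKING_END_D}]"
            )

    def first_qualifying_seizure(self) -> float | None:
        ages = [ev.age_d for ev in self.seizure_events if ev.qualifying]
        return min(ages) if ages else None


@dataclass(frozen=True)
class SurvivalCurve:
    age_d: np.ndarray
    fraction_surviving: np.ndarray

    def __post_init__(self) -> None:
        f = np.asarray(self.fraction_surviving, dtype=float)
        if f[0] > 1 + 1e-12 or np.any(np.diff(f) > 1e-12):
            raise ValueError("survival fraction must start <= 1 and be non-increasing")


def survival_curve(
    records: list[AnimalRecord], age_grid_d: np.ndarray | None = None
) -> SurvivalCurve:
    """Empirical fraction of animals alive at each day of the grid.

    Censored animals count as alive through P500.
    """
    if not records:
        raise ValueError("need at least one record")
    grid = (
        np.arange(0.0, TRACKING_END_D + 1.0) if age_grid_d is None else np.asarray(age_grid_d)
    )
    deaths = np.array(
        [np.inf if r.censored else r.death_age_d for r in records], dtype=float
    )
    frac = (deaths[None, :] > grid[:, None]).mean(axis=1)
    return SurvivalCurve(age_d=grid, fraction_surviving=frac)


def mean_death_age(records: list[AnimalRecord]) -> tuple[float, float, int]:
    """(mean, SEM, n) of death age over uncensored animals; NaNs if none died."""
    ages = np.array([r.death_age_d for r in records if not r.censored])
    if ages.size == 0:
        return float("nan"), float("nan"), 0
    sem = ages.std(ddof=1) / np.sqrt(ages.size) if ages.size > 1 else float("nan")
    return float(ages.mean()), float(sem), int(ages.size)


def seizure_summary(records: list[AnimalRecord]) -> tuple[float, float]:
    """(incidence, mean onset age) of qualifying (Racine >= 4) seizures.

    Incidence is the fraction of animals with at least one qualifying
    event; onset age averages each such animal's first qualifying event
    (NaN when no animal qualifies).
    """
    if not records:
        raise ValueError("need at least one record")
    onsets = [r.first_qualifying_seizure() for r in records]
    onsets = [a for a in onsets if a is not None]
    incidence = len(onsets) / len(records)
    mean_onset = float(np.mean(onsets)) if onsets else float("nan")
    return incidence, mean_onset


def _pooled_ranks(groups: dict[str, np.ndarray]) -> tuple[dict[str, np.ndarray], float, int]:
    """Rank all values jointly; return per-group ranks, tie sum T=sum(t^3-t), N."""
    labels = list(groups)
    arrays = [np.asarray(groups[g], dtype=float) for g in labels]
    if any(a.size < 1 for a in arrays):
        raise ValueError("every group needs at least one value")
    pooled = np.concatenate(arrays)
    ranks = rankdata(pooled)
    _, counts = np.unique(pooled, return_counts=True)
    tie_sum = float(np.sum(counts.astype(float) ** 3 - counts))
    out, k = {}, 0
    for g, a in zip(labels, arrays):
        out[g] = ranks[k : k + a.size]
        k += a.size
    return out, tie_sum, pooled.size


def kruskal_wallis(groups: dict[str, np.ndarray]) -> tuple[float, float]:
    """Tie-corrected Kruskal-Wallis H and its chi-square p-value.

    All-identical data yield (H=0, p=1) by convention.
    """
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    granks, tie_sum, n = _pooled_ranks(groups)
    correction = 1.0 - tie_sum / (n**3 - n) if n > 1 else 0.0
    if correction <= 0:  # every value identical
        return 0.0, 1.0
    h = 12.0 / (n * (n + 1)) * sum(r.sum() ** 2 / r.size for r in granks.values()) - 3.0 * (
        n + 1
    )
    h /= correction
    h = max(h, 0.0)
    p = float(chi2.sf(h, df=len(groups) - 1))
    return float(h), p


@dataclass(frozen=True)
class DunnResult:
    z: float
    p: float
    p_adjusted: float


def dunn_posthoc(
    groups: dict[str, np.ndarray],
    control_label: str,
    adjust: str = "bonferroni",
) -> dict[str, DunnResult]:
    """Dunn's post-test of each group against the control.

    z is the difference in pooled-rank means over its tie-corrected
    standard error (positive when the group's ranks exceed the control's);
    two-sided normal p-values are Bonferroni-adjusted over the family of
    control comparisons (``adjust="none"`` disables adjustment).
    """
    if control_label not in groups:
        raise ValueError(f"control group {control_label!r} absent")
    if adjust not in ("bonferroni", "none"):
        raise ValueError(f"unknown adjustment {adjust!r}")
    granks, tie_sum, n = _pooled_ranks(groups)
    sigma2 = n * (n + 1) / 12.0 - (tie_sum / (12.0 * (n - 1)) if n > 1 else 0.0)
    m = len(groups) - 1
    rc = granks[control_label]
    out: dict[str, DunnResult] = {}
    for g, rg in granks.items():
        if g == control_label:
            continue
        se = np.sqrt(sigma2 * (1.0 / rg.size + 1.0 / rc.size))
        z = float((rg.mean() - rc.mean()) / se) if se > 0 else 0.0
        p = float(2.0 * norm.sf(abs(z)))
        p_adj = min(1.0, p * m) if adjust == "bonferroni" else p
        out[g] = DunnResult(z=z, p=p, p_adjusted=p_adj)
    return out


@dataclass(frozen=True)
class GroupComparison:
    h: float
    p_global: float
    posthoc: dict[str, DunnResult]


def compare_groups(
    groups: dict[str, np.ndarray], control_label: str, adjust: str = "bonferroni"
) -> GroupComparison:
    """Kruskal-Wallis omnibus test plus Dunn's post-test vs control."""
    h, p = kruskal_wallis(groups)
    return GroupComparison(
        h=h, p_global=p, posthoc=dunn_posthoc(groups, control_label, adjust=adjust)
    )
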