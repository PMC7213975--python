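"""Rank statistics against independent oracles; survival and seizure rules."""

import numpy as np
import pytest
from scipy.stats import rankdata

from statephys.stats import (
    AnimalRecord,
    SeizureEvent,
    compare_groups,
    dunn_posthoc,
    kruskal_wallis,
    mean_death_age,
    seizure_summary,
    survival_curve,
)


def _kw_rank_oracle(groups):
    """Exhaustive rank computation of tie-corrected H, written from the
    rank-sum definition (independent of the implementation)."""
    pooled = np.concatenate(list(groups.values()))
    ranks = rankdata(pooled)
    n = pooled.size
    h, k = 0.0, 0
    for g in groups.values():
        r = ranks[k : k + len(g)]
        h += r.sum() ** 2 / len(g)
        k += len(g)
    h = 12.0 / (n * (n + 1)) * h - 3 * (n + 1)
    _, counts = np.unique(pooled, return_counts=True)
    denom = 1.0 - np.sum(counts**3 - counts) / (n**3 - n)
    return h / denom


class TestKruskalWallis:
    def test_hand_derived_case(self):
        # rank sums 6, 15, 24 -> H = 12/90 * 279 - 30 = 7.2
        h, p = kruskal_wallis({"a": [1, 2, 3], "b": [4, 5, 6], "c": [7, 8, 9]})
        assert h == pytest.approx(7.2, abs=1e-12)

    def test_identical_groups_zero(self):
        h, p = kruskal_wallis({"a": [1.0, 2.0, 3.0], "b": [1.0, 2.0, 3.0]})
        assert h == pytest.approx(0.0, abs=1e-12)

    def test_all_values_identical_convention(self):
        h, p = kruskal_wallis({"a": [2.0, 2.0], "b": [2.0, 2.0]})
        assert (h, p) == (0.0, 1.0)

    def test_fuzz_against_rank_oracle_and_scipy(self):
        from scipy.stats import kruskal

        rng = np.random.default_rng(42)
        for _ in range(1000):
            k = rng.integers(2, 5)
            groups = {
                str(i): rng.integers(0, 8, size=rng.integers(2, 9)).astype(float)
                for i in range(k)
            }
            if np.unique(np.concatenate(list(groups.values()))).size < 2:
                continue
            h, p = kruskal_wallis(groups)
            assert h == pytest.approx(_kw_rank_oracle(groups), abs=1e-12)
            h_sp, p_sp = kruskal(*groups.values())
            assert h == pytest.approx(h_sp, abs=1e-10)
            assert p == pytest.approx(p_sp, abs=1e-10)


def _dunn_permutation_oracle(groups, control, target):
    """z from the exact permutation distribution of rank-mean differences:
    pooled ranks are reallocated to groups in every distinct way and the
    empirical SD of (mean_rank_target - mean_rank_control) is the SE."""
    from sympy.utilities.iterables import multiset_permutations

    labels = []
    for g, v in groups.items():
        labels += [g] * len(v)
    pooled = np.concatenate(list(groups.values()))
    ranks = rankdata(pooled)
    obs = (
        ranks[np.array(labels) == target].mean()
        - ranks[np.array(labels) == control].mean()
    )
    diffs = []
    for perm in multiset_permutations(labels):
        perm = np.array(perm)
        diffs.append(ranks[perm == target].mean() - ranks[perm == control].mean())
    return obs / np.std(diffs)


class TestDunn:
    def test_identical_to_control(self):
        groups = {"ctrl": np.arange(6.0), "same": np.arange(6.0), "far": np.arange(6.0) + 10}
        res = dunn_posthoc(groups, "ctrl")
        assert res["same"].z == pytest.approx(0.0, abs=1e-12)
        assert res["same"].p_adjusted == 1.0

    def test_label_swap_negates_z(self):
        rng = np.random.default_rng(1)
        a, b = rng.normal(0, 1, 7), rng.normal(1, 1, 7)
        z_ab = dunn_posthoc({"c": a, "g": b}, "c")["g"].z
        z_ba = dunn_posthoc({"c": b, "g": a}, "c")["g"].z
        assert z_ab == pytest.approx(-z_ba)

    def test_matches_exhaustive_permutation_oracle(self):
        rng = np.random.default_rng(3)
        for trial in range(3):
            groups = {
                "ctrl": rng.integers(0, 6, 3).astype(float),
                "g1": rng.integers(0, 6, 3).astype(float),
                "g2": rng.integers(0, 6, 3).astype(float),
            }
            res = dunn_posthoc(groups, "ctrl", adjust="none")
            for target in ("g1", "g2"):
                z_oracle = _dunn_permutation_oracle(groups, "ctrl", target)
                assert res[target].z == pytest.approx(z_oracle, abs=1e-9)

    def test_missing_control_rejected(self):
        with pytest.raises(ValueError):
            dunn_posthoc({"a": np.ones(3), "b": np.ones(3)}, "ctrl")

    def test_bonferroni_adjustment(self):
        rng = np.random.default_rng(4)
        groups = {
            "ctrl": rng.normal(0, 1, 8),
            "g1": rng.normal(2, 1, 8),
            "g2": rng.normal(0, 1, 8),
        }
        raw = dunn_posthoc(groups, "ctrl", adjust="none")
        adj = dunn_posthoc(groups, "ctrl", adjust="bonferroni")
        for g in ("g1", "g2"):
            assert adj[g].p_adjusted == pytest.approx(min(1.0, raw[g].p * 2))


def _record(group, death, censored=False, seizures=()):
    return AnimalRecord(
        animal_id=f"{group}_{death}",
        group=group,
        death_age_d=death,
        censored=censored,
        seizure_events=tuple(SeizureEvent(a, l) for a, l in seizures),
    )


class TestSurvival:
    def test_all_censored_flat_curve(self):
        records = [_record("a", 500.0, censored=True) for _ in range(5)]
        curve = survival_curve(records)
        assert np.all(curve.fraction_surviving == 1.0)
        mean, sem, n = mean_death_age(records)
        assert np.isnan(mean) and n == 0

    def test_two_deaths_step_curve(self):
        records = [_record("a", 100.0), _record("a", 200.0)]
        curve = survival_curve(records)
        frac = dict(zip(curve.age_d, curve.fraction_surviving))
        assert frac[99.0] == 1.0
        assert frac[150.0] == 0.5
        assert frac[250.0] == 0.0

    def test_monotone_nonincreasing_property(self):
        rng = np.random.default_rng(9)
        records = [
            _record("a", float(d), censored=bool(c))
            for d, c in zip(rng.uniform(21, 500, 40), rng.integers(0, 2, 40))
        ]
        for r in records:
            if r.censored:
                object.__setattr__(r, "death_age_d", 500.0)
        curve = survival_curve(records)
        assert np.all(np.diff(curve.fraction_surviving) <= 1e-12)

    def test_exponential_hazard_mean_recovery(self):
        from statephys.simulate import CohortSpec, GroupEffect, gen_outcome_cohort

        hazard = 1.0 / 80.0  # mean death at 21 + 80 d, far below censoring
        spec = CohortSpec(
            groups=(("A", 150),),
            effects={"A": GroupEffect(mortality_hazard_per_d=hazard)},
            control_label="A",
            seed=13,
        )
        records, _ = gen_outcome_cohort(spec)
        mean, sem, n = mean_death_age([r for r in records if not r.censored])
        assert mean == pytest.approx(101.0, abs=3 * 80.0 / np.sqrt(n) + 1.0)


class TestSeizures:
    def test_subthreshold_events_do_not_qualify(self):
        records = [_record("a", 300.0, seizures=[(100.0, 3), (200.0, 2)])]
        incidence, onset = seizure_summary(records)
        assert incidence == 0.0 and np.isnan(onset)

    def test_count_ratio(self):
        records = [_record("a", 400.0, seizures=[(100.0, 4)]) for _ in range(3)]
        records += [_record("a", 400.0) for _ in range(5)]
        incidence, onset = seizure_summary(records)
        assert incidence == pytest.approx(3 / 8)
        assert onset == pytest.approx(100.0)

    def test_first_qualifying_event_used(self):
        rec = _record("a", 400.0, seizures=[(90.0, 3), (150.0, 5), (120.0, 4)])
        assert rec.first_qualifying_seizure() == 120.0

    def test_planted_hazard_incidence(self):
        from statephys.simulate import CohortSpec, GroupEffect, gen_outcome_cohort

        spec = CohortSpec(
            groups=(("A", 200),),
            effects={"A": GroupEffect(
                seizure_hazard_per_d=1.0 / 100.0, mortality_hazard_per_d=0.0
            )},
            control_label="A",
            seed=7,
        )
        records, _ = gen_outcome_cohort(spec)
        incidence, _ = seizure_summary(records)
        p = 1.0 - np.exp(-479.0 / 100.0)  # P(first seizure before censoring)
        assert incidence == pytest.approx(p, abs=3 * np.sqrt(p * (1 - p) / 200))


class TestCompareGroups:
    def test_bundles_omnibus_and_posthoc(self):
        rng = np.random.default_rng(2)
        groups = {
            "CON": rng.normal(0, 1, 10),
            "MUT": rng.normal(3, 1, 10),
        }
        comp = compare_groups(groups, "CON")
        assert comp.p_global < 0.01
        assert comp.posthoc["MUT"].p_adjusted < 0.01
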