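"""Coverage estimator and Hill-number rarefaction/extrapolation tests."""

from pathlib import Path

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from biodivmap.coverage import (
    classify_saturated,
    coverage_at_effort,
    diversity_at_coverage,
    effort_for_coverage,
    hill_at_effort,
    sample_coverage,
    _asymptotic_richness,
)
from biodivmap.errors import InsufficientDataError, UnattainableCoverageError
from biodivmap.ingest import IncidenceData

DATA = Path(__file__).parent / "data"


def inc(T, Y):
    return IncidenceData(cell_id=0, T=T, Y=np.asarray(Y))


class TestSampleCoverage:
    def test_hand_evaluated_formula(self):
        # U=7, Q1=2, Q2=1, A=0.75 -> C(T) = 1 - (2/7)*0.75
        c = sample_coverage(inc(4, [3, 2, 1, 1]), 0)
        assert c == pytest.approx(1 - (2 / 7) * 0.75, abs=1e-10)

    def test_doubled_effort_formula(self):
        c = sample_coverage(inc(4, [3, 2, 1, 1]), 4)
        assert c == pytest.approx(1 - (2 / 7) * 0.75**5, abs=1e-10)

    def test_no_singletons_gives_full_coverage(self):
        cell = inc(3, [2, 2, 3])
        for t_extra in (0, 1, 10):
            assert sample_coverage(cell, t_extra) == 1.0

    def test_monotone_in_extra_effort(self):
        cell = inc(6, [4, 3, 2, 1, 1, 1, 2, 5])
        values = [sample_coverage(cell, t) for t in range(0, 20)]
        assert all(b >= a for a, b in zip(values, values[1:]))

    def test_insufficient_units_rejected(self):
        with pytest.raises(InsufficientDataError):
            sample_coverage(inc(1, [1]), 0)

    @given(st.integers(0, 2**31 - 1))
    def test_coverage_bounded_and_monotone(self, seed):
        from conftest import random_incidence

        cell = random_incidence(np.random.default_rng(seed))
        grid = np.linspace(0.5, 3 * cell.T, 25)
        vals = [coverage_at_effort(cell, t) for t in grid]
        assert all(0.0 <= v <= 1.0 + 1e-12 for v in vals)
        assert all(b >= a - 1e-9 for a, b in zip(vals, vals[1:]))


class TestSaturation:
    def test_no_singletons_always_saturated(self):
        prof = classify_saturated(inc(3, [2, 2, 3]), C_threshold=1.0)
        assert prof.saturated and prof.C_T == 1.0 and prof.C_2T == 1.0

    def test_boundary_is_inclusive(self):
        cell = inc(4, [3, 2, 1, 1])
        c2t = sample_coverage(cell, 4)
        assert classify_saturated(cell, C_threshold=c2t).saturated
        assert not classify_saturated(cell, C_threshold=c2t + 1e-9).saturated

    def test_saturation_monotone_in_effort(self, demo_landscape):
        """Scaling observer effort up flips unsaturated cells to saturated."""
        import dataclasses

        from biodivmap import ingest
        from biodivmap.synthetic import generate_occurrences

        cfg, truth, _ = demo_landscape
        flips_possible = 0
        for seed in range(5):
            c_low = dataclasses.replace(cfg, seed=seed, corruption_frac=0.0)
            sat_frac = {}
            for rate in (4.0, 40.0):
                occ = generate_occurrences(truth, c_low, observer_rate=rate)
                asg, _ = ingest.assign_grid(occ, truth.grid)
                cells = ingest.build_incidence_by_cell(asg)
                flags = []
                for cell in cells:
                    if cell.T < 2:
                        continue
                    flags.append(classify_saturated(cell).saturated)
                sat_frac[rate] = np.mean(flags)
            assert sat_frac[40.0] >= sat_frac[4.0]
            flips_possible += sat_frac[40.0] > sat_frac[4.0]
        assert flips_possible >= 4


class TestEffortForCoverage:
    def test_fixed_point_at_observed_coverage(self):
        cell = inc(4, [3, 2, 1, 1])
        c_t = sample_coverage(cell, 0)
        assert effort_for_coverage(cell, c_t) == pytest.approx(cell.T, abs=1e-9)

    def test_small_target_needs_small_effort(self):
        cell = inc(6, [4, 3, 2, 1, 1, 1])
        m = effort_for_coverage(cell, 1e-6)
        assert 0 < m < 0.01

    def test_unattainable_full_coverage(self):
        with pytest.raises(UnattainableCoverageError):
            effort_for_coverage(inc(4, [3, 2, 1, 1]), 1.0)

    def test_integer_lattice_consistency(self):
        """ceil(m*) is the first integer effort whose coverage reaches target."""
        rng = np.random.default_rng(7)
        from conftest import random_incidence

        checked = 0
        for _ in range(60):
            cell = random_incidence(rng)
            target = 0.8
            m = effort_for_coverage(cell, target)
            if m > cell.T or m < 1:  # stay on the interpolation lattice
                continue
            lattice = np.array([coverage_at_effort(cell, j) for j in range(1, cell.T + 1)])
            first = 1 + int(np.argmax(lattice >= target))
            assert int(np.ceil(m - 1e-9)) == first
            checked += 1
        assert checked >= 10


class TestHillNumbers:
    def test_rarefied_richness_by_enumeration(self):
        # two units {A,B} and {A}: a single random unit has 1.5 species on average
        assert hill_at_effort(inc(2, [2, 1]), 0, 1) == pytest.approx(1.5, abs=1e-12)

    def test_monoculture_is_one_for_all_orders(self):
        for T, y in ((5, [5]), (4, [2]), (9, [7])):
            cell = inc(T, [y[0]])
            est = [diversity_at_coverage(cell, q, 0.5).D_hat for q in (0, 1, 2)]
            assert est == pytest.approx([1.0, 1.0, 1.0], abs=1e-9)

    def test_equal_incidence_collapse(self):
        # equal incidence across S species at full effort: D0 = D1 = D2 = S
        cell = inc(5, [3] * 7)
        for q in (0, 1, 2):
            assert hill_at_effort(cell, q, 5) == pytest.approx(7.0, abs=1e-10)

    @given(st.integers(0, 2**31 - 1))
    def test_hill_ordering_at_fixed_coverage(self, seed):
        from conftest import random_incidence

        cell = random_incidence(np.random.default_rng(seed))
        try:
            ests = [diversity_at_coverage(cell, q, 0.8).D_hat for q in (0, 1, 2)]
        except UnattainableCoverageError:
            return
        assert ests[0] >= ests[1] - 1e-9 >= ests[2] - 2e-9

    def test_q0_bounded_by_asymptote(self):
        rng = np.random.default_rng(3)
        from conftest import random_incidence

        for _ in range(50):
            cell = random_incidence(rng)
            d0 = hill_at_effort(cell, 0, 2.0 * cell.T)
            assert d0 <= _asymptotic_richness(cell) + 1e-9

    def test_golden_agreement_with_independent_implementation(self):
        """Frozen values from an independently coded base-R oracle (1e-6)."""
        golden = pd.read_csv(DATA / "golden_incidence.csv", skipinitialspace=True)
        for _, row in golden.iterrows():
            cell = inc(int(row["T"]), [int(v) for v in str(row["Y"]).split(";")])
            assert sample_coverage(cell, 0) == pytest.approx(row["C_T"], abs=1e-6)
            assert sample_coverage(cell, cell.T) == pytest.approx(row["C_2T"], abs=1e-6)
            m = effort_for_coverage(cell, 0.8)
            assert m == pytest.approx(row["m_star"], abs=1e-6)
            m_eval = max(m, 1.0)
            for q, col in ((0, "D0"), (1, "D1"), (2, "D2")):
                assert hill_at_effort(cell, q, m_eval) == pytest.approx(row[col], abs=1e-6)

    def test_rank_stability_between_80_and_90_coverage(self, demo_cells):
        """Diversity at 80% vs 90% coverage agree strongly in rank order."""
        from scipy.stats import spearmanr

        from biodivmap import ingest

        _, _, cells = demo_cells
        eligible, _ = ingest.apply_effort_filter(cells, 40)
        d80, d90 = [], []
        for cell in eligible:
            prof = classify_saturated(cell)
            if not prof.saturated or sample_coverage(cell, cell.T) < 0.9:
                continue
            d80.append(diversity_at_coverage(cell, 0, 0.80).D_hat)
            d90.append(diversity_at_coverage(cell, 0, 0.90).D_hat)
        assert len(d80) >= 15
        rho = spearmanr(d80, d90).statistic
        assert rho > 0.9


def mc_rarefied_hill(cell: IncidenceData, m: int, n_subsets: int, seed: int = 0):
    """Monte-Carlo oracle: Hill numbers from subset-averaged incidence counts.

    Realizes a unit-by-species membership matrix consistent with the incidence
    frequencies, subsamples m of T units ``n_subsets`` times, averages the
    species counts by incidence class, and evaluates the Hill functional on
    those averages. Returns (point estimates, batch-based MC standard errors).
    """
    rng = np.random.default_rng(seed)
    T, Y = cell.T, cell.Y
    member = np.zeros((T, cell.S_obs), dtype=bool)
    for j, yj in enumerate(Y):
        member[rng.choice(T, size=yj, replace=False), j] = True

    picks = np.argsort(rng.random((n_subsets, T)), axis=1)[:, :m]
    counts = member[picks].sum(axis=1)  # (n_subsets, S): per-species incidence

    def hill_from_mean_q(qk: np.ndarray) -> tuple[float, float, float]:
        k = np.arange(1, m + 1)
        u = float((k * qk).sum())
        d0 = float(qk.sum())
        pos = qk > 0
        d1 = float(np.exp(-((k[pos] / u) * np.log(k[pos] / u) * qk[pos]).sum()))
        d2 = float(u * u / ((k * k * qk).sum()))
        return d0, d1, d2

    qk_all = np.zeros(m)
    n_batches = 50
    batch_vals = np.zeros((n_batches, 3))
    batches = np.array_split(np.arange(n_subsets), n_batches)
    for b, idx in enumerate(batches):
        qk = np.zeros(m)
        c = counts[idx]
        for k in range(1, m + 1):
            qk[k - 1] = (c == k).sum(axis=1).mean()
        batch_vals[b] = hill_from_mean_q(qk)
        qk_all += qk * len(idx)
    qk_all /= n_subsets
    point = np.array(hill_from_mean_q(qk_all))
    se = batch_vals.std(axis=0, ddof=1) / np.sqrt(n_batches)
    return point, se


def test_rarefied_hill_matches_monte_carlo_small():
    """Spot check of the hypergeometric formulas against MC subsampling."""
    rng = np.random.default_rng(5)
    from conftest import random_incidence

    for trial in range(4):
        cell = random_incidence(rng, t_max=10, s_max=12)
        m = int(rng.integers(2, cell.T))
        point, se = mc_rarefied_hill(cell, m, n_subsets=20000, seed=trial)
        for q in (0, 1, 2):
            got = hill_at_effort(cell, q, m)
            assert abs(got - point[q]) <= 3 * se[q] + 1e-9
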