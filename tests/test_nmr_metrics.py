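"""CSP, CPMG flatness, CEST dip scan and assignment transfer."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.optimize import linear_sum_assignment

from mtlattice.nmr_metrics import (
    CESTProfile,
    CPMGSeries,
    ShiftRecord,
    assignment_completeness,
    cest_dip_scan,
    cpmg_flatness,
    csp,
    simulate_cpmg_two_state,
    transfer_assignments,
)


class TestCSP:
    @pytest.mark.parametrize(
        "dH,dN,expected",
        [
            (0.0, 0.0, 0.0),
            (0.3, 2.0, math.sqrt(0.09 + 0.09)),
            (0.1, 1.0, math.sqrt(0.01 + 0.0225)),
        ],
    )
    def test_hand_values(self, dH, dN, expected):
        assert csp(dH, dN) == pytest.approx(expected, abs=1e-9)

    @settings(derandomize=True, max_examples=50, deadline=None)
    @given(
        dH=st.floats(-2, 2, allow_nan=False),
        dN=st.floats(-10, 10, allow_nan=False),
        c=st.floats(0.1, 5.0),
    )
    def test_sign_flip_and_scaling_invariances(self, dH, dN, c):
        v = csp(dH, dN)
        assert v >= 0
        assert csp(-dH, dN) == pytest.approx(v, rel=1e-12, abs=1e-12)
        assert csp(dH, -dN) == pytest.approx(v, rel=1e-12, abs=1e-12)
        assert csp(c * dH, c * dN) == pytest.approx(c * v, rel=1e-9, abs=1e-12)

    def test_zero_iff_both_zero(self):
        assert csp(0.0, 0.0) == 0.0
        assert csp(1e-6, 0.0) > 0
        assert csp(0.0, 1e-6) > 0


class TestCPMG:
    def test_constant_profile_is_flat(self):
        s = CPMGSeries(1, (50.0, 150.0, 250.0), (100.0, 100.0, 100.0))
        assert cpmg_flatness(s) == 0.0

    def test_sd_over_mean_arithmetic(self):
        # intensities constructed with sample SD 5 about mean 100
        x = np.array([95.0, 105.0, 95.0, 105.0, 95.0, 105.0])
        x = 100.0 + (x - x.mean()) * (5.0 / x.std(ddof=1))
        s = CPMGSeries(1, tuple(50.0 + 100 * np.arange(6)), tuple(x))
        assert cpmg_flatness(s) == pytest.approx(0.05, abs=1e-12)

    def test_scale_invariance(self):
        base = CPMGSeries(1, (50.0, 250.0, 450.0), (90.0, 100.0, 110.0))
        scaled = CPMGSeries(1, base.frequencies, tuple(7.7 * v for v in base.intensities))
        assert cpmg_flatness(scaled) == pytest.approx(cpmg_flatness(base), rel=1e-12)

    def test_exchange_exceeds_flat_null(self, rng):
        # forward-simulated two-state exchange vs matched-noise flat profiles
        noise = 0.5
        exch = simulate_cpmg_two_state(
            1, k_ex=800.0, p_minor=0.05, delta_omega=2 * math.pi * 200.0,
            noise_sd=noise, rng=rng,
        )
        nulls = []
        for _ in range(200):
            flat = simulate_cpmg_two_state(
                2, k_ex=800.0, p_minor=0.0, delta_omega=0.0, noise_sd=noise, rng=rng
            )
            nulls.append(cpmg_flatness(flat))
        assert cpmg_flatness(exch) > np.percentile(nulls, 99)

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            cpmg_flatness(CPMGSeries(1, (50.0,), (1.0,)))


def _cest_profile(dips=(), noise_sd=0.0, rng=None):
    offsets = np.arange(8200.0, 6325.0 - 1, -25.0)
    intens = np.ones_like(offsets)
    main = 7300.0
    intens -= 0.8 * np.exp(-0.5 * ((offsets - main) / 40.0) ** 2)
    for off, depth in dips:
        intens -= depth * np.exp(-0.5 * ((offsets - off) / 30.0) ** 2)
    if noise_sd and rng is not None:
        intens = intens + rng.normal(0, noise_sd, size=intens.shape)
    return CESTProfile(1, tuple(offsets), tuple(intens))


class TestCEST:
    def test_single_dip_profile_reports_nothing(self):
        assert cest_dip_scan(_cest_profile(), noise_sd=0.01) == []

    def test_injected_minor_dip_located(self):
        prof = _cest_profile(dips=[(6800.0, 0.05)])
        found = cest_dip_scan(prof, noise_sd=0.01)
        assert len(found) == 1
        assert abs(found[0] - 6800.0) <= 25.0

    def test_null_false_positive_rate(self, rng):
        hits = 0
        n = 300
        for _ in range(n):
            offsets = np.arange(8200.0, 6325.0 - 1, -25.0)
            intens = 1.0 + rng.normal(0, 0.01, size=offsets.shape)
            prof = CESTProfile(1, tuple(offsets), tuple(intens))
            hits += bool(cest_dip_scan(prof, noise_sd=0.01))
        # single points below 3 sigma occur with p~0.0013 per point; with
        # ~76 points a profile trips occasionally but rarely
        assert hits / n < 0.25

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            cest_dip_scan(CESTProfile(1, (1.0, 2.0, 3.0), (1.0, 1.0, 1.0)), 0.1)


def _table(rng, n, start=1):
    return [
        ShiftRecord(start + i, "ALA", float(rng.uniform(6, 10)),
                    float(rng.uniform(100, 130)), float(rng.uniform(40, 65)))
        for i in range(n)
    ]


def _optimal_match_count(solution, observed, tol):
    """Exhaustive-optimal oracle via the Hungarian algorithm."""
    big = 1e6
    C = np.full((len(solution), len(observed)), big)
    for i, s in enumerate(solution):
        for j, o in enumerate(observed):
            d = [(s.HN - o.HN) / tol["HN"], (s.N - o.N) / tol["N"], (s.CA - o.CA) / tol["CA"]]
            if all(abs(x) <= 1 for x in d):
                C[i, j] = float(np.sqrt(np.sum(np.square(d))))
    rows, cols = linear_sum_assignment(C)
    return int(np.sum(C[rows, cols] < big))


class TestTransfer:
    TOL = {"HN": 0.1, "N": 0.6, "CA": 0.5}

    def test_identical_tables_all_matched(self, rng):
        table = _table(rng, 20)
        res = transfer_assignments(table, table, self.TOL)
        assert len(res["matches"]) == 20
        assert all(m["distance"] == 0.0 for m in res["matches"])
        assert all(m["solution_id"] == m["observed_id"] for m in res["matches"])

    def test_out_of_tolerance_peak_unmatched(self, rng):
        table = _table(rng, 1)
        shifted = [ShiftRecord(1, "ALA", table[0].HN + 0.2, table[0].N, table[0].CA)]
        res = transfer_assignments(table, shifted, self.TOL)
        assert res["matches"] == []
        assert res["unmatched_solution"] == [1]

    def test_greedy_equals_optimal_on_small_instances(self, rng):
        # brute-force bipartite matching oracle on <= 10-peak instances
        for trial in range(30):
            n = int(rng.integers(3, 11))
            sol = _table(rng, n)
            obs = [
                ShiftRecord(
                    s.residue_id, s.residue_name,
                    s.HN + rng.normal(0, 0.05), s.N + rng.normal(0, 0.3),
                    s.CA + rng.normal(0, 0.25),
                )
                for s in sol
                if rng.uniform() > 0.1  # some peaks missing
            ]
            if not obs:
                continue
            res = transfer_assignments(sol, obs, self.TOL)
            assert len(res["matches"]) == _optimal_match_count(sol, obs, self.TOL)

    def test_recovery_on_141_residue_table(self, rng):
        # construct-sized table, half-tolerance perturbations, 10% missing
        sol = _table(rng, 141, start=1474)
        obs = [
            ShiftRecord(s.residue_id, s.residue_name,
                        s.HN + rng.normal(0, 0.05), s.N + rng.normal(0, 0.3),
                        s.CA + rng.normal(0, 0.25))
            for s in sol
            if rng.uniform() > 0.1
        ]
        res = transfer_assignments(sol, obs, self.TOL)
        correct = sum(m["solution_id"] == m["observed_id"] for m in res["matches"])
        # each dimension is within tolerance w.p. ~0.954 at half-tolerance
        # noise, so ~87% of peaks are matchable at all
        assert correct / len(obs) > 0.8
        assert correct / len(res["matches"]) > 0.95


class TestCompleteness:
    def test_hsckk_construct(self):
        assert assignment_completeness(range(1474, 1474 + 124), (1474, 1613)) == 88.6

    def test_ngckk_construct(self):
        assert assignment_completeness(range(621, 621 + 87), (621, 788)) == 51.8

    def test_full_assignment(self):
        assert assignment_completeness(range(1, 11), (1, 10)) == 100.0

    def test_empty_range_rejected(self):
        with pytest.raises(ValueError):
            assignment_completeness([1], (10, 5))
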