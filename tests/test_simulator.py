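import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from allosim.affinity import PmHA
from allosim.expression import OrganOperator
from allosim.simulator import (
    CompetitionWeights,
    SimulationConfig,
    clone_capacity,
    clone_step,
    logistic_step,
    power_law_diagnostic,
    run_drp,
    run_organ,
)


def make_operator(ic50s, pexps=None, tissue="colon"):
    pexps = pexps if pexps is not None else [1.0] * len(ic50s)
    entries = []
    for i, (x, p) in enumerate(zip(ic50s, pexps)):
        pm = PmHA(sequence=f"{chr(65 + i % 26)}" * 9, hla_allele=f"A{i:04d}", ic50_nm=x, gene_id=f"g{i}")
        entries.append((pm, p))
    entries.sort(key=lambda e: (e[0].ic50_nm, e[0].sequence, e[0].hla_allele))
    return OrganOperator(tissue=tissue, entries=tuple(entries))


def oracle_trajectories(ic50s, pexps, cfg):
    """Independent pure-Python evaluation of the competing-clone map.

    Written directly from the closed formula with explicit loops; shares no
    code with the numpy implementation under test.
    """
    n = len(ic50s)
    af = [1.0 / x for x in ic50s]
    keff = [(pexps[i] * cfg.k) ** af[i] for i in range(n)]
    order = sorted(range(n), key=lambda i: ic50s[i])
    ic50s = [ic50s[i] for i in order]
    af = [af[i] for i in order]
    keff = [keff[i] for i in order]
    curr = [cfg.n0] * n
    traj = [list(curr)]
    r = -cfg.r if cfg.flip_r_sign else cfg.r
    for t in range(1, cfg.iterations + 1):
        nxt = []
        for x in range(n):
            if cfg.competition:
                s = sum(
                    curr[i] * (ic50s[x] / ic50s[i])
                    for i in range(n)
                    if cfg.include_self or i != x
                )
            else:
                s = curr[x]
            denom = (keff[x] - s) * math.exp(max(-700, min(700, -r * t * af[x]))) + 1.0
            nxt.append(max(0.0, keff[x] * cfg.n0 / denom) if denom > 0 else 0.0)
        curr = nxt
        traj.append(list(curr))
    return np.array(traj)


class TestLogisticStep:
    def test_at_capacity_returns_k_times_n0(self):
        assert logistic_step(1e6, 1.0, 1e6, 1.5, 7) == pytest.approx(1e6)

    def test_first_iteration_value(self):
        # direct arithmetic: 1e6*1 / ((1e6-1)*exp(-1.5) + 1)
        expected = 1e6 / ((1e6 - 1) * math.exp(-1.5) + 1.0)
        got = logistic_step(1.0, 1.0, 1e6, 1.5, 1)
        assert got == pytest.approx(expected, rel=1e-12)
        assert got == pytest.approx(4.4817, rel=1e-4)

    def test_large_t_approaches_k_times_n0(self):
        assert logistic_step(123.0, 1.0, 1e6, 1.5, 400) == pytest.approx(1e6, rel=1e-9)

    def test_invalid_args(self):
        with pytest.raises(ValueError):
            logistic_step(1.0, 1.0, 0.0, 1.5, 1)
        with pytest.raises(ValueError):
            logistic_step(1.0, 1.0, 1e6, 1.5, 0)

    def test_never_negative(self):
        assert logistic_step(2e6, 1.0, 1e6, -5.0, 3) >= 0.0


class TestCloneCapacity:
    def test_unit_exponent(self):
        assert clone_capacity(1.0, 1e6, 1.0) == pytest.approx(1e6)

    def test_fractional_exponent(self):
        assert clone_capacity(10.0, 1e6, 50.0) == pytest.approx(1e7**0.02, rel=1e-12)
        assert clone_capacity(10.0, 1e6, 50.0) == pytest.approx(1.3804, rel=1e-4)

    def test_infinite_ic50_limit(self):
        assert clone_capacity(1.0, 1e6, 1e12) == pytest.approx(1.0, rel=1e-9)

    def test_below_one_allowed(self):
        assert 0 < clone_capacity(1e-9, 1e6, 1e6) <= 1.0


class TestCompetitionWeights:
    def test_invariants(self):
        w = CompetitionWeights([1.0, 10.0, 500.0])
        for x in range(3):
            assert w.alpha(x, x) == 1.0
            for i in range(3):
                assert w.alpha(x, i) * w.alpha(i, x) == pytest.approx(1.0)

    def test_diagonal_structure_sorted_ascending(self):
        m = CompetitionWeights([1.0, 10.0, 500.0]).matrix()
        for x in range(3):
            for i in range(3):
                if i > x:
                    assert m[x, i] < 1
                elif i < x:
                    assert m[x, i] > 1


class TestCloneStep:
    def test_single_clone_matches_affinity_logistic(self):
        cfg = SimulationConfig(iterations=20, averaging_window=(11, 20))
        ic50, pexp = 10.0, 1.0
        af, keff = 1 / ic50, (pexp * cfg.k) ** (1 / ic50)
        w = CompetitionWeights([ic50])
        n_prev, n_eq3 = [cfg.n0], cfg.n0
        for t in range(1, 21):
            stepped = clone_step(0, n_prev, [keff], [af], w, cfg, t)
            n_eq3 = keff * cfg.n0 / ((keff - n_eq3) * math.exp(-cfg.r * t * af) + 1.0)
            assert stepped == pytest.approx(n_eq3, rel=1e-12)
            n_prev = [stepped]

    def test_reduces_to_base_logistic_at_af_one(self):
        # Eq 3 == Eq 1 when af = 1 and pexp = 1
        cfg = SimulationConfig(iterations=10, averaging_window=(5, 10))
        w = CompetitionWeights([1.0])
        n_clone, n_base = cfg.n0, cfg.n0
        for t in range(1, 11):
            n_clone = clone_step(0, [n_clone], [cfg.k], [1.0], w, cfg, t)
            n_base = logistic_step(n_base, cfg.n0, cfg.k, cfg.r, t)
            assert n_clone == pytest.approx(n_base, rel=1e-12)

    def test_high_affinity_clone_dominates_pairwise(self):
        cfg = SimulationConfig(iterations=50, averaging_window=(41, 50))
        op = make_operator([1.0, 500.0])
        sim = run_organ(op, cfg)
        hi = next(c for c in sim.clone_states if c.ic50_nm == 1.0)
        lo = next(c for c in sim.clone_states if c.ic50_nm == 500.0)
        assert np.all(hi.trajectory >= lo.trajectory)

    def test_three_clone_oracle_match(self):
        ic50s, pexps = [2.0, 37.0, 450.0], [5.0, 1.0, 20.0]
        cfg = SimulationConfig(iterations=10, averaging_window=(6, 10))
        expected = oracle_trajectories(ic50s, pexps, cfg)
        sim = run_organ(make_operator(ic50s, pexps), cfg)
        got = np.stack([c.trajectory for c in sim.clone_states], axis=1)
        np.testing.assert_allclose(got, expected, rtol=1e-9)

    def test_scalar_clone_step_matches_vectorized(self):
        ic50s = [3.0, 80.0, 220.0]
        cfg = SimulationConfig(iterations=8, averaging_window=(5, 8), competition=True)
        op = make_operator(ic50s)
        sim = run_organ(op, cfg)
        af = [1 / x for x in sorted(ic50s)]
        keff = [cfg.k ** a for a in af]
        w = CompetitionWeights(sorted(ic50s))
        for t in range(1, 9):
            n_prev = [c.trajectory[t - 1] for c in sim.clone_states]
            for x in range(3):
                got = clone_step(x, n_prev, keff, af, w, cfg, t)
                assert got == pytest.approx(sim.clone_states[x].trajectory[t], rel=1e-12)

    def test_exclude_self_oracle_match(self):
        ic50s, pexps = [5.0, 100.0], [1.0, 1.0]
        cfg = SimulationConfig(
            iterations=10, averaging_window=(6, 10), include_self=False
        )
        expected = oracle_trajectories(ic50s, pexps, cfg)
        sim = run_organ(make_operator(ic50s, pexps), cfg)
        got = np.stack([c.trajectory for c in sim.clone_states], axis=1)
        np.testing.assert_allclose(got, expected, rtol=1e-9)


class TestRunOrgan:
    def test_single_strong_clone_converges_to_k(self):
        cfg = SimulationConfig()
        sim = run_organ(make_operator([1.0]), cfg, keep_trajectories=False)
        assert sim.organ_count == pytest.approx(1e6, rel=0.01)

    def test_empty_operator_zero(self):
        sim = run_organ(OrganOperator(tissue="skin", entries=()), SimulationConfig())
        assert sim.organ_count == 0.0 and sim.n_clones_active == 0

    def test_duplicated_operator_doubles_without_competition(self):
        cfg = SimulationConfig(competition=False, iterations=100, averaging_window=(51, 100))
        ic50s = [2.0, 90.0, 400.0]
        single = run_organ(make_operator(ic50s), cfg)
        double = run_organ(make_operator(ic50s + ic50s), cfg)
        assert double.organ_count == pytest.approx(2 * single.organ_count, rel=1e-12)

    def test_no_nan_inf_even_with_extreme_inputs(self):
        cfg = SimulationConfig(iterations=100, averaging_window=(51, 100))
        ic50s = [0.001, 0.5, 1.0, 250.0, 500.0]
        pexps = [1e4, 0.0001, 1.0, 5000.0, 2.0]
        sim = run_organ(make_operator(ic50s, pexps), cfg)
        for c in sim.clone_states:
            assert np.all(np.isfinite(c.trajectory))
            assert np.all(c.trajectory >= 0)

    def test_monotone_growth_without_competition(self):
        cfg = SimulationConfig(competition=False, iterations=80, averaging_window=(41, 80))
        sim = run_organ(make_operator([5.0, 120.0], [2.0, 7.0]), cfg)
        for c in sim.clone_states:
            diffs = np.diff(c.trajectory[1:])
            assert np.all(diffs >= -1e-9)

    def test_determinism_bit_identical(self):
        cfg = SimulationConfig(iterations=120, averaging_window=(101, 120))
        op = make_operator([1.5, 40.0, 333.0], [2.0, 0.5, 9.0])
        a = run_organ(op, cfg)
        b = run_organ(op, cfg)
        assert a.organ_count == b.organ_count
        for ca, cb in zip(a.clone_states, b.clone_states):
            assert np.array_equal(ca.trajectory, cb.trajectory)

    @given(st.floats(1.0, 500.0), st.floats(1.0, 100.0), st.floats(1.1, 50.0))
    @settings(max_examples=30, deadline=None)
    def test_window_mean_monotone_in_pexp_and_affinity(self, ic50, pexp, factor):
        cfg = SimulationConfig(iterations=200, averaging_window=(101, 200))

        def mean_for(i, p):
            sim = run_organ(make_operator([i], [p]), cfg, keep_trajectories=False)
            return sim.clone_states[0].window_mean

        base = mean_for(ic50, pexp)
        assert mean_for(ic50, pexp * factor) >= base - 1e-9 * abs(base)
        assert mean_for(ic50 / factor, pexp) >= base - 1e-9 * abs(base)


class TestRunDrp:
    def test_total_is_sum_of_organs(self):
        cfg = SimulationConfig(iterations=50, averaging_window=(26, 50))
        ops = {
            "skin": make_operator([2.0, 80.0], tissue="skin"),
            "colon": make_operator([10.0], tissue="colon"),
        }
        res = run_drp(ops, cfg)
        assert res.total == pytest.approx(
            res.organ_counts["skin"] + res.organ_counts["colon"]
        )

    def test_order_invariance(self):
        cfg = SimulationConfig(iterations=50, averaging_window=(26, 50))
        ops = {
            "skin": make_operator([2.0, 80.0], tissue="skin"),
            "colon": make_operator([10.0, 444.0], tissue="colon"),
            "lung": make_operator([33.0], tissue="lung"),
        }
        fwd = run_drp(dict(ops), cfg)
        rev = run_drp(dict(reversed(list(ops.items()))), cfg)
        assert fwd.total == rev.total
        assert fwd.organ_counts == rev.organ_counts


class TestPowerLawDiagnostic:
    def test_exact_power_law(self):
        sizes = [1000.0 / r for r in range(1, 40)]
        slope, r2 = power_law_diagnostic(sizes)
        assert slope == pytest.approx(-1.0, abs=1e-9)
        assert r2 == pytest.approx(1.0, abs=1e-9)

    def test_constant_sizes(self):
        slope, _ = power_law_diagnostic([7.0] * 25)
        assert slope == pytest.approx(0.0, abs=1e-12)

    def test_too_few_clones_raises(self):
        with pytest.raises(ValueError):
            power_law_diagnostic([1.0] * 9)

    def test_simulated_repertoire_fits_power_law(self):
        # log-uniform IC50 operator, as the synthetic affinity model produces
        rng = np.random.default_rng(42)
        ic50s = list(10 ** rng.uniform(0, np.log10(500), size=150))
        pexps = list(10 ** rng.normal(np.log10(5), 0.8, size=150))
        cfg = SimulationConfig()
        sim = run_organ(make_operator(ic50s, pexps), cfg, keep_trajectories=False)
        sizes = [c.window_mean for c in sim.clone_states if c.window_mean > 0]
        _, r2 = power_law_diagnostic(sizes)
        assert r2 >= 0.8
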