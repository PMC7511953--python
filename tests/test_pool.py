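"""Whole-cell pool conservation, polysome prediction, knockdown scenarios."""

import math

import numpy as np
import pytest

from ribocompete.model import JammedRegimeError, TranscriptParams, protein_yield
from ribocompete.pool import (
    ElongationModel,
    KnockdownScenario,
    PolysomeProfile,
    PoolState,
    polysome_fractions,
    simulate_knockdown,
    solve_free_ribosomes,
    total_bound,
)
from ribocompete.synthetic import calibrate_r_total, generate_transcriptome
from tests.conftest import make_transcript, random_transcriptome


def bound_oracle(transcripts, R):
    """Independent, vectorized bound computation (numpy transcription of the
    closed form), used to cross-check the package's bookkeeping."""
    ki = np.array([t.ki for t in transcripts])
    ke = np.array([t.ke for t in transcripts])
    m = np.array([t.m for t in transcripts])
    n = np.array([t.n_codons for t in transcripts])
    L = np.array([t.L for t in transcripts])
    p = 1.0 - L / (ke / (ki * R) + L - 1.0)
    return float(np.sum(m * R * ki * p * n / ke))


def solve_oracle(transcripts, R_total, iters=200):
    """Brute-force bisection on the conservation residual."""
    lo, hi = 1e-12 * R_total, min([R_total] + [t.ke / t.ki for t in transcripts])
    for _ in range(iters):
        mid = 0.5 * (lo + hi)
        if mid + bound_oracle(transcripts, mid) < R_total:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


class TestTotalBound:
    def test_empty_transcriptome(self):
        assert total_bound([], 1.0) == 0.0

    def test_no_initiation_without_free_ribosomes(self):
        assert total_bound([make_transcript()], 0.0) == 0.0

    def test_single_gene_equals_per_copy_load(self):
        t = make_transcript(ki=0.1, ke=10.0, m=1.0, n_codons=300)
        assert total_bound([t], 1.0) == pytest.approx((0.1 * 99 / 109) * 30, rel=1e-12)

    def test_jamming_error_names_gene(self):
        t = make_transcript(gene_id="offender", ki=1.0, ke=1.0)
        with pytest.raises(JammedRegimeError, match="offender"):
            total_bound([t], 5.0)

    def test_increasing_below_maximal_current(self):
        # monotone in R_free while every gene stays below x* = 1/(sqrt(L)+1)
        rng = np.random.default_rng(4)
        ts = random_transcriptome(rng, 30)
        x_star = 1.0 / (math.sqrt(10) + 1.0)
        r_max = x_star * min(t.ke / t.ki for t in ts)
        grid = np.linspace(1e-3, r_max, 50)
        vals = [total_bound(ts, r) for r in grid]
        assert all(a < b for a, b in zip(vals, vals[1:]))


class TestSolveFreeRibosomes:
    def test_empty_transcriptome_keeps_everything_free(self):
        assert solve_free_ribosomes([], 100.0).R_free == 100.0

    def test_zero_abundance_keeps_everything_free(self):
        ts = [make_transcript(m=0.0)]
        assert solve_free_ribosomes(ts, 5.0).R_free == 5.0

    def test_single_gene_matches_bisection_oracle(self):
        ts = [make_transcript(ki=0.1, ke=10.0, m=1.0, n_codons=300)]
        state = solve_free_ribosomes(ts, 3.0)
        resid = state.R_free + total_bound(ts, state.R_free) - 3.0
        assert abs(resid) < 1e-8
        assert state.R_free == pytest.approx(solve_oracle(ts, 3.0), abs=1e-9)

    def test_conservation_on_random_transcriptomes(self):
        rng = np.random.default_rng(7)
        for _ in range(20):
            ts = random_transcriptome(rng, int(rng.integers(20, 120)))
            R_total = float(rng.uniform(1.0, 10.0))
            state = solve_free_ribosomes(ts, R_total)
            resid = abs(state.R_free + total_bound(ts, state.R_free) - R_total)
            assert resid / R_total < 1e-8
            assert abs(state.R_free - solve_oracle(ts, R_total)) <= 1e-6 * R_total

    def test_jamming_reported_with_binding_gene(self):
        # huge pool, tiny mRNA capacity: conservation would cross the jamming point
        ts = [make_transcript(gene_id="fast", ki=1.0, ke=10.0, m=0.001)]
        with pytest.raises(JammedRegimeError, match="fast"):
            solve_free_ribosomes(ts, 100.0)

    def test_invalid_total_rejected(self):
        with pytest.raises(ValueError):
            solve_free_ribosomes([make_transcript()], 0.0)


class TestPolysomeFractions:
    def test_all_free_without_mrna(self):
        pool = PoolState(R_total=5.0, R_free=5.0)
        prof = polysome_fractions([make_transcript(m=0.0)], pool)
        assert prof.free_frac == 1.0
        assert prof.mono_frac == prof.light_frac == prof.heavy_frac == 0.0
        assert prof.mono_to_poly_capped and math.isinf(prof.mono_to_poly)

    def test_matches_truncated_poisson_enumeration(self):
        # single gene with load lambda = 2, capacity 30: exhaustive enumeration
        t = make_transcript(ki=0.1, ke=10.0, m=1.0, n_codons=300)
        # pick R so that load_per_mrna = 2: R*ki*p*n/ke = 2
        from scipy.optimize import brentq

        R = brentq(lambda r: protein_yield(t, r).load_per_mrna - 2.0, 1e-6, 9.0)
        lam = protein_yield(t, R).load_per_mrna
        bound = t.m * lam
        pool = PoolState(R_total=bound + R, R_free=R)
        prof = polysome_fractions([t], pool)

        j = np.arange(31)
        pmf = np.exp(-lam) * lam**j / np.array([math.factorial(int(k)) for k in j])
        pmf /= pmf.sum()
        w = j * pmf
        total = R + bound
        assert prof.mono_frac == pytest.approx(bound * w[1] / w.sum() / total, rel=1e-9)
        assert prof.light_frac == pytest.approx(bound * w[2:5].sum() / w.sum() / total, rel=1e-9)
        assert prof.heavy_frac == pytest.approx(bound * w[5:].sum() / w.sum() / total, rel=1e-9)

    def test_fractions_sum_to_one(self):
        rng = np.random.default_rng(11)
        ts = random_transcriptome(rng, 40)
        state = solve_free_ribosomes(ts, 5.0)
        prof = polysome_fractions(ts, state)
        total = prof.free_frac + prof.mono_frac + prof.light_frac + prof.heavy_frac
        assert total == pytest.approx(1.0, abs=1e-9)

    def test_validation_rejects_bad_fractions(self):
        with pytest.raises(ValueError):
            PolysomeProfile(0.5, 0.5, 0.5, 0.5, 1.0)


class TestKnockdownScenario:
    def test_depletion_factor_bounds(self):
        for f in (0.0, 1.5, -0.1):
            with pytest.raises(ValueError):
                KnockdownScenario(f)

    def test_uniform_scaling_without_charge_model(self):
        ts = [make_transcript(ki=0.1, ke=10.0)]
        base, kd = KnockdownScenario(0.2, elongation=None).transcriptomes(ts)
        assert base[0].ke == 10.0
        assert kd[0].ke == pytest.approx(2.0)

    def test_charge_model_slows_charged_genes_less(self):
        n = 200
        charged = make_transcript("c", n_codons=n, charge_profile=np.ones(n, dtype=int))
        plain = make_transcript("p", n_codons=n)
        sc = KnockdownScenario(0.05)
        base, kd = sc.transcriptomes([charged, plain])
        f_charged = kd[0].ke / base[0].ke
        f_plain = kd[1].ke / base[1].ke
        assert f_charged > f_plain  # the charge handicap dilutes under scarcity
        # uncharged transcript at full availability keeps its nominal rate
        assert base[1].ke == pytest.approx(10.0)

    def test_charge_factor_bounds(self):
        em = ElongationModel(beta=0.3, W=10)
        n = 50
        assert em.charge_factor(make_transcript(n_codons=n)) == 1.0
        hot = make_transcript(n_codons=n, charge_profile=np.ones(n, dtype=int))
        assert em.charge_factor(hot) > 1.0


class TestSimulateKnockdown:
    def test_identity_scenario_changes_nothing(self, default_transcriptome):
        ts = default_transcriptome.transcripts
        R_total = calibrate_r_total(default_transcriptome, KnockdownScenario(1.0))
        res = simulate_knockdown(ts, R_total, KnockdownScenario(1.0))
        assert (res.table["log2_rel_yield_change"] == 0.0).all()
        assert res.baseline_pool.R_free == res.knockdown_pool.R_free

    def test_depletion_favors_top_class(self, default_transcriptome):
        ts = default_transcriptome
        sc = KnockdownScenario(0.05)
        res = simulate_knockdown(ts.transcripts, calibrate_r_total(ts, sc), sc)
        tab = res.table.copy()
        tab["class"] = ts.class_label
        med = tab.groupby("class")["log2_rel_yield_change"].median()
        assert med["TOP"] > 0.0 > med["other"]
        # pool and polysome signatures of impaired elongation
        assert res.knockdown_pool.R_free < res.baseline_pool.R_free
        assert res.knockdown_profile.mono_to_poly < res.baseline_profile.mono_to_poly
        assert res.knockdown_profile.heavy_frac > res.baseline_profile.heavy_frac

    def test_deeper_depletion_monotone_signatures(self, default_transcriptome):
        ts = default_transcriptome
        R_total = calibrate_r_total(ts, KnockdownScenario(0.05))
        r_free, m2p, top_median = [], [], []
        for f in (1.0, 0.3, 0.05):
            res = simulate_knockdown(ts.transcripts, R_total, KnockdownScenario(f))
            tab = res.table.copy()
            tab["class"] = ts.class_label
            r_free.append(res.knockdown_pool.R_free)
            m2p.append(res.knockdown_profile.mono_to_poly)
            top_median.append(tab.groupby("class")["log2_rel_yield_change"].median()["TOP"])
        assert r_free[0] >= r_free[1] >= r_free[2]
        assert m2p[0] >= m2p[1] >= m2p[2]
        assert top_median[0] <= top_median[1] <= top_median[2]

    def test_overdepletion_reports_jam(self):
        # uniform scaling with a tiny transcriptome cannot absorb the pool
        ts = [make_transcript(ki=0.5, ke=10.0, m=0.01, n_codons=200)]
        with pytest.raises(JammedRegimeError):
            simulate_knockdown(ts, 10.0, KnockdownScenario(0.01, elongation=None))
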