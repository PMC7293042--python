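"""The site-calling statistics: binomial tests, winsorized Fisher, BH."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from tmodscan.pileup import PILEUP_COLUMNS
from tmodscan.simulate import simulate_null_pileups
from tmodscan.stats import (
    bh_adjust,
    call_sites,
    estimate_background,
    fisher_combine,
    test_event as binom_tail_test,
    winsorize_pvalues,
)


def binom_tail_oracle(k, n, pi):
    """Brute-force enumeration of P(X >= k)."""
    return sum(
        math.comb(n, i) * pi**i * (1 - pi) ** (n - i) for i in range(k, n + 1)
    )


def bh_oracle(p):
    """Step-up definition: q_i = min over p_(j) >= p_i of m*p_(j)/j, capped."""
    m = len(p)
    order = np.argsort(p, kind="stable")
    q = np.empty(m)
    running = math.inf
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, m * p[i] / rank)
        q[i] = min(running, 1.0)
    return q


class TestTestEvent:
    def test_zero_count_is_one(self):
        assert binom_tail_test(0, 50, 0.01) == 1.0

    def test_k_equals_n_closed_form(self):
        assert binom_tail_test(7, 7, 0.1) == pytest.approx(0.1**7, rel=1e-12)

    def test_matches_enumeration(self):
        assert binom_tail_test(3, 10, 0.1) == pytest.approx(
            binom_tail_oracle(3, 10, 0.1), rel=1e-12
        )

    def test_zero_trials_returns_one(self):
        assert binom_tail_test(0, 0, 0.1) == 1.0

    def test_monotone_in_k_and_pi(self):
        ps = [binom_tail_test(k, 30, 0.05) for k in range(0, 31)]
        assert all(a >= b for a, b in zip(ps, ps[1:]))
        pis = [binom_tail_test(4, 30, x) for x in (0.001, 0.01, 0.05, 0.2)]
        assert all(a <= b for a, b in zip(pis, pis[1:]))

    def test_invalid_background_rejected(self):
        with pytest.raises(ValueError):
            binom_tail_test(1, 10, 0.0)


class TestWinsorize:
    def test_removes_extremes(self):
        assert winsorize_pvalues([0.01, 0.5, 0.9]) == [0.5]

    def test_ties_remove_one_occurrence_each(self):
        assert winsorize_pvalues([0.2, 0.2, 0.2, 0.2]) == [0.2, 0.2]

    def test_short_lists_unchanged(self):
        assert winsorize_pvalues([0.3, 0.7]) == [0.3, 0.7]

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            winsorize_pvalues([])


class TestFisher:
    def test_single_value_identity(self):
        for p in (1e-6, 1e-3, 0.05, 0.5, 0.99):
            assert fisher_combine([p]) == pytest.approx(p, abs=1e-12)

    def test_all_ones_is_one(self):
        assert fisher_combine([1.0, 1.0]) == pytest.approx(1.0)

    def test_chi2_df4_closed_form(self):
        # survival of chi2 with 4 df at x is (1 + x/2) exp(-x/2)
        x = -2 * (math.log(0.1) + math.log(0.1))
        expected = (1 + x / 2) * math.exp(-x / 2)
        assert fisher_combine([0.1, 0.1]) == pytest.approx(expected, rel=1e-12)


class TestBH:
    def test_all_equal(self):
        assert bh_adjust([0.03, 0.03, 0.03]) == pytest.approx([0.03] * 3)

    def test_step_up_example(self):
        assert bh_adjust([0.01, 0.02, 0.03]) == pytest.approx([0.03, 0.03, 0.03])

    def test_single_test(self):
        assert bh_adjust([0.2]) == pytest.approx([0.2])

    @settings(max_examples=40, derandomize=True, deadline=None)
    @given(st.integers(0, 10_000))
    def test_matches_brute_force_on_random_vectors(self, seed):
        rng = np.random.default_rng(seed)
        p = rng.random(int(rng.integers(1, 200)))
        assert bh_adjust(p) == pytest.approx(bh_oracle(p), rel=1e-10)


def _uniform_error_frame(rng, n_sites=400, cov=500, g_to_a=0.01):
    """Pileup with G positions carrying uniform G->A errors, others clean."""
    refs = np.array(list("GCGT"))[rng.integers(0, 4, n_sites)]
    rows = []
    for i, ref in enumerate(refs):
        counts = dict.fromkeys("ACGT", 0)
        err = rng.binomial(cov, g_to_a) if ref == "G" else 0
        counts[ref] = cov - err
        if ref == "G":
            counts["A"] += err
        rows.append(
            {
                "target_id": "t", "pos": i + 1, "ref": ref, **counts,
                "del": 0, "ins": 0, "coverage": cov,
                "error_rate": (cov - counts[ref]) / cov,
            }
        )
    return pd.DataFrame(rows, columns=PILEUP_COLUMNS)


class TestBackground:
    def test_uniform_error_rate_recovered(self, rng):
        frame = _uniform_error_frame(rng)
        bg = estimate_background(frame)
        assert bg.rate("G", "A") == pytest.approx(0.01, rel=0.2)
        # unused substitution types sit at the floor
        assert bg.rate("C", "T") == pytest.approx(1e-6)

    def test_error_free_pileup_floored(self, rng):
        frame = _uniform_error_frame(rng, g_to_a=0.0)
        bg = estimate_background(frame)
        assert all(r == pytest.approx(1e-6) for r in bg.rates.values())

    def test_saturated_outlier_trimmed(self, rng):
        frame = _uniform_error_frame(rng, n_sites=100)
        hot = frame.index[frame["ref"] == "G"][0]
        frame.loc[hot, ["A", "G", "error_rate"]] = [450, 50, 0.9]
        bg_all = estimate_background(frame)
        clean = frame.drop(index=hot)
        bg_clean = estimate_background(clean)
        assert bg_all.n_positions_trimmed >= 1
        assert bg_all.rate("G", "A") == pytest.approx(
            bg_clean.rate("G", "A"), rel=0.1
        )


class TestCallSites:
    def test_coverage_gate_blocks_saturated_site(self, rng):
        frames = simulate_null_pileups(200, 150, 0.003, 1, rng)
        frame = next(iter(frames.values()))
        # a 100%-mismatch site with coverage 9 must not be called
        frame.loc[0, ["A", "C", "G", "T", "del", "coverage", "error_rate"]] = 0
        ref = frame.loc[0, "ref"]
        alt = "A" if ref != "A" else "C"
        frame.loc[0, alt] = 9
        frame.loc[0, "coverage"] = 9
        frame.loc[0, "error_rate"] = 1.0
        callset = call_sites({"s1": frame}, min_cov=10, fdr=0.01)
        assert ("null", 1) not in callset.sites

    def test_strong_site_called_in_every_replicate(self, rng):
        frames = simulate_null_pileups(500, 200, 0.002, 3, rng)
        for frame in frames.values():
            # 20% misincorporation spread over 3 substitutions + deletions
            ref = frame.loc[10, "ref"]
            alts = [b for b in "ACGT" if b != ref]
            frame.loc[10, alts] = [14, 13, 13]
            frame.loc[10, "del"] = 10
            frame.loc[10, ref] = 160
            frame.loc[10, "coverage"] = 200
            frame.loc[10, "error_rate"] = 40 / 200
        callset = call_sites(frames, min_cov=10, fdr=0.01)
        assert ("null", 11) in callset.sites
        for sample, frame in callset.per_sample.items():
            assert frame.loc[frame["pos"] == 11, "passes"].all(), sample

    def test_events_subs_mode_reduces_to_middle_p(self, rng):
        frames = simulate_null_pileups(50, 100, 0.003, 1, rng)
        callset = call_sites(frames, events="subs")
        frame = next(iter(callset.per_sample.values()))
        assert {"p_sub1", "p_sub2", "p_sub3"} <= set(frame.columns)
        assert "p_del" not in frame.columns

    def test_requires_samples(self):
        with pytest.raises(ValueError):
            call_sites({})
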