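"""Entropy estimators against brute-force oracles and their invariants."""

import numpy as np
import pytest

from etfe.entropy import (NO_MATCH, EntropyConfig, apen, embed, entropy_value,
                          fuzzen, incren, peen, sampen, wpeen)

from oracles import (apen_brute, fuzzen_brute, incren_brute, peen_brute,
                     sampen_brute, wpeen_brute)


class TestEmbed:
    def test_basic(self):
        np.testing.assert_array_equal(embed([1, 2, 3, 4], 2, 1),
                                      [[1, 2], [2, 3], [3, 4]])

    def test_delay(self):
        np.testing.assert_array_equal(embed([1, 2, 3, 4, 5], 3, 2), [[1, 3, 5]])

    def test_too_short(self):
        with pytest.raises(ValueError):
            embed([1, 2, 3, 4], 3, 2)  # needs (gamma-1)*tau + 1 = 5


class TestDefaults:
    def test_standard_parameterizations(self):
        for m in ("apen", "sampen", "fuzzen"):
            c = EntropyConfig.default_for(m)
            assert (c.gamma, c.r) == (3, 0.2)
        for m in ("peen", "wpeen"):
            c = EntropyConfig.default_for(m)
            assert (c.gamma, c.tau) == (4, 1)
        c = EntropyConfig.default_for("incren")
        assert (c.gamma, c.phi) == (3, 2)

    @pytest.mark.parametrize("kwargs", [
        {"method": "nope"}, {"gamma": 1}, {"r": 0.0}, {"tau": 0}, {"phi": 0},
    ])
    def test_invalid(self, kwargs):
        with pytest.raises(ValueError):
            EntropyConfig(**kwargs)


class TestOracleAgreement:
    """Every estimator matches a direct nested-loop implementation to 1e-12."""

    @pytest.mark.parametrize("seed", [0, 1, 2])
    @pytest.mark.parametrize("n", [40, 120])
    def test_apen(self, seed, n):
        x = np.random.default_rng(seed).standard_normal(n)
        cfg = EntropyConfig(method="apen", gamma=2, r=0.2)
        r_abs = 0.2 * np.std(x)
        assert apen(x, cfg) == pytest.approx(apen_brute(x, 2, r_abs), abs=1e-12)

    def test_apen_even_series(self):
        x = np.arange(2, 21, 2, dtype=float)
        cfg = EntropyConfig(method="apen", gamma=2, r=0.2)
        assert apen(x, cfg) == pytest.approx(
            apen_brute(x, 2, 0.2 * np.std(x)), abs=1e-12)

    def test_sampen_alternating(self):
        x = np.array([1.0, -1, 1, -1, 1, -1, 1, -1])
        cfg = EntropyConfig(method="sampen", gamma=2, r=0.5, r_mode="abs")
        assert sampen(x, cfg) == pytest.approx(sampen_brute(x, 2, 0.5),
                                               abs=1e-12)

    @pytest.mark.parametrize("seed", [3, 4])
    def test_sampen_random(self, seed):
        x = np.random.default_rng(seed).standard_normal(100)
        cfg = EntropyConfig(method="sampen", gamma=3, r=0.2)
        assert sampen(x, cfg) == pytest.approx(
            sampen_brute(x, 3, 0.2 * np.std(x)), abs=1e-12)

    @pytest.mark.parametrize("seed", [5, 6])
    def test_fuzzen_random(self, seed):
        x = np.random.default_rng(seed).standard_normal(200)
        cfg = EntropyConfig(method="fuzzen", gamma=3, r=0.2, fuzz_power=2)
        assert fuzzen(x, cfg) == pytest.approx(
            fuzzen_brute(x, 3, 0.2 * np.std(x), 2), abs=1e-12)

    @pytest.mark.parametrize("seed", [7, 8])
    def test_peen_random(self, seed):
        x = np.random.default_rng(seed).standard_normal(150)
        cfg = EntropyConfig(method="peen", gamma=4, tau=1)
        assert peen(x, cfg) == pytest.approx(peen_brute(x, 4, 1), abs=1e-12)

    def test_peen_updown(self):
        x = [1, 3, 2, 4, 3, 5, 4, 6]
        cfg = EntropyConfig(method="peen", gamma=2, tau=1)
        assert peen(x, cfg) == pytest.approx(peen_brute(x, 2, 1), abs=1e-12)
        # 4 ups, 3 downs over 7 patterns
        expected = -(4 / 7 * np.log(4 / 7) + 3 / 7 * np.log(3 / 7))
        assert peen(x, cfg) == pytest.approx(expected, abs=1e-12)

    def test_wpeen_two_amplitudes(self):
        x = np.concatenate([np.tile([0.1, -0.1], 10), np.tile([10, -10], 10)])
        cfg = EntropyConfig(method="wpeen", gamma=2, tau=1)
        assert wpeen(x, cfg) == pytest.approx(wpeen_brute(x, 2, 1), abs=1e-12)

    @pytest.mark.parametrize("seed", [9, 10])
    def test_wpeen_random(self, seed):
        x = np.random.default_rng(seed).standard_normal(150)
        cfg = EntropyConfig(method="wpeen", gamma=4, tau=1)
        assert wpeen(x, cfg) == pytest.approx(wpeen_brute(x, 4, 1), abs=1e-12)

    def test_incren_sawtooth(self):
        x = [1, 2, 1, 3, 1, 4, 1, 5]
        cfg = EntropyConfig(method="incren", gamma=3, phi=2)
        assert incren(x, cfg) == pytest.approx(incren_brute(x, 3, 2), abs=1e-12)

    @pytest.mark.parametrize("seed", [11, 12])
    def test_incren_random(self, seed):
        x = np.random.default_rng(seed).standard_normal(120)
        cfg = EntropyConfig(method="incren", gamma=3, phi=2)
        assert incren(x, cfg) == pytest.approx(incren_brute(x, 3, 2), abs=1e-12)


class TestSpecialValues:
    @pytest.mark.parametrize("method", ["apen", "sampen", "fuzzen", "wpeen",
                                        "incren"])
    def test_constant_series_is_zero(self, method):
        cfg = EntropyConfig.default_for(method)
        assert entropy_value(np.full(60, 3.7), cfg) == 0.0

    def test_monotone_peen_zero(self):
        cfg = EntropyConfig.default_for("peen")
        assert peen(np.arange(30.0), cfg) == 0.0

    def test_linear_ramp_incren_zero(self):
        cfg = EntropyConfig.default_for("incren")
        assert incren(np.arange(30.0) * 2.5, cfg) == 0.0

    def test_noise_more_complex_than_sine(self):
        rng = np.random.default_rng(0)
        noise = rng.uniform(size=500)
        sine = np.sin(2 * np.pi * 5 * np.arange(500) / 500)
        cfg = EntropyConfig.default_for("apen")
        assert apen(noise, cfg) > apen(sine, cfg)

    def test_sampen_no_match_sentinel(self):
        # widely spaced values, tiny absolute radius: no matches at all
        x = np.array([0.0, 10, 1, 11, 2, 12, 3, 13])
        cfg = EntropyConfig(method="sampen", gamma=2, r=1e-6, r_mode="abs")
        with pytest.warns(UserWarning):
            assert sampen(x, cfg) == NO_MATCH

    def test_wpeen_equals_peen_for_equal_variance_embeddings(self):
        x = np.tile([0.0, 1.0], 15)  # every length-2 embedding has var 0.25
        p = EntropyConfig(method="peen", gamma=2)
        w = EntropyConfig(method="wpeen", gamma=2)
        assert wpeen(x, w) == pytest.approx(peen(x, p), abs=1e-15)


class TestInvariances:
    METHODS = ["apen", "sampen", "fuzzen", "peen", "wpeen", "incren"]

    @pytest.mark.parametrize("method", METHODS)
    def test_translation_invariant(self, method, rng):
        x = rng.standard_normal(100)
        cfg = EntropyConfig.default_for(method)
        a, b = entropy_value(x, cfg), entropy_value(x + 57.3, cfg)
        assert a == pytest.approx(b, abs=1e-9)

    @pytest.mark.parametrize("method", ["apen", "sampen", "fuzzen"])
    def test_scale_invariant_with_std_radius(self, method, rng):
        x = rng.standard_normal(100)
        cfg = EntropyConfig.default_for(method)
        a, b = entropy_value(x, cfg), entropy_value(x * 13.0, cfg)
        assert a == pytest.approx(b, abs=1e-9)

    @pytest.mark.parametrize("method", ["peen", "wpeen", "incren"])
    def test_bounded_by_log_pattern_count(self, method, rng):
        x = rng.standard_normal(200)
        cfg = EntropyConfig.default_for(method)
        v = entropy_value(x, cfg)
        if method in ("peen", "wpeen"):
            import math
            bound = np.log(float(math.factorial(cfg.gamma)))
        else:
            bound = np.log(float((2 * (cfg.phi + 1) + 1) ** cfg.gamma))
        assert -1e-12 <= v <= bound + 1e-12

    @pytest.mark.parametrize("method", METHODS)
    def test_deterministic(self, method, rng):
        x = rng.standard_normal(80)
        cfg = EntropyConfig.default_for(method)
        assert entropy_value(x, cfg) == entropy_value(x.copy(), cfg)
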