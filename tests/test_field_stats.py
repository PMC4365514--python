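"""Variance components, repeatability, correlation and HSD grouping."""

import numpy as np
import pandas as pd
import pytest

from aeropheno.errors import (
    InsufficientReplicationError,
    UnbalancedDesignError,
    UndefinedCorrelationError,
)
from aeropheno.field_stats import (
    correlate,
    estimate_components,
    hsd_compare,
    repeatability_profile,
    significance_code,
)
from aeropheno.scene import simulate_balanced_trait


def balanced_table(values: np.ndarray) -> pd.DataFrame:
    g, r = values.shape
    rows = [
        {
            "genotype": f"g{i:02d}",
            "block": f"b{j + 1}",
            "rows_per_plot": 4,
            "campaign": "c",
            "trait": "y",
            "value": values[i, j],
        }
        for i in range(g)
        for j in range(r)
    ]
    return pd.DataFrame(rows)


class TestVarianceComponents:
    def test_noiseless_genotype_effects_give_h2_of_one(self):
        y = np.tile(np.arange(16.0)[:, None], (1, 4))
        vc = estimate_components(balanced_table(y), "y")
        assert vc.h2 == 1.0
        assert vc.sigma2_eps == pytest.approx(0.0, abs=1e-20)

    def test_pure_noise_gives_near_zero_h2(self, rng):
        h2s = [
            estimate_components(
                balanced_table(rng.normal(size=(16, 4))), "y"
            ).h2
            for _ in range(200)
        ]
        assert np.median(h2s) < 0.15

    # Expected finite-sample means of the ANOVA h2 estimator (g=16, r=4),
    # frozen from a 200k-replicate simulation oracle.  The estimator
    # h2 = 1 - MS_e/MS_g carries a Jensen bias of roughly
    # -(s2e/(r*s2g+s2e)) * df/(df-2) below the plug-in ratio, so at low
    # genotypic variance the mean sits visibly under the plug-in value.
    @pytest.mark.parametrize(
        "ratio, expected_mean",
        [(0.25, 0.4448), (1.0, 0.7694), (3.0, 0.9112), (4.0, 0.9320)],
    )
    def test_parameter_recovery_across_variance_ratios(
        self, ratio, expected_mean, rng
    ):
        h2s = [
            estimate_components(
                simulate_balanced_trait(16, 4, ratio, 1.0, rng), "y"
            ).h2
            for _ in range(500)
        ]
        assert np.mean(h2s) == pytest.approx(expected_mean, abs=0.03)
        # at the higher ratios the mean also tracks the plug-in value
        if ratio >= 3.0:
            plugin = ratio / (ratio + 1.0 / 4)
            assert np.mean(h2s) == pytest.approx(plugin, abs=0.03)

    def test_h2_bounded_under_fuzzing(self, rng):
        for _ in range(100):
            y = rng.normal(
                scale=rng.uniform(0.01, 100), size=(int(rng.integers(2, 20)), 4)
            )
            vc = estimate_components(balanced_table(y), "y")
            assert 0.0 <= vc.h2 <= 1.0
            assert vc.sigma2_gen >= 0.0

    def test_location_scale_invariance(self, rng):
        y = rng.normal(size=(16, 4))
        base = estimate_components(balanced_table(y), "y").h2
        shifted = estimate_components(balanced_table(y + 123.4), "y").h2
        scaled = estimate_components(balanced_table(y * 55.5), "y").h2
        assert shifted == pytest.approx(base, rel=1e-9)
        assert scaled == pytest.approx(base, rel=1e-9)

    def test_block_effects_removed_as_fixed(self, rng):
        y = rng.normal(size=(16, 4))
        with_blocks = y + np.array([0.0, 10.0, -5.0, 3.0])[None, :]
        a = estimate_components(balanced_table(y), "y")
        b = estimate_components(balanced_table(with_blocks), "y")
        assert b.h2 == pytest.approx(a.h2, rel=1e-9)

    def test_unbalanced_layout_rejected(self):
        table = balanced_table(np.zeros((16, 4))).iloc[:-1]
        with pytest.raises(UnbalancedDesignError):
            estimate_components(table, "y")
        doubled = pd.concat([balanced_table(np.ones((4, 4)))] * 2)
        with pytest.raises(UnbalancedDesignError):
            estimate_components(doubled, "y")

    def test_single_block_rejected(self):
        with pytest.raises(
            (InsufficientReplicationError, UnbalancedDesignError)
        ):
            estimate_components(balanced_table(np.zeros((16, 1))), "y")


class TestRepeatabilityProfile:
    def test_h2_non_decreasing_with_plot_size(self, rng):
        # residual variance inversely proportional to rows_per_plot
        frames = []
        g_eff = rng.normal(0, 1.0, 16)
        for rpp in (1, 2, 3, 4):
            y = g_eff[:, None] + rng.normal(0, np.sqrt(2.0 / rpp), (16, 4))
            df = balanced_table(y)
            df["rows_per_plot"] = rpp
            frames.append(df)
        prof = repeatability_profile(pd.concat(frames), "y")
        prof = prof.sort_values("rows_per_plot")
        # averaged over enough genotypes the trend holds; allow tiny noise
        assert prof["h2"].iloc[-1] > prof["h2"].iloc[0]
        assert prof.shape[0] == 4

    def test_absent_trait_warns_and_returns_empty(self):
        with pytest.warns(UserWarning, match="absent"):
            out = repeatability_profile(balanced_table(np.zeros((4, 4))), "nope")
        assert out.empty

    def test_single_stratum(self, rng):
        prof = repeatability_profile(balanced_table(rng.normal(size=(16, 4))), "y")
        assert len(prof) == 1


class TestCorrelate:
    def test_perfect_line(self):
        r, p, code = correlate([0, 1, 2, 3, 4], [1, 3, 5, 7, 9])
        assert r == pytest.approx(1.0)
        assert code == "***"

    def test_hand_computed_zero_correlation(self):
        # sum((x-xbar)(y-ybar)) = 0 for these three pairs
        r, _, code = correlate([0, 1, 2], [0, 1, 0])
        assert r == pytest.approx(0.0, abs=1e-12)

    def test_matches_brute_force_formula(self, rng):
        for _ in range(25):
            x = rng.normal(size=int(rng.integers(3, 30)))
            y = rng.normal(size=x.size)
            r, _, _ = correlate(x, y)
            manual = float(
                ((x - x.mean()) * (y - y.mean())).sum()
                / np.sqrt(((x - x.mean()) ** 2).sum() * ((y - y.mean()) ** 2).sum())
            )
            assert r == pytest.approx(manual, abs=1e-12)

    def test_null_type_one_error_rate(self, rng):
        hits = 0
        for _ in range(200):
            x = rng.normal(size=50)
            y = rng.normal(size=50)
            _, _, code = correlate(x, y)
            hits += code != "ns"
        assert hits <= 20  # 'ns' in >= 90% of null replicates

    def test_zero_variance_rejected(self):
        with pytest.raises(UndefinedCorrelationError):
            correlate([1.0, 1.0, 1.0], [0.0, 1.0, 2.0])

    def test_too_few_pairs_rejected(self):
        with pytest.raises(UndefinedCorrelationError):
            correlate([1.0, 2.0], [0.0, 1.0])

    def test_significance_codes(self):
        assert significance_code(0.0005) == "***"
        assert significance_code(0.005) == "**"
        assert significance_code(0.03) == "*"
        assert significance_code(0.2) == "ns"


class TestHsd:
    def test_null_familywise_error_controlled(self, rng):
        false_positives = 0
        for _ in range(200):
            df = simulate_balanced_trait(16, 4, 0.0, 1.0, rng)
            res = hsd_compare(df, "y")
            # any pair declared different = some genotype missing a shared letter
            letters = res["letters"].tolist()
            if not all(set(a) & set(b) for a in letters for b in letters):
                false_positives += 1
        assert false_positives / 200 <= 0.10  # nominal 5%, binomial slack

    def test_large_separation_declared_different(self, rng):
        y = np.vstack(
            [rng.normal(0.0, 1.0, (1, 4)), rng.normal(10.0, 1.0, (1, 4))]
        )
        res = hsd_compare(balanced_table(y), "y")
        a, b = res["letters"]
        assert not set(a) & set(b)

    def test_noiseless_distinct_means_all_different(self):
        y = np.tile(np.array([1.0, 2.0, 3.0])[:, None], (1, 4))
        res = hsd_compare(balanced_table(y), "y")
        assert res.attrs["hsd"] == 0.0
        letters = res["letters"].tolist()
        assert len({frozenset(l) for l in letters}) == 3

    def test_single_block_rejected(self):
        with pytest.raises(
            (InsufficientReplicationError, UnbalancedDesignError)
        ):
            hsd_compare(balanced_table(np.zeros((16, 1))), "y")
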