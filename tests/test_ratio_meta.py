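"""Random-effects pooling of per-run ratios and the differential call."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fluidmark.ratio_meta import (
    PooledRatio,
    RatioObservation,
    build_differential_table,
    call_differential,
    pool_all,
    pool_ratios,
    read_observations_tsv,
    variance_from_peptides,
    write_observations_tsv,
)


def obs(ratio, var, run="r1", protein="P1", comparison="M/N"):
    return RatioObservation(protein, comparison, run, ratio, var)


def dl_oracle(y, v):
    """Brute-force DerSimonian–Laird pooling on the log2 scale.

    Independent transcription of the textbook formulas: fixed-effect weights
    1/v, Cochran's Q, tau2 = max(0, (Q - df) / c), then re-weighted mean and
    normal CI. Kept free of any package code.
    """
    y, v = list(y), list(v)
    w = [1.0 / vi for vi in v]
    theta_f = sum(wi * yi for wi, yi in zip(w, y)) / sum(w)
    q = sum(wi * (yi - theta_f) ** 2 for wi, yi in zip(w, y))
    c = sum(w) - sum(wi * wi for wi in w) / sum(w)
    tau2 = max(0.0, (q - (len(y) - 1)) / c)
    w_re = [1.0 / (vi + tau2) for vi in v]
    theta = sum(wi * yi for wi, yi in zip(w_re, y)) / sum(w_re)
    se = 1.0 / math.sqrt(sum(w_re))
    z = 1.959963984540054
    return theta, tau2, (theta - z * se, theta + z * se)


class TestPooling:
    def test_single_observation_hand_computed(self):
        # y = 1, se = 0.5 -> CI on log2 scale (0.02, 1.98)
        p = pool_ratios([obs(2.0, 0.25)])
        assert p.pooled_ratio == pytest.approx(2.0)
        assert p.ci_low == pytest.approx(2 ** (1 - 1.959963984540054 * 0.5), rel=1e-9)
        assert p.ci_high == pytest.approx(2 ** (1 + 1.959963984540054 * 0.5), rel=1e-9)
        assert p.significant and p.direction == "up"

    def test_symmetric_pair_pools_to_one(self):
        p = pool_ratios([obs(2.0, 0.1, "r1"), obs(0.5, 0.1, "r2")])
        assert p.pooled_ratio == pytest.approx(1.0)
        assert not p.significant and p.direction == "none"

    @pytest.mark.parametrize("k", [2, 4, 9])
    def test_identical_observations_shrink_ci_by_sqrt_k(self, k):
        single = pool_ratios([obs(1.5, 0.09)], method="fixed")
        many = pool_ratios([obs(1.5, 0.09, f"r{i}") for i in range(k)], method="fixed")
        assert many.pooled_ratio == pytest.approx(1.5)
        width1 = math.log2(single.ci_high) - math.log2(single.ci_low)
        widthk = math.log2(many.ci_high) - math.log2(many.ci_low)
        assert widthk == pytest.approx(width1 / math.sqrt(k), rel=1e-12)

    def test_heterogeneous_pair_matches_dl_oracle(self):
        y, v = [1.0, 0.0], [0.04, 0.04]
        p = pool_ratios([obs(2.0 ** y[0], v[0], "r1"), obs(2.0 ** y[1], v[1], "r2")])
        theta, tau2, (lo, hi) = dl_oracle(y, v)
        assert math.log2(p.pooled_ratio) == pytest.approx(theta, abs=1e-10)
        assert p.tau2 == pytest.approx(tau2, abs=1e-10)
        assert math.log2(p.ci_low) == pytest.approx(lo, abs=1e-10)
        assert math.log2(p.ci_high) == pytest.approx(hi, abs=1e-10)

    def test_matches_dl_oracle_on_random_small_inputs(self, rng):
        for _ in range(50):
            k = int(rng.integers(2, 6))
            y = rng.normal(0, 1, k)
            v = rng.uniform(0.01, 0.5, k)
            p = pool_ratios([obs(2.0 ** yi, vi, f"r{i}") for i, (yi, vi) in enumerate(zip(y, v))])
            theta, tau2, (lo, hi) = dl_oracle(y, v)
            assert math.log2(p.pooled_ratio) == pytest.approx(theta, abs=1e-10)
            assert p.tau2 == pytest.approx(tau2, abs=1e-10)
            assert math.log2(p.ci_low) == pytest.approx(lo, abs=1e-10)
            assert math.log2(p.ci_high) == pytest.approx(hi, abs=1e-10)

    def test_matches_statsmodels_combine_effects(self, rng):
        from statsmodels.stats.meta_analysis import combine_effects

        y = rng.normal(0, 1, 5)
        v = rng.uniform(0.02, 0.3, 5)
        p = pool_ratios([obs(2.0 ** yi, vi, f"r{i}") for i, (yi, vi) in enumerate(zip(y, v))])
        res = combine_effects(y, v, method_re="dl")
        row = res.summary_frame().loc["random effect"]
        assert p.tau2 == pytest.approx(res.tau2, abs=1e-10)
        assert math.log2(p.pooled_ratio) == pytest.approx(row["eff"], abs=1e-10)
        assert math.log2(p.ci_low) == pytest.approx(row["ci_low"], abs=1e-8)

    def test_fixed_effect_estimate_within_observed_range(self, rng):
        y = rng.normal(0, 1, 6)
        v = rng.uniform(0.01, 1.0, 6)
        p = pool_ratios([obs(2.0 ** yi, vi, f"r{i}") for i, (yi, vi) in enumerate(zip(y, v))],
                        method="fixed")
        assert y.min() - 1e-12 <= math.log2(p.pooled_ratio) <= y.max() + 1e-12

    def test_order_and_run_label_invariance(self):
        a = [obs(1.4, 0.05, "r1"), obs(0.9, 0.2, "r2"), obs(2.2, 0.1, "r3")]
        b = [obs(2.2, 0.1, "x"), obs(1.4, 0.05, "y"), obs(0.9, 0.2, "z")]
        pa, pb = pool_ratios(a), pool_ratios(b)
        assert pa.pooled_ratio == pytest.approx(pb.pooled_ratio, rel=1e-14)
        assert (pa.ci_low, pa.ci_high) == (pytest.approx(pb.ci_low), pytest.approx(pb.ci_high))

    @settings(deadline=None, max_examples=40, derandomize=True)
    @given(st.lists(st.tuples(st.floats(0.1, 10), st.floats(0.01, 1)), min_size=1, max_size=6))
    def test_reciprocal_symmetry(self, pairs):
        fwd = pool_ratios([obs(r, v, f"r{i}") for i, (r, v) in enumerate(pairs)])
        rev = pool_ratios([obs(1.0 / r, v, f"r{i}") for i, (r, v) in enumerate(pairs)])
        assert fwd.pooled_ratio == pytest.approx(1.0 / rev.pooled_ratio, rel=1e-9)
        assert fwd.ci_low == pytest.approx(1.0 / rev.ci_high, rel=1e-9)
        assert fwd.significant == rev.significant

    def test_weights_normalized(self):
        p = pool_ratios([obs(1.2, 0.1, "r1"), obs(1.5, 0.3, "r2")])
        assert sum(p.weights.values()) == pytest.approx(1.0)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            pool_ratios([])

    def test_mixed_proteins_rejected(self):
        with pytest.raises(ValueError):
            pool_ratios([obs(1.0, 0.1, protein="A"), obs(1.0, 0.1, protein="B")])

    def test_nonpositive_inputs_rejected(self):
        with pytest.raises(ValueError):
            RatioObservation("P", "M/N", "r1", -1.0, 0.1)
        with pytest.raises(ValueError):
            RatioObservation("P", "M/N", "r1", 1.0, 0.0)


class TestDifferentialCall:
    @pytest.mark.parametrize("lo,hi,expected", [
        ((1.1), 2.0, (True, "up")),
        (0.9, 1.2, (False, "none")),
        (0.3, 0.8, (True, "down")),
    ])
    def test_ci_rule(self, lo, hi, expected):
        p = PooledRatio("P", "M/N", math.sqrt(lo * hi), lo, hi, 0.0, 3, {}, False, "none")
        assert call_differential(p) == expected


class TestVarianceFromPeptides:
    def test_variance_of_the_mean(self):
        x = [0.1, 0.3, 0.5]
        assert variance_from_peptides(x) == pytest.approx(np.var(x, ddof=1) / 3)

    def test_single_peptide_rejected(self):
        with pytest.raises(ValueError):
            variance_from_peptides([0.2])

    def test_estimated_variance_path_pools(self, rng):
        # per-run variance estimated from replicate peptide ratios, then pooled
        runs = []
        for i in range(4):
            peptides = rng.normal(0.5, 0.3, 10)
            runs.append(obs(2.0 ** peptides.mean(), variance_from_peptides(peptides), f"r{i}"))
        p = pool_ratios(runs)
        assert 1.0 < p.pooled_ratio < 2.0


class TestBuildTable:
    def test_no_significant_gives_empty_table(self):
        pooled = [pool_ratios([obs(1.05, 0.5, "r1", protein="P1", comparison=c)])
                  for c in ("B/N", "M/N", "M/B")]
        table = build_differential_table(pooled, fluid="saliva")
        assert len(table) == 0

    def test_single_significant_comparison_kept(self):
        pooled = [
            pool_ratios([obs(1.0, 0.5, "r1", comparison="B/N")]),
            pool_ratios([obs(4.0, 0.25, "r1", comparison="M/N")]),
        ]
        table = build_differential_table(pooled, fluid="saliva")
        assert len(table) == 1
        rec = table.records[0]
        assert rec.significant == {"B/N": False, "M/N": True, "M/B": False}
        assert rec.ratio["M/B"] == 1.0  # missing comparison recorded as absent

    def test_bh_flag_is_more_conservative(self, rng):
        pooled = []
        for i in range(60):
            y = rng.normal(0, 0.35)
            pooled.append(pool_ratios([obs(2.0 ** y, 0.04, "r1", protein=f"P{i:02d}")]))
        raw = build_differential_table(pooled, "saliva")
        adj = build_differential_table(pooled, "saliva", adjust_bh=True)
        assert len(adj) <= len(raw)


class TestTsvRoundTrip:
    def test_observations_round_trip(self, tmp_path, rng):
        original = [obs(float(r), float(v), f"r{i}", protein=f"P{i % 3}")
                    for i, (r, v) in enumerate(zip(rng.uniform(0.2, 5, 9), rng.uniform(0.01, 1, 9)))]
        path = tmp_path / "obs.tsv"
        write_observations_tsv(original, path)
        back = read_observations_tsv(path)
        assert back == original

    def test_pooled_table_round_trips_through_fixture_loader(self, tmp_path):
        from fluidmark import fixtures as fx

        pooled = [pool_ratios([obs(4.0, 0.25, "r1", protein="PX", comparison=c)])
                  for c in ("B/N", "M/N", "M/B")]
        table = build_differential_table(pooled, fluid="saliva")
        p = tmp_path / "dt.csv"
        table.write_csv(p)
        again = fx.load_differential_table(p, "saliva")
        assert len(again) == len(table) == 1
        assert again.records[0].significant["B/N"]
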