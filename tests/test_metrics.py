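"""Evaluation statistics against independent naive-loop oracles."""

import math

import numpy as np
import pytest

from actimpute import (
    MissingMask,
    MvpaConfig,
    RecordSet,
    compute_report,
    iv_index,
    mvpa_minutes,
    partial_mae,
    partial_rmse,
    record_sd,
    rmse_of_aggregate,
)

from conftest import make_record


# ---------------------------------------------------------------------------
# independent oracles: plain python triple loops, no vectorization shared
# with the implementation
# ---------------------------------------------------------------------------

def oracle_partial_rmse(x, xi, flags):
    num, den = 0.0, 0
    for i in range(len(x)):
        for j in range(len(x[i])):
            if flags[i][j]:
                num += (x[i][j] - xi[i][j]) ** 2
                den += 1
    return math.sqrt(num / den)


def oracle_partial_mae(x, xi, flags):
    num, den = 0.0, 0
    for i in range(len(x)):
        for j in range(len(x[i])):
            if flags[i][j]:
                num += abs(x[i][j] - xi[i][j])
                den += 1
    return num / den


def oracle_sd(values):
    n = len(values)
    mean = sum(values) / n
    return math.sqrt(sum((v - mean) ** 2 for v in values) / (n - 1))


def oracle_iv(values):
    n = len(values)
    mean = sum(values) / n
    num = sum((values[j] - values[j - 1]) ** 2 for j in range(1, n))
    den = sum((v - mean) ** 2 for v in values)
    return n * num / ((n - 1) * den)


def oracle_mvpa(values, cutoff, bout_len=10, fraction=0.8):
    total, t = 0, 0
    while t <= len(values) - bout_len:
        window = values[t : t + bout_len]
        if sum(1 for v in window if v > cutoff) >= fraction * bout_len:
            total += bout_len
            t += bout_len
        else:
            t += 1
    return total


def _random_instance(rng, m=5, n=40):
    x = rng.integers(0, 2000, size=(m, n)).astype(float)
    xi = np.maximum(x + rng.normal(0, 300, size=(m, n)), 0.0)
    flags = np.zeros((m, n), dtype=bool)
    for i in range(m):
        start = rng.integers(0, n - 8)
        flags[i, start : start + 8] = True
    return x, xi, flags


def _as_sets(x, xi, flags):
    origin = RecordSet([make_record(row, subject=f"S{i}") for i, row in enumerate(x)])
    imputed = RecordSet([make_record(row, subject=f"S{i}") for i, row in enumerate(xi)])
    masks = [MissingMask(f) for f in flags]
    return origin, imputed, masks


class TestPartialErrorMetrics:
    def test_perfect_imputation_zero(self, rng):
        x, _, flags = _random_instance(rng)
        origin, _, masks = _as_sets(x, x, flags)
        assert partial_rmse(origin, origin, masks) == 0.0
        assert partial_mae(origin, origin, masks) == 0.0

    def test_single_cell_error(self):
        x = np.zeros((1, 20))
        xi = x.copy()
        xi[0, 5] = 7.0
        flags = np.zeros((1, 20), bool)
        flags[0, 5] = True
        origin, imputed, masks = _as_sets(x, xi, flags)
        assert partial_rmse(origin, imputed, masks) == pytest.approx(7.0)
        assert partial_mae(origin, imputed, masks) == pytest.approx(7.0)

    def test_mae_of_mixed_signs(self):
        x = np.zeros((1, 10))
        xi = x.copy()
        xi[0, 0], xi[0, 1] = 3.0, 1.0
        flags = np.zeros((1, 10), bool)
        flags[0, :2] = True
        origin, imputed, masks = _as_sets(x, xi, flags)
        assert partial_mae(origin, imputed, masks) == pytest.approx(2.0)

    def test_invariant_to_unmasked_cells(self, rng):
        x, xi, flags = _random_instance(rng)
        origin, imputed, masks = _as_sets(x, xi, flags)
        base = partial_rmse(origin, imputed, masks)
        xi2 = xi.copy()
        xi2[~flags] += 999.0
        _, imputed2, _ = _as_sets(x, xi2, flags)
        assert partial_rmse(origin, imputed2, masks) == base

    def test_matches_oracles_on_100_random_instances(self, rng):
        for _ in range(100):
            x, xi, flags = _random_instance(rng)
            origin, imputed, masks = _as_sets(x, xi, flags)
            r = partial_rmse(origin, imputed, masks)
            m = partial_mae(origin, imputed, masks)
            r0 = oracle_partial_rmse(x.tolist(), xi.tolist(), flags.tolist())
            m0 = oracle_partial_mae(x.tolist(), xi.tolist(), flags.tolist())
            assert abs(r - r0) <= 1e-10 * max(1.0, r0)
            assert abs(m - m0) <= 1e-10 * max(1.0, m0)

    def test_no_masked_cells_is_an_error(self):
        x = np.ones((2, 10))
        origin, imputed, masks = _as_sets(x, x, np.zeros((2, 10), bool))
        with pytest.raises(ValueError):
            partial_rmse(origin, imputed, masks)


class TestRecordSd:
    def test_constant_record(self):
        assert record_sd(np.full(10, 3.0)) == 0.0

    def test_two_point(self):
        assert record_sd(np.array([0.0, 2.0])) == pytest.approx(math.sqrt(2.0))

    def test_matches_two_pass_oracle(self, rng):
        values = rng.integers(0, 500, 100).astype(float)
        assert record_sd(values) == pytest.approx(oracle_sd(values.tolist()), rel=1e-12)


class TestIvIndex:
    def test_linear_ramp_closed_form(self):
        n = 720
        ramp = np.arange(n, dtype=float) * 3.0
        # successive differences are constant d; arithmetic-series algebra
        # gives IV = 12 / (N^2 - 1)
        assert iv_index(ramp) == pytest.approx(12.0 / (n**2 - 1), rel=1e-12)
        assert iv_index(ramp) == pytest.approx(oracle_iv(ramp.tolist()), rel=1e-12)

    def test_white_noise_iv_near_two(self, rng):
        values = rng.normal(size=10**4)
        assert iv_index(values) == pytest.approx(2.0, abs=0.1)

    def test_nonnegative_and_oracle_agreement(self, rng):
        for _ in range(20):
            values = rng.integers(0, 100, 50).astype(float)
            if np.all(values == values[0]):
                continue
            iv = iv_index(values)
            assert iv >= 0
            assert iv == pytest.approx(oracle_iv(values.tolist()), rel=1e-10)

    def test_constant_record_flagged_undefined(self):
        assert math.isnan(iv_index(np.full(10, 4.0)))


class TestMvpa:
    CFG = MvpaConfig(cutoff=1267.0)

    def test_all_below_cutoff(self):
        assert mvpa_minutes(np.zeros(60), self.CFG) == 0

    def test_exactly_ten_above(self):
        values = np.zeros(60)
        values[20:30] = 2000.0
        assert mvpa_minutes(values, self.CFG) == 10

    def test_eight_of_ten_qualifies_seven_does_not(self):
        values = np.zeros(10)
        values[:8] = 2000.0
        assert mvpa_minutes(values, self.CFG) == 10
        values[7] = 0.0  # now 7 above
        assert mvpa_minutes(values, self.CFG) == 0

    def test_strict_mode_excludes_exact_80_percent(self):
        cfg = MvpaConfig(cutoff=1267.0, strict_fraction=True)
        values = np.zeros(10)
        values[:8] = 2000.0
        assert mvpa_minutes(values, cfg) == 0

    def test_short_sequence_returns_zero(self):
        assert mvpa_minutes(np.full(5, 9999.0), self.CFG) == 0

    def test_monotone_in_added_above_cutoff_minutes(self, rng):
        values = rng.integers(0, 2500, 120).astype(float)
        base = mvpa_minutes(values, self.CFG)
        more = values.copy()
        more[values <= 1267] = 1500.0  # push everything above the cutoff
        assert mvpa_minutes(more, self.CFG) >= base

    def test_matches_oracle_on_random_sequences(self, rng):
        for _ in range(100):
            values = rng.integers(0, 2600, rng.integers(10, 80)).astype(float)
            assert mvpa_minutes(values, self.CFG) == oracle_mvpa(values.tolist(), 1267.0)

    def test_cutoff_keyed_to_axis_kind(self):
        assert MvpaConfig.for_axis("uniaxial").cutoff == 1267.0
        assert MvpaConfig.for_axis("magnitude").cutoff == 2691.0


class TestRmseOfAggregate:
    def test_identical_sets_zero(self, rng):
        x, _, flags = _random_instance(rng)
        origin, _, masks = _as_sets(x, x, flags)
        for agg in ("sd", "iv", "mvpa_missing_only"):
            assert rmse_of_aggregate(origin, origin, agg, masks=masks, cfg=self._cfg()) == 0.0

    @staticmethod
    def _cfg():
        return MvpaConfig(cutoff=1267.0)

    def test_single_record_sd_difference(self):
        a = np.array([0.0, 2.0, 4.0, 6.0])
        b = np.array([0.0, 0.0, 0.0, 6.0])
        origin, imputed, masks = _as_sets(a[None, :], b[None, :], np.ones((1, 4), bool))
        expected = abs(oracle_sd(a.tolist()) - oracle_sd(b.tolist()))
        assert rmse_of_aggregate(origin, imputed, "sd") == pytest.approx(expected, rel=1e-12)

    def test_matches_per_record_oracle(self, rng):
        x, xi, flags = _random_instance(rng, m=8, n=60)
        origin, imputed, masks = _as_sets(x, xi, flags)
        for agg, fn in (("sd", oracle_sd), ("iv", oracle_iv)):
            got = rmse_of_aggregate(origin, imputed, agg, masks=masks)
            diffs = [fn(x[i].tolist()) - fn(xi[i].tolist()) for i in range(len(x))]
            expected = math.sqrt(sum(d * d for d in diffs) / len(diffs))
            assert got == pytest.approx(expected, rel=1e-10)
        got = rmse_of_aggregate(origin, imputed, "mvpa_missing_only", masks=masks, cfg=self._cfg())
        diffs = [
            oracle_mvpa(x[i][flags[i]].tolist(), 1267.0) - oracle_mvpa(xi[i][flags[i]].tolist(), 1267.0)
            for i in range(len(x))
        ]
        expected = math.sqrt(sum(d * d for d in diffs) / len(diffs))
        assert got == pytest.approx(expected, rel=1e-10)

    def test_undefined_iv_records_are_excluded(self):
        ok = np.array([1.0, 5.0, 2.0, 8.0])
        const = np.full(4, 3.0)
        origin, imputed, _ = _as_sets(
            np.stack([ok, const]), np.stack([ok * 2, const]), np.ones((2, 4), bool)
        )
        with pytest.warns(UserWarning):
            got = rmse_of_aggregate(origin, imputed, "iv")
        expected = abs(oracle_iv(ok.tolist()) - oracle_iv((ok * 2).tolist()))
        assert got == pytest.approx(expected, rel=1e-10)


def test_compute_report_populates_all_metrics(rng):
    x, xi, flags = _random_instance(rng, m=6, n=50)
    origin, imputed, masks = _as_sets(x, xi, flags)
    report = compute_report(origin, imputed, masks)
    for value in report.to_dict().values():
        assert np.isfinite(value) and value >= 0
    assert report.sd_origin.shape == (6,)
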