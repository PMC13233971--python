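import itertools

import numpy as np
import pandas as pd
import pytest

from congrad.correspondence import (fdr_adjust, parametric_test,
                                    permutation_test, subgroup_split,
                                    voxelwise_correlation)
from congrad.errors import (ArgumentError, DimensionError,
                            UndefinedCorrelationError)
from congrad.image_io import MaskedVolume
from congrad.trend_surface import TSMCoefficients


def _tsm(slopes):
    slopes = np.asarray(slopes, dtype=float)
    return TSMCoefficients(slopes, 0.0, 1.0, slopes.size,
                           {a: (0.0, 1.0) for a in "XYZ"})


def _bh_oracle(p):
    """Definitional Benjamini-Hochberg step-up."""
    p = np.asarray(p, dtype=float)
    m = p.size
    order = np.argsort(p, kind="stable")
    q = np.empty(m)
    prev = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        val = min(prev, p[i] * m / rank)
        q[i] = val
        prev = val
    return q


class TestPermutation:
    def test_exhaustive_enumeration_matches_oracle(self, rng):
        """Full enumeration of per-coefficient shuffles of 3 templates
        reproduces a brute-force oracle exactly."""
        g = [_tsm(rng.normal(size=6))]
        templates = np.vstack([g[0].slopes + 0.05 * rng.normal(size=6),
                               rng.normal(size=6), rng.normal(size=6)])
        ts = [_tsm(row) for row in templates]
        res = permutation_test(g, ts, n_perm=1, exhaustive=True)

        def absz(u, v):
            return np.arctanh(abs(np.corrcoef(u, v)[0, 1]))

        perms = list(itertools.permutations(range(3)))
        obs = [absz(g[0].slopes, templates[ti]) for ti in range(3)]
        count = np.zeros(3, dtype=int)
        total = 0
        for combo in itertools.product(perms, repeat=6):
            total += 1
            for ti in range(3):
                null_t = np.array([templates[combo[j][ti], j]
                                   for j in range(6)])
                if absz(g[0].slopes, null_t) >= obs[ti]:
                    count[ti] += 1
        expected = (1 + count) / (1 + total)
        got = res.table.sort_values("template").p_perm.to_numpy()
        assert np.allclose(got, expected, atol=1e-12)

    def test_null_calibration(self, rng):
        """Independent gradients/templates: rejection rate at alpha=0.05
        stays inside the binomial band (small version of the full check)."""
        rej = total = 0
        for _ in range(60):
            g = [_tsm(rng.normal(size=9))]
            ts = [_tsm(rng.normal(size=9)) for _ in range(18)]
            res = permutation_test(g, ts, 500,
                                   seed=int(rng.integers(2 ** 31)))
            rej += int((res.table.p_perm < 0.05).sum())
            total += len(res.table)
        rate = rej / total
        assert 0.02 < rate < 0.09

    def test_p_bounds_and_metadata(self, rng):
        g = [_tsm(rng.normal(size=9))]
        ts = [_tsm(rng.normal(size=9)) for _ in range(4)]
        res = permutation_test(g, ts, 200, seed=5)
        assert res.n_permutations == 200
        assert res.scheme == "across"
        assert ((res.table.p_perm > 0) & (res.table.p_perm <= 1)).all()

    def test_single_template_falls_back_to_within(self, rng, caplog):
        import logging
        g = [_tsm(rng.normal(size=9))]
        with caplog.at_level(logging.WARNING):
            res = permutation_test(g, [_tsm(rng.normal(size=9))], 100, seed=1)
        assert res.scheme == "within"

    def test_template_relabeling_invariance(self, rng):
        """Across-template null is invariant to template order: the same
        seed gives identical per-pair p-values after relabeling."""
        g = [_tsm(rng.normal(size=9))]
        ts = [_tsm(rng.normal(size=9)) for _ in range(5)]
        a = permutation_test(g, ts, 400, seed=9).table
        order = [4, 2, 0, 1, 3]
        b = permutation_test(g, [ts[i] for i in order], 400, seed=9).table
        # observed statistics must map through the relabeling exactly
        for new_pos, old_pos in enumerate(order):
            assert a.loc[a.template == old_pos, "abs_z"].item() == \
                b.loc[b.template == new_pos, "abs_z"].item()

    def test_determinism_given_seed(self, rng):
        g = [_tsm(rng.normal(size=9))]
        ts = [_tsm(rng.normal(size=9)) for _ in range(6)]
        a = permutation_test(g, ts, 300, seed=123).table
        b = permutation_test(g, ts, 300, seed=123).table
        pd.testing.assert_frame_equal(a, b)


class TestParametric:
    def test_zero_correlation_gives_p_one(self, rng):
        a = rng.normal(size=9)
        b = rng.normal(size=9)
        az = a - a.mean()
        bz = b - b.mean()
        bz -= (bz @ az) / (az @ az) * az  # exactly orthogonal, demeaned
        row = parametric_test([_tsm(az)], [_tsm(bz)]).iloc[0]
        assert row.r_tsm == pytest.approx(0.0, abs=1e-12)
        assert row.p_param == pytest.approx(1.0, abs=1e-12)

    def test_closed_form_t_value(self, rng):
        """r = 0.6664 with 9 coefficients gives t = 2.364 and p ~ 0.0499."""
        from scipy import stats
        base = rng.normal(size=9)
        noise = rng.normal(size=9)
        # construct a pair with correlation very close to the target
        target = 0.6664
        zb = (base - base.mean()) / base.std()
        zn = noise - noise.mean()
        zn -= (zn @ zb) / (zb @ zb) * zb
        zn /= zn.std()
        v = target * zb + np.sqrt(1 - target ** 2) * zn
        row = parametric_test([_tsm(zb)], [_tsm(v)]).iloc[0]
        assert row.r_tsm == pytest.approx(target, abs=1e-10)
        t = target * np.sqrt(7 / (1 - target ** 2))
        assert t == pytest.approx(2.364, abs=5e-3)
        assert row.p_param == pytest.approx(2 * stats.t.sf(t, 7), abs=1e-12)
        assert row.p_param == pytest.approx(0.0499, abs=5e-3)

    def test_p_monotone_in_abs_r(self, rng):
        zb = rng.normal(size=9)
        zb = (zb - zb.mean()) / zb.std()
        zn = rng.normal(size=9)
        zn = zn - zn.mean()
        zn -= (zn @ zb) / (zb @ zb) * zb
        zn /= zn.std()
        ps = []
        for r in (0.1, 0.3, 0.5, 0.7, 0.9):
            v = r * zb + np.sqrt(1 - r ** 2) * zn
            ps.append(parametric_test([_tsm(zb)], [_tsm(v)]).iloc[0].p_param)
        assert np.all(np.diff(ps) < 0)


class TestVoxelwise:
    def _vol(self, values, mask, name=""):
        return MaskedVolume(values, mask, np.eye(4), name)

    def test_identity_and_inversion(self, rng):
        mask = rng.random((8, 8, 8)) < 0.5
        vals = rng.normal(size=int(mask.sum()))
        g = self._vol(vals, mask)
        assert voxelwise_correlation(g, g) == pytest.approx(1.0)
        assert voxelwise_correlation(
            g, self._vol(1.0 - vals, mask)) == pytest.approx(-1.0)

    def test_matches_covariance_formula(self, rng):
        mask = rng.random((8, 8, 8)) < 0.5
        a = rng.normal(size=int(mask.sum()))
        b = rng.normal(size=int(mask.sum()))
        got = voxelwise_correlation(self._vol(a, mask), self._vol(b, mask))
        expected = (np.mean(a * b) - a.mean() * b.mean()) / (a.std() * b.std())
        assert got == pytest.approx(expected, abs=1e-12)

    def test_constant_map_rejected(self, rng):
        mask = np.ones((4, 4, 4), bool)
        with pytest.raises(UndefinedCorrelationError):
            voxelwise_correlation(self._vol(np.ones(64), mask),
                                  self._vol(rng.normal(size=64), mask))

    def test_mask_mismatch_rejected(self, rng):
        m1 = np.zeros((4, 4, 4), bool)
        m1[0] = True
        m2 = np.zeros((4, 4, 4), bool)
        m2[1] = True
        with pytest.raises(DimensionError):
            voxelwise_correlation(self._vol(np.ones(16) + np.arange(16), m1),
                                  self._vol(np.arange(16.0), m2))


class TestFDR:
    def test_worked_example(self):
        q = fdr_adjust([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(q, 0.04)

    def test_single_p_unchanged(self):
        assert fdr_adjust([0.3])[0] == pytest.approx(0.3)

    def test_matches_definitional_oracle(self, rng):
        for _ in range(1000):
            p = rng.random(rng.integers(1, 40))
            assert np.allclose(fdr_adjust(p), _bh_oracle(p), atol=1e-12)

    def test_q_at_least_p(self, rng):
        p = rng.random(25)
        assert np.all(fdr_adjust(p) >= p - 1e-15)

    def test_empty_family_rejected(self):
        with pytest.raises(ArgumentError):
            fdr_adjust([])


class TestSubgroupSplit:
    def test_median_split_ties_low(self):
        t = pd.DataFrame({"subject_id": list("abcd"),
                          "motion": [0.1, 0.2, 0.3, 0.4]})
        low, high = subgroup_split(t, "motion")
        assert sorted(low.motion) == [0.1, 0.2]
        assert sorted(high.motion) == [0.3, 0.4]

    def test_boolean_partition(self):
        t = pd.DataFrame({"subject_id": list("abcdef"),
                          "medication": [0, 1, 0, 1, 1, 0]})
        low, high = subgroup_split(t, "medication", rule="boolean")
        assert len(low) == 3 and len(high) == 3
        assert (high.medication == 1).all()

    def test_small_subgroup_warns(self):
        t = pd.DataFrame({"subject_id": list("abc"),
                          "motion": [0.1, 0.2, 0.3]})
        with pytest.warns(RuntimeWarning, match="subgroup"):
            subgroup_split(t, "motion")
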