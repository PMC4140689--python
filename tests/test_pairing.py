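import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from symaxis import (
    FixtureSpec,
    KeyPoint,
    PolarPoint,
    ToleranceConfig,
    find_symmetric_pairs,
    geometric_pair_test,
    gradient_pair_test,
    make_point_constellation,
    normalize_magnitudes,
)
from symaxis.geometry import wrap_angle


def pp(r, theta):
    return PolarPoint(r=float(r), theta=float(wrap_angle(theta)))


def kp_with(mag, ori):
    return KeyPoint(
        x=0.0, y=0.0, scale=1.0, grad_magnitude=float(mag),
        grad_orientation=float(ori % 360.0),
    )


# --------------------------------------------------------------------------
# independent oracle: exhaustive enumeration + the documented greedy rule
# --------------------------------------------------------------------------


def oracle_pairs(items, alpha, tol, bin_width=10.0, min_radius=1.0):
    """Brute-force re-implementation of the pairing contract, kept separate
    from the library code on purpose."""

    def wrap(a):
        w = (a + 180.0) % 360.0 - 180.0
        return 180.0 if w == -180.0 else w

    def geo(pa, pb):
        if abs(pa.r - pb.r) > tol.theta_r:
            return False
        return abs(wrap(pa.theta + pb.theta - 2 * alpha)) <= tol.theta_theta

    def grad(ka, kb):
        if not ka.oriented or not kb.oriented:
            return False
        for ma, qa in ka.orientation_hypotheses():
            for mb, qb in kb.orientation_hypotheses():
                if abs(ma - mb) > tol.grad_mag_tol:
                    continue
                if abs(wrap(qa + qb - 2 * alpha)) / bin_width <= tol.grad_ori_tol:
                    return True
        return False

    cands = []
    for i in range(len(items)):
        pa, ka = items[i]
        if pa.r < min_radius:
            continue
        for j in range(i + 1, len(items)):
            pb, kb = items[j]
            if pb.r < min_radius:
                continue
            if geo(pa, pb) and grad(ka, kb):
                res = 0.0
                if tol.theta_r > 0:
                    res += abs(pa.r - pb.r) / tol.theta_r
                if tol.theta_theta > 0:
                    res += abs(wrap(pa.theta + pb.theta - 2 * alpha)) / tol.theta_theta
                cands.append((res, i, j))
    cands.sort()
    used, out = set(), []
    for _, i, j in cands:
        if i in used or j in used:
            continue
        used |= {i, j}
        out.append((i, j))
    return out


def pair_indices(items, pairs):
    """Map SymmetricPair endpoints back to item indices."""
    lookup = {id(p): i for i, (p, _) in enumerate(items)}
    return [tuple(sorted((lookup[id(s.a)], lookup[id(s.b)]))) for s in pairs]


class TestGeometricPairTest:
    def test_polar_axis_rule(self):
        tol = ToleranceConfig(theta_r=1.0, theta_theta=2.0)
        assert geometric_pair_test(pp(5, 30), pp(5, -30), 0.0, tol)

    def test_boundary_inclusive_at_45(self):
        tol = ToleranceConfig(theta_r=1.0, theta_theta=2.0)
        # residual 70 + 22 - 90 = 2 degrees, exactly on the band edge
        assert geometric_pair_test(pp(5, 70), pp(5, 22), 45.0, tol)

    def test_r_mismatch_fails(self):
        tol = ToleranceConfig(theta_r=1.0, theta_theta=2.0)
        assert not geometric_pair_test(pp(5, 30), pp(8, -30), 0.0, tol)

    @given(
        st.floats(0, 100), st.floats(-179.99, 180), st.floats(0, 100),
        st.floats(-179.99, 180), st.floats(0, 179.99),
    )
    @settings(max_examples=200, deadline=None)
    def test_symmetric_in_arguments(self, r1, t1, r2, t2, alpha):
        tol = ToleranceConfig(theta_r=3.0, theta_theta=5.0)
        a, b = pp(r1, t1), pp(r2, t2)
        assert geometric_pair_test(a, b, alpha, tol) == geometric_pair_test(
            b, a, alpha, tol
        )


class TestGradientPairTest:
    def test_exact_mirror_passes(self):
        tol = ToleranceConfig(theta_r=1, theta_theta=1, grad_mag_tol=5, grad_ori_tol=2)
        a, b = kp_with(10, 30), kp_with(12, 330)
        assert gradient_pair_test(a, b, 0.0, tol, bin_width=10.0)

    def test_magnitude_band_violated(self):
        tol = ToleranceConfig(theta_r=1, theta_theta=1, grad_mag_tol=5, grad_ori_tol=2)
        assert not gradient_pair_test(kp_with(0, 30), kp_with(10, 330), 0.0, tol)

    def test_orientation_bin_distance_five(self):
        # reflected Q_b = 310, circular distance to Q_a = 0 is 50 deg = 5 bins
        tol = ToleranceConfig(theta_r=1, theta_theta=1, grad_mag_tol=5, grad_ori_tol=2)
        assert not gradient_pair_test(kp_with(10, 0), kp_with(10, 50), 0.0, tol)

    def test_unoriented_rejected_without_exception(self):
        tol = ToleranceConfig(theta_r=1, theta_theta=1)
        un = KeyPoint(x=0, y=0, scale=1.0, grad_magnitude=0.0,
                      grad_orientation=0.0, unoriented=True)
        assert not gradient_pair_test(un, kp_with(10, 0), 0.0, tol)

    def test_symmetric_in_arguments(self):
        tol = ToleranceConfig(theta_r=1, theta_theta=1, grad_mag_tol=5, grad_ori_tol=2)
        a, b = kp_with(50, 123), kp_with(52, 237 + 2 * 40)
        for alpha in (0.0, 40.0, 90.0):
            assert gradient_pair_test(a, b, alpha, tol) == gradient_pair_test(
                b, a, alpha, tol
            )


def mirrored_items(alpha, n_half, seed, mag=50.0):
    rng = np.random.default_rng(seed)
    items = []
    for _ in range(n_half):
        r = rng.uniform(10, 80)
        t = rng.uniform(-180, 180)
        q = rng.uniform(0, 360)
        items.append((pp(r, t), kp_with(mag, q)))
        items.append((pp(r, 2 * alpha - t), kp_with(mag, 2 * alpha - q)))
    return items


class TestFindSymmetricPairs:
    def test_five_exact_mirrors(self):
        items = mirrored_items(30.0, 5, seed=1)
        tol = ToleranceConfig(theta_r=0.5, theta_theta=0.5)
        assert len(find_symmetric_pairs(items, 30.0, tol)) == 5

    def test_orthogonal_axis_has_no_pairs(self):
        items = mirrored_items(30.0, 5, seed=1)
        tol = ToleranceConfig(theta_r=0.5, theta_theta=2.0)
        got = find_symmetric_pairs(items, 120.0, tol)
        assert got == []
        assert oracle_pairs(items, 120.0, tol) == []

    def test_greedy_prefers_smaller_residual(self):
        # b could pair with a or c; a-b has the smaller residual and wins,
        # after which c is blocked (a-c fails the theta band anyway)
        a = (pp(5, 30), kp_with(10, 0))
        b = (pp(5, -30), kp_with(10, 0))
        c = (pp(5, -31), kp_with(10, 0))
        tol = ToleranceConfig(theta_r=1.0, theta_theta=2.0, grad_mag_tol=5,
                              grad_ori_tol=2)
        pairs = find_symmetric_pairs([a, b, c], 0.0, tol)
        assert pair_indices([a, b, c], pairs) == [(0, 1)]

    def test_near_origin_points_excluded(self):
        a = (pp(0.2, 10), kp_with(10, 0))
        b = (pp(0.2, -10), kp_with(10, 0))
        tol = ToleranceConfig(theta_r=5.0, theta_theta=30.0)
        assert find_symmetric_pairs([a, b], 0.0, tol) == []

    def test_perfect_mirror_completeness(self):
        for alpha in (0.0, 17.0, 90.0, 155.0):
            items = mirrored_items(alpha, 8, seed=int(alpha))
            tol = ToleranceConfig(theta_r=1e-6, theta_theta=1e-6)
            assert len(find_symmetric_pairs(items, alpha, tol)) == 8

    @pytest.mark.parametrize("seed", range(8))
    def test_oracle_equivalence_random_constellations(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(5, 50))
        items = []
        for _ in range(n):
            items.append(
                (pp(rng.uniform(0, 60), rng.uniform(-180, 180)),
                 kp_with(rng.uniform(0, 100), rng.uniform(0, 360)))
            )
        tol = ToleranceConfig(theta_r=4.0, theta_theta=8.0, grad_mag_tol=30,
                              grad_ori_tol=4)
        for alpha in np.arange(0, 180, 15.0):
            got = pair_indices(items, find_symmetric_pairs(items, float(alpha), tol))
            assert got == oracle_pairs(items, float(alpha), tol)

    def test_pair_level_tolerance_monotonicity(self):
        items = mirrored_items(25.0, 10, seed=3)
        small = ToleranceConfig(theta_r=0.5, theta_theta=0.5)
        large = ToleranceConfig(theta_r=2.0, theta_theta=3.0)
        ok_small = {
            (i, j)
            for i in range(len(items))
            for j in range(i + 1, len(items))
            if geometric_pair_test(items[i][0], items[j][0], 25.0, small)
        }
        ok_large = {
            (i, j)
            for i in range(len(items))
            for j in range(i + 1, len(items))
            if geometric_pair_test(items[i][0], items[j][0], 25.0, large)
        }
        assert ok_small <= ok_large


class TestNormalizeMagnitudes:
    def test_linear_maps_max_to_100(self):
        pts = [kp_with(20, 0), kp_with(50, 0)]
        out = normalize_magnitudes(pts, "linear")
        assert out[1].grad_magnitude == pytest.approx(100.0)
        assert out[0].grad_magnitude == pytest.approx(40.0)

    def test_log_maps_max_to_100_and_compresses(self):
        pts = [kp_with(20, 0), kp_with(50, 0)]
        out = normalize_magnitudes(pts, "log")
        assert out[1].grad_magnitude == pytest.approx(100.0)
        assert out[0].grad_magnitude > 40.0  # compressive

    def test_unoriented_untouched(self):
        un = KeyPoint(x=0, y=0, scale=1.0, grad_magnitude=0.0,
                      grad_orientation=0.0, unoriented=True)
        out = normalize_magnitudes([un, kp_with(10, 0)], "linear")
        assert out[0].grad_magnitude == 0.0

    def test_tolerance_config_rejects_negative(self):
        with pytest.raises(ValueError):
            ToleranceConfig(theta_r=-1.0, theta_theta=0.0)


class TestConstellationFixtures:
    def test_exact_mirror_constellation_yields_half_pairs(self):
        items, truth = make_point_constellation(
            FixtureSpec(kind="mirrored_points", seed=2, true_alpha=30.0, n_points=10)
        )
        tol = ToleranceConfig(theta_r=0.5, theta_theta=0.5)
        assert len(find_symmetric_pairs(items, 30.0, tol)) == 5
        assert truth["true_alpha"] == 30.0
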