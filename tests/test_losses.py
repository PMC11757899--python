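"""Loss family: hand-computed values, degeneracies, gradient-ratio oracles."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays
from scipy.special import expit as sigmoid

from skeltube import losses
from skeltube.losses import (
    STLParams,
    dice_loss,
    gradient_ratio_dice,
    gradient_ratio_stl,
    gradient_ratio_tversky,
    loss_curve_table,
    overall_loss,
    stl_loss,
    tversky_loss,
)

P01 = STLParams(0.1, 0.9, 10.0)
P_DEFAULT = STLParams()  # 0.01 / 0.99 / 7


def random_pair(rng, shape=(4, 4, 4)):
    p = rng.uniform(0.05, 0.95, size=shape)
    g = (rng.random(shape) < 0.3).astype(float)
    if g.sum() == 0:
        g.flat[0] = 1.0
    if g.sum() == g.size:
        g.flat[0] = 0.0
    return p, g


def finite_difference_ratio(loss_fn, p, g, h=1e-6):
    """|dL/dp_f / dL/dp_b| via central differences, for one fg/bg voxel each."""
    p = p.copy().ravel()
    gf = g.ravel()
    i_fg = int(np.flatnonzero(gf == 1)[0])
    i_bg = int(np.flatnonzero(gf == 0)[0])

    def d(i):
        p1, p2 = p.copy(), p.copy()
        p1[i] += h
        p2[i] -= h
        return (loss_fn(p1, gf) - loss_fn(p2, gf)) / (2 * h)

    return abs(d(i_fg) / d(i_bg)), float(p[i_fg])


class TestLossValues:
    def test_dice_hand_example(self):
        assert dice_loss([0.8, 0.4], [1, 0]) == pytest.approx(1 - 1.6 / 2.2, abs=1e-12)

    def test_dice_perfect_and_empty_limits(self):
        g = np.zeros((3, 3, 3))
        g[1, 1, 1] = 1
        # epsilon-clamping leaves a residue of order eps * N / sum(g)
        assert dice_loss(g, g) == pytest.approx(0.0, abs=1e-4)
        p = np.full((3, 3, 3), 0.4)
        assert dice_loss(p, np.zeros((3, 3, 3))) == pytest.approx(1.0, abs=1e-12)

    def test_tversky_hand_example(self):
        got = tversky_loss([0.8, 0.4], [1, 0], P01)
        assert got == pytest.approx(1 - 0.8 / 1.02, abs=1e-12)

    def test_tversky_perfect_binary_is_zero(self):
        g = np.zeros((4, 4, 4))
        g[:2] = 1
        for a in (0.1, 0.3, 0.7):
            assert tversky_loss(g, g, STLParams(a, 1 - a, 5.0)) == pytest.approx(0.0, abs=1e-5)

    def test_stl_hand_example(self):
        got = stl_loss([0.8, 0.4], [1, 0], P01)
        assert got == pytest.approx(1 - sigmoid(3.0) / 1.02, abs=1e-9)

    def test_stl_perfect_prediction_floor(self):
        # STL never reaches 0: perfect prediction leaves 1 - sigmoid(gamma/2)
        g = np.zeros((4, 4, 4))
        g[0] = 1
        got = stl_loss(g, g, P_DEFAULT)
        assert got == pytest.approx(1 - sigmoid(3.5), abs=1e-4)
        assert got > 0

    def test_stl_numerator_half_at_midpoint(self):
        # sigma(0) = 0.5, so the numerator is 0.5 * sum(g) for any gamma
        g = np.ones(5)
        for gamma in (1.0, 7.0, 50.0):
            prm = STLParams(0.1, 0.9, gamma)
            got = stl_loss(np.full(5, 0.5), g, prm)
            assert got == pytest.approx(1 - 2.5 / (0.1 * 2.5 + 0.9 * 5), abs=1e-9)

    def test_overall_loss_additivity(self):
        rng = np.random.default_rng(0)
        p, g = random_pair(rng)
        ph, gh = random_pair(rng)
        lo = overall_loss(p, g, ph, gh, P_DEFAULT, skel_weight=1.0)
        assert lo == pytest.approx(dice_loss(p, g) + stl_loss(ph, gh, P_DEFAULT), abs=1e-12)
        assert overall_loss(p, g, ph, gh, P_DEFAULT, skel_weight=0.0) == pytest.approx(
            dice_loss(p, g), abs=1e-12)

    def test_degenerate_empty_pair_warns_and_returns_zero(self):
        with pytest.warns(UserWarning):
            assert dice_loss(np.zeros(0), np.zeros(0)) == 0.0

    def test_shape_mismatch_raises(self):
        with pytest.raises(ValueError):
            dice_loss(np.zeros((2, 2)), np.zeros((3, 3)))

    def test_losses_bounded(self, rng):
        for _ in range(20):
            p, g = random_pair(rng)
            for v in (dice_loss(p, g), tversky_loss(p, g, P01), stl_loss(p, g, P01)):
                assert 0.0 <= v <= 1.0


class TestPropertyInvariants:
    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(p=arrays(np.float64, (2, 3, 4),
                    elements=st.floats(1e-4, 1 - 1e-4)),
           g=arrays(np.int8, (2, 3, 4), elements=st.sampled_from([0, 1])),
           alpha=st.floats(0.05, 0.95))
    def test_loss_family_bounded_and_ordered(self, p, g, alpha):
        """All losses lie in [0, 1]; Tversky at alpha=beta=0.5 equals Dice."""
        prm = STLParams(alpha, 1 - alpha, 7.0)
        for v in (dice_loss(p, g), tversky_loss(p, g, prm),
                  stl_loss(p, g, prm)):
            assert 0.0 <= v <= 1.0
        half = STLParams(0.5, 0.5, 7.0)
        assert tversky_loss(p, g, half) == pytest.approx(dice_loss(p, g),
                                                         abs=1e-12)


class TestDegeneracies:
    def test_tversky_half_half_equals_dice(self, rng):
        prm = STLParams(0.5, 0.5, 7.0)
        for _ in range(50):
            p, g = random_pair(rng)
            assert tversky_loss(p, g, prm) == pytest.approx(dice_loss(p, g), abs=1e-12)

    def test_gradient_ratio_tversky_alpha_half_equals_dice(self):
        for l in (0.0, 0.2, 0.5, 0.9):
            assert gradient_ratio_tversky(l, 0.5) == pytest.approx(
                gradient_ratio_dice(l), abs=1e-12)


class TestGradientRatios:
    def test_dice_ratio_substitutions(self):
        assert gradient_ratio_dice(0.0) == pytest.approx(1.0)
        assert gradient_ratio_dice(0.5) == pytest.approx(3.0)

    def test_tversky_ratio_substitution(self):
        assert gradient_ratio_tversky(0.5, 0.1) == pytest.approx(19.0)

    def test_dice_ratio_monotone_in_loss(self):
        grid = np.linspace(0.0, 0.95, 40)
        vals = [gradient_ratio_dice(l) for l in grid]
        assert np.all(np.diff(vals) > 0)

    def test_stl_ratio_peaks_at_half(self):
        prm = STLParams(0.1, 0.9, 10.0)
        r_mid = gradient_ratio_stl(0.3, 0.5, prm)
        r_high = gradient_ratio_stl(0.3, 0.95, prm)
        assert r_mid > r_high

    def test_out_of_range_raises(self):
        with pytest.raises(ValueError):
            gradient_ratio_dice(1.0)
        with pytest.raises(ValueError):
            gradient_ratio_tversky(0.5, 0.0)
        with pytest.raises(ValueError):
            gradient_ratio_stl(0.5, 1.0, P01)

    @pytest.mark.parametrize("family", ["dice", "tversky", "stl"])
    def test_closed_forms_match_finite_differences(self, family, rng):
        """Eq-style closed forms agree with numeric loss gradients to 1e-5."""
        prm = STLParams(0.1, 0.9, 10.0)
        for _ in range(25):
            p, g = random_pair(rng)
            if family == "dice":
                fn = dice_loss
                expected = lambda l, pf: gradient_ratio_dice(l)
            elif family == "tversky":
                fn = lambda pp, gg: tversky_loss(pp, gg, prm)
                expected = lambda l, pf: gradient_ratio_tversky(l, prm.alpha)
            else:
                fn = lambda pp, gg: stl_loss(pp, gg, prm)
                expected = lambda l, pf: gradient_ratio_stl(l, pf, prm)
            got, p_f = finite_difference_ratio(fn, p, g)
            assert got == pytest.approx(expected(fn(p, g), p_f), rel=1e-5)


class TestAnalyticGradients:
    """The trainer's closed-form dL/dp helpers vs central differences."""

    @pytest.mark.parametrize("name", ["dice", "tversky", "stl"])
    def test_grad_matches_fd(self, name, rng):
        prm = STLParams(0.3, 0.7, 7.0)
        fns = {
            "dice": (lambda p, g: dice_loss(p, g),
                     lambda p, g: losses.dice_loss_grad(p, g)),
            "tversky": (lambda p, g: tversky_loss(p, g, prm),
                        lambda p, g: losses.tversky_loss_grad(p, g, prm)),
            "stl": (lambda p, g: stl_loss(p, g, prm),
                    lambda p, g: losses.stl_loss_grad(p, g, prm)),
        }
        fn, gradfn = fns[name]
        p, g = random_pair(rng, shape=(3, 3, 3))
        analytic = gradfn(p, g).ravel()
        h = 1e-6
        for i in range(0, p.size, 5):
            p1, p2 = p.ravel().copy(), p.ravel().copy()
            p1[i] += h
            p2[i] -= h
            fd = (fn(p1, g.ravel()) - fn(p2, g.ravel())) / (2 * h)
            assert analytic[i] == pytest.approx(fd, rel=1e-4, abs=1e-9)


class TestLossCurves:
    def test_all_curves_non_increasing_on_default_grid(self):
        prm = STLParams(0.1, 0.9, 10.0)
        for fam in ("dice", "tversky", "stl"):
            tab = loss_curve_table(fam, prm)
            assert np.all(np.diff(tab[:, 1]) <= 1e-12)

    def test_stl_steeper_than_tversky_at_half(self):
        # the sigmoid reweighting concentrates slope at p = 0.5
        prm = STLParams(0.1, 0.9, 10.0)
        grid = [0.45, 0.5, 0.55]
        t = loss_curve_table("tversky", prm, grid=grid)[:, 1]
        s = loss_curve_table("stl", prm, grid=grid)[:, 1]
        slope_t = abs((t[2] - t[0]) / 0.1)
        slope_s = abs((s[2] - s[0]) / 0.1)
        assert slope_s > slope_t

    def test_empty_or_invalid_grid_raises(self):
        with pytest.raises(ValueError):
            loss_curve_table("dice", P01, grid=[])
        with pytest.raises(ValueError):
            loss_curve_table("dice", P01, grid=[0.0, 0.5])
        with pytest.raises(ValueError):
            loss_curve_table("focal", P01)


class TestSTLParams:
    def test_alpha_beta_must_sum_to_one(self):
        with pytest.raises(ValueError):
            STLParams(0.3, 0.6, 7.0)
        with pytest.raises(ValueError):
            STLParams(0.5, 0.5, -1.0)
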