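import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

from nmrtopo import pre_restraints as pr
from nmrtopo import synthetic_data as sd
from nmrtopo.io_formats import PeakPair, ResidueId, SpinLabelSite


def _pair(i_para, i_dia, sigma=0.0, idx=10):
    return PeakPair(ResidueId(idx, "A"), i_para, i_dia, sigma)


# ---------------------------------------------------------------------------
# intensity ratios
# ---------------------------------------------------------------------------

def test_equal_intensities_give_unit_ratio():
    ratio, err = pr.intensity_ratio(_pair(2.0, 2.0))
    assert ratio == 1.0 and err == 0.0


def test_vanished_peak_gives_zero_ratio():
    ratio, _ = pr.intensity_ratio(_pair(0.0, 1.0))
    assert ratio == 0.0


def test_negative_intensity_is_clamped_with_warning(caplog):
    with caplog.at_level("WARNING"):
        ratio, _ = pr.intensity_ratio(_pair(-0.3, 1.0))
    assert ratio == 0.0
    assert any("clamped" in r.message for r in caplog.records)


def test_uncertainty_matches_first_order_propagation():
    # independent sigma on both peaks: err = (sigma/I_dia) * sqrt(1 + ratio^2)
    ratio, err = pr.intensity_ratio(_pair(50.0, 100.0, sigma=5.0))
    assert ratio == pytest.approx(0.5)
    assert err == pytest.approx((5.0 / 100.0) * math.sqrt(1 + 0.25))


# ---------------------------------------------------------------------------
# ratio -> R2sp inversion
# ---------------------------------------------------------------------------

def _bisection_oracle(ratio, r2_dia, t_inept, lo=0.0, hi=1e6, tol=1e-10):
    f = lambda r: r2_dia * math.exp(-r * t_inept) / (r2_dia + r) - ratio
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if f(mid) > 0:
            lo = mid
        else:
            hi = mid
        if hi - lo < tol * max(1.0, mid):
            break
    return 0.5 * (lo + hi)


def test_r2sp_matches_independent_bisection():
    got = pr.ratio_to_r2sp(0.5, r2_dia=20.0, t_inept=0.010)
    expected = _bisection_oracle(0.5, 20.0, 0.010)
    assert got == pytest.approx(expected, rel=1e-8)


def test_ratio_near_one_gives_vanishing_r2sp():
    assert pr.ratio_to_r2sp(0.999999, 20.0, 0.010) < 1e-3


@pytest.mark.parametrize("bad", [0.0, 1.0, 1.5, -0.1])
def test_out_of_range_ratios_are_rejected(bad):
    with pytest.raises(ValueError):
        pr.ratio_to_r2sp(bad, 20.0, 0.010)


def test_forward_inverse_round_trip_over_grid():
    """Any R2sp in [1, 200] s^-1 is recovered to 1e-6 relative through the
    intensity-ratio relation and back."""
    r2_dia, t = 20.0, 0.010
    for r2sp in np.linspace(1.0, 200.0, 64):
        ratio = r2_dia * math.exp(-r2sp * t) / (r2_dia + r2sp)
        back = pr.ratio_to_r2sp(ratio, r2_dia, t)
        assert back == pytest.approx(r2sp, rel=1e-6)


# ---------------------------------------------------------------------------
# R2sp -> distance
# ---------------------------------------------------------------------------

def test_distance_is_monotone_decreasing_in_r2sp():
    ds = [pr.r2sp_to_distance(r, 15e-9, 2 * math.pi * 800e6) for r in (1, 5, 20, 100)]
    assert ds == sorted(ds, reverse=True)


def test_k_const_scaling_law():
    base = pr.r2sp_to_distance(20.0, 15e-9, 2 * math.pi * 800e6, k_const=1e16)
    doubled = pr.r2sp_to_distance(20.0, 15e-9, 2 * math.pi * 800e6, k_const=2e16)
    assert doubled == pytest.approx(base * 2 ** (1 / 6))


def test_distance_matches_direct_evaluation():
    r2sp, tau, omega, k = 20.0, 15e-9, 2 * math.pi * 800e6, pr.DEFAULT_K_CONST
    expected = (k / r2sp * (4 * tau + 3 * tau / (1 + omega**2 * tau**2))) ** (1 / 6)
    assert pr.r2sp_to_distance(r2sp, tau, omega, k) == pytest.approx(expected, rel=1e-12)


@given(st.floats(min_value=5.0, max_value=40.0))
def test_distance_round_trip_through_forward_rate(d):
    params = pr.PREParams()
    r2sp = pr.r2sp_from_distance(d, params)
    assert pr.r2sp_to_distance(r2sp, params.tau_c, params.omega_h,
                               params.k_const) == pytest.approx(d, rel=1e-9)


# ---------------------------------------------------------------------------
# restraint building
# ---------------------------------------------------------------------------

def _measurements(ratios, site_idx=89, params=pr.PREParams()):
    site = SpinLabelSite(ResidueId(site_idx, "M"))
    pairs = [_pair(r, 1.0, idx=i) for i, r in enumerate(ratios, start=1)]
    return pr.classify_pairs(pairs, site, params), site


def test_ratio_above_cutoff_is_unrestrained():
    meas, _ = _measurements([0.90])
    restraints, report = pr.build_restraints(meas)
    assert restraints[0].klass == "unrestrained"
    assert restraints[0].d is None


def test_vanished_ratio_gives_upper_only():
    meas, _ = _measurements([0.0])
    restraints, _ = pr.build_restraints(meas)
    assert restraints[0].klass == "upper_only"
    params = pr.PREParams()
    assert restraints[0].upper == pytest.approx(
        pr.ratio_to_distance(params.vanish_cutoff, params))


def test_label_site_residue_is_excluded(caplog):
    site = SpinLabelSite(ResidueId(2, "M"))
    pairs = [_pair(0.5, 1.0, idx=1), _pair(0.5, 1.0, idx=2)]
    meas = pr.classify_pairs(pairs, site, pr.PREParams())
    with caplog.at_level("INFO"):
        restraints, report = pr.build_restraints(meas)
    assert len(restraints) == 1
    assert report.counts["excluded"] == 1


def test_class_counts_partition_the_input():
    ratios = [0.0, 0.05, 0.3, 0.5, 0.7, 0.86, 0.95, 1.2]
    meas, _ = _measurements(ratios)
    restraints, report = pr.build_restraints(meas)
    assert report.total() == len(ratios)
    assert report.n_input == len(ratios)


def test_bounded_interval_contains_its_own_inversion():
    params = pr.PREParams()
    meas, _ = _measurements([0.2, 0.4, 0.6, 0.8], params=params)
    restraints, _ = pr.build_restraints(meas, params)
    for m, r in zip(meas, restraints):
        assert r.klass == "bounded"
        d = pr.ratio_to_distance(m.ratio, params)
        assert r.lower <= d <= r.upper


def test_noise_free_simulation_recovers_distances_within_bounds(study_truth, pre_params):
    """Closed loop: forward-simulated peak pairs invert to restraints whose
    bounds bracket the true label-amide distances for every bounded entry,
    and distances decrease monotonically with true distance."""
    site = study_truth.label_sites[0]
    pairs = sd.simulate_pre(study_truth, site, pre_params, 0.0, seed=3)
    restraints, _ = pr.build_restraints(
        pr.classify_pairs(pairs, site, pre_params), pre_params)
    label = study_truth.structure.coords[site.residue.index]
    bounded = [(np.linalg.norm(study_truth.structure.coords[r.residue.index] - label), r)
               for r in restraints if r.klass == "bounded"]
    assert bounded
    for d_true, r in bounded:
        assert r.lower <= d_true <= r.upper
    bounded.sort(key=lambda t: t[0])
    ds = [r.d for _, r in bounded]
    assert all(a <= b + 1e-9 for a, b in zip(ds, ds[1:]))
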