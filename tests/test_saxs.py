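"""SAXS theory and analysis: Debye, Guinier, P(r)/IFT, chi, V_r."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ccpo import saxs as sx
from ccpo.saxs import (
    SAXSProfile, ProfileError, read_profile, write_profile, debye_intensity,
    guinier_rg, pr_from_model, ift, chi_fit, volatility_ratio, vr_matrix,
)
from ccpo.synth import NoiseSpec, gen_geometry_profile, sphere_bead_model

SPHERE_RG = math.sqrt(3.0 / 5.0) * 5.0  # uniform 5 nm sphere


@pytest.fixture(scope="module")
def sphere_profile():
    prof, _ = gen_geometry_profile("sphere", np.linspace(0.05, 4.0, 500),
                                   radius=5.0)
    return prof.with_sigma()


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def test_read_profile_with_header_and_units(tmp_path):
    path = tmp_path / "p.dat"
    path.write_text("# comment line\nSample description\n"
                    "0.010 100.0 1.0\n0.100 50.0 0.5\n0.500 10.0 0.2\n"
                    "0.800 5.0 0.1\n")
    prof = read_profile(path)
    # q_max < 1 -> interpreted as A^-1 and converted
    assert prof.q[-1] == pytest.approx(8.0)
    prof_nm = read_profile(path, units="nm")
    assert prof_nm.q[-1] == pytest.approx(0.8)


def test_write_read_round_trip(tmp_path, sphere_profile):
    path = tmp_path / "sphere.dat"
    write_profile(sphere_profile, path)
    back = read_profile(path, units="nm")
    assert np.allclose(back.q, sphere_profile.q)
    assert np.allclose(back.intensity, sphere_profile.intensity)
    assert np.allclose(back.sigma, sphere_profile.sigma)


def test_missing_sigma_synthesised(tmp_path):
    path = tmp_path / "two_col.dat"
    path.write_text("1.0 10.0\n2.0 5.0\n3.0 1.0\n")
    prof = read_profile(path)
    assert prof.sigma_synthesised
    assert np.allclose(prof.sigma, 0.02 * prof.intensity)


def test_profile_validation_errors():
    with pytest.raises(ProfileError, match="increasing"):
        SAXSProfile(q=[1.0, 1.0, 2.0], intensity=[1, 1, 1])
    with pytest.raises(ProfileError, match="sigma"):
        SAXSProfile(q=[1.0, 2.0], intensity=[1, 1], sigma=[1.0, -1.0])


# ---------------------------------------------------------------------------
# Debye scattering
# ---------------------------------------------------------------------------

def test_debye_two_bead_closed_form():
    d_nm = 2.0
    beads = np.array([[0.0, 0, 0], [0, 0, 20.0]])  # 20 A apart
    q = np.array([0.3, 0.9, 1.7])
    prof = debye_intensity(beads, q, form_factor=1.5, bin_width_nm=1e-4)
    expect = 1.5 ** 2 * 2 * (1 + np.sin(q * d_nm) / (q * d_nm))
    assert np.allclose(prof.intensity, expect, rtol=1e-3)


def test_debye_forward_intensity_conserved(dense_sphere_beads):
    q = np.linspace(1e-4, 1.0, 50)
    prof = debye_intensity(dense_sphere_beads, q)
    n = len(dense_sphere_beads)
    assert prof.intensity[0] == pytest.approx(n ** 2, rel=1e-3)
    assert np.all(prof.intensity > 0)


def test_guinier_of_debye_sphere_within_2_percent(dense_sphere_beads):
    q = np.linspace(0.02, 1.5, 300)
    prof = debye_intensity(dense_sphere_beads, q)
    fit = guinier_rg(prof.with_sigma())
    assert fit.rg == pytest.approx(SPHERE_RG, rel=0.02)
    assert fit.qmax_rg <= 1.3 + 1e-9


# ---------------------------------------------------------------------------
# Guinier
# ---------------------------------------------------------------------------

def test_guinier_on_analytic_sphere(sphere_profile):
    fit = guinier_rg(sphere_profile)
    assert fit.rg == pytest.approx(SPHERE_RG, rel=0.02)
    assert fit.i0 == pytest.approx(1.0, rel=0.05)


def test_guinier_recovery_bias_under_noise():
    q = np.linspace(0.05, 2.0, 300)
    rgs = []
    for seed in range(100):
        prof, _ = gen_geometry_profile(
            "sphere", q, radius=5.0,
            noise=NoiseSpec(relative_sd=0.02, seed=seed))
        prof = sx.SAXSProfile(q=prof.q, intensity=np.abs(prof.intensity),
                              sigma=prof.sigma)
        rgs.append(guinier_rg(prof).rg)
    bias = abs(np.mean(rgs) - SPHERE_RG) / SPHERE_RG
    assert bias < 0.02


def test_guinier_rejects_rising_profile():
    q = np.linspace(0.05, 1.0, 50)
    prof = SAXSProfile(q=q, intensity=np.exp(+q ** 2)).with_sigma()
    with pytest.raises(ProfileError):
        guinier_rg(prof)


# ---------------------------------------------------------------------------
# P(r)
# ---------------------------------------------------------------------------

def test_pr_two_beads():
    beads = np.array([[0.0, 0, 0], [0, 0, 30.0]])  # 3 nm
    pr = pr_from_model(beads, bin_width=0.1)
    assert pr.dmax == pytest.approx(3.0)
    occupied = pr.r[pr.p > 0]
    assert len(occupied) == 1 and occupied[0] == pytest.approx(2.95, abs=0.1)


def test_pr_rg_matches_coordinates(dense_sphere_beads):
    pr = pr_from_model(dense_sphere_beads, bin_width=0.05)
    x = dense_sphere_beads / 10.0
    rg_coord = np.sqrt(((x - x.mean(0)) ** 2).sum(1).mean())
    assert pr.rg == pytest.approx(rg_coord, abs=0.05)


def test_pr_sphere_peak_position(dense_sphere_beads):
    pr = pr_from_model(dense_sphere_beads, bin_width=0.1)
    peak_r = pr.r[np.argmax(pr.p)]
    assert peak_r == pytest.approx(0.525 * pr.dmax, rel=0.1)


# ---------------------------------------------------------------------------
# IFT
# ---------------------------------------------------------------------------

def test_ift_recovers_sphere_dmax_and_rg():
    prof, _ = gen_geometry_profile(
        "sphere", np.linspace(0.05, 3.0, 300), radius=5.0,
        noise=NoiseSpec(relative_sd=0.01, seed=3))
    pr = ift(prof, np.arange(7.0, 15.5, 0.5))
    assert pr.dmax == pytest.approx(10.0, abs=0.5)
    assert pr.rg == pytest.approx(SPHERE_RG, rel=0.02)
    assert np.all(pr.p >= 0)
    assert pr.p[0] == 0 and pr.p[-1] == 0


def test_ift_residual_small_on_clean_fixture():
    prof, _ = gen_geometry_profile(
        "shell", np.linspace(0.05, 3.0, 250), r_outer=5.0, r_inner=3.5,
        noise=NoiseSpec(relative_sd=0.005, seed=5))
    from ccpo.saxs import _ift_single
    chi, pr = _ift_single(prof.with_sigma(), 10.0, 60, None)
    assert chi <= 1.5
    assert pr.dmax == 10.0


def test_ift_empty_scan_raises(sphere_profile):
    with pytest.raises(ProfileError):
        ift(sphere_profile, [])


# ---------------------------------------------------------------------------
# chi fit
# ---------------------------------------------------------------------------

def test_chi_exact_scaling(sphere_profile):
    doubled = SAXSProfile(q=sphere_profile.q,
                          intensity=2.0 * sphere_profile.intensity,
                          sigma=sphere_profile.sigma)
    fit = chi_fit(sphere_profile, doubled)
    assert fit.scale == pytest.approx(2.0, rel=1e-6)
    assert fit.chi == pytest.approx(0.0, abs=1e-6)


def test_chi_of_pure_noise_is_one():
    rng = np.random.default_rng(42)
    q = np.linspace(0.05, 2.0, 500)
    base = np.exp(-q ** 2)
    sigma = 0.05 * base
    noisy = SAXSProfile(q=q, intensity=base + rng.normal(size=500) * sigma,
                        sigma=sigma)
    model = SAXSProfile(q=q, intensity=base)
    assert chi_fit(model, noisy).chi == pytest.approx(1.0, abs=0.1)


def test_chi_invariant_under_joint_rescaling(sphere_profile):
    rng = np.random.default_rng(1)
    noisy = SAXSProfile(
        q=sphere_profile.q,
        intensity=sphere_profile.intensity *
        (1 + 0.03 * rng.normal(size=len(sphere_profile))),
        sigma=0.03 * sphere_profile.intensity)
    model = SAXSProfile(q=sphere_profile.q,
                        intensity=sphere_profile.intensity)
    chi1 = chi_fit(model, noisy).chi
    scaled = SAXSProfile(q=noisy.q, intensity=7.0 * noisy.intensity,
                         sigma=7.0 * noisy.sigma)
    chi2 = chi_fit(model, scaled).chi
    assert chi1 == pytest.approx(chi2, rel=1e-9)


def test_chi_invariant_under_model_grid_refinement(sphere_profile):
    coarse, _ = gen_geometry_profile("sphere", np.linspace(0.04, 4.0, 150),
                                     radius=4.0)
    fine, _ = gen_geometry_profile("sphere", np.linspace(0.04, 4.0, 1200),
                                   radius=4.0)
    c1 = chi_fit(coarse, sphere_profile).chi
    c2 = chi_fit(fine, sphere_profile).chi
    assert c1 == pytest.approx(c2, abs=1e-3 * max(c1, 1.0))


# ---------------------------------------------------------------------------
# volatility ratio
# ---------------------------------------------------------------------------

def test_vr_of_scaled_copy_is_zero(sphere_profile):
    scaled = SAXSProfile(q=sphere_profile.q,
                         intensity=13.7 * sphere_profile.intensity)
    assert volatility_ratio(sphere_profile, sphere_profile).value \
        == pytest.approx(0.0, abs=1e-12)
    assert volatility_ratio(sphere_profile, scaled).value \
        == pytest.approx(0.0, abs=1e-9)


@settings(max_examples=25, deadline=None)
@given(st.integers(0, 10_000), st.floats(0.1, 10.0))
def test_vr_symmetry_and_scale_invariance(seed, scale):
    rng = np.random.default_rng(seed)
    q = np.linspace(0.1, 2.0, 120)
    ia = np.exp(rng.normal(size=len(q)) * 0.3) * np.exp(-q)
    ib = np.exp(rng.normal(size=len(q)) * 0.3) * np.exp(-q)
    a = SAXSProfile(q=q, intensity=ia)
    b = SAXSProfile(q=q, intensity=ib)
    v_ab = volatility_ratio(a, b).value
    v_ba = volatility_ratio(b, a).value
    assert v_ab == pytest.approx(v_ba, abs=1e-9)
    b_scaled = SAXSProfile(q=q, intensity=scale * ib)
    assert volatility_ratio(a, b_scaled).value == pytest.approx(v_ab, rel=1e-9)


def test_vr_bins_match_pi_over_d():
    prof, _ = gen_geometry_profile("sphere", np.linspace(0.1, 2.0, 400),
                                   radius=5.0)
    res = volatility_ratio(prof, prof)
    widths = np.diff(res.bin_edges)
    assert widths[0] == pytest.approx(math.pi / 40.0, rel=1e-9)
    # 17 full bins plus a partial final bin over 0.15-1.5 nm^-1
    assert len(res.bin_edges) - 1 == 18


def test_vr_orders_shape_perturbations():
    # bodies small enough that no scattering minimum (where the ratio
    # statistic diverges) falls inside the 0.15-1.5 nm^-1 window
    q = np.linspace(0.05, 2.0, 300)
    sphere, _ = gen_geometry_profile("sphere", q, radius=2.0)
    tiny, _ = gen_geometry_profile("sphere", q, radius=2.05)
    perturbed, _ = gen_geometry_profile("sphere", q, radius=2.2)
    rod, _ = gen_geometry_profile("rod", q, length=8.0)
    v_tiny = volatility_ratio(sphere, tiny).value
    v_small = volatility_ratio(sphere, perturbed).value
    v_large = volatility_ratio(sphere, rod).value
    assert 0 < v_tiny < v_small < v_large


def test_vr_matrix_properties(sphere_profile):
    q = np.linspace(0.05, 2.0, 300)
    rod, _ = gen_geometry_profile("rod", q, length=12.0)
    shell, _ = gen_geometry_profile("shell", q, r_outer=5.0, r_inner=3.0)
    mat = vr_matrix([sphere_profile, rod, shell])
    assert np.allclose(mat, mat.T, atol=1e-9)
    assert np.allclose(np.diag(mat), 0.0)
    same = vr_matrix([sphere_profile] * 3)
    assert np.allclose(same, 0.0, atol=1e-9)


def test_vr_grid_refinement_invariance():
    coarse, _ = gen_geometry_profile("sphere", np.linspace(0.05, 2.0, 200),
                                     radius=4.0)
    fine, _ = gen_geometry_profile("sphere", np.linspace(0.05, 2.0, 1600),
                                   radius=4.0)
    ref, _ = gen_geometry_profile("sphere", np.linspace(0.05, 2.0, 200),
                                  radius=4.5)
    v1 = volatility_ratio(ref, coarse).value
    v2 = volatility_ratio(ref, fine).value
    assert v1 == pytest.approx(v2, abs=1e-2 * v1)


def test_vr_rejects_nonpositive_intensity(sphere_profile):
    bad = SAXSProfile(q=np.linspace(0.1, 2.0, 50),
                      intensity=np.linspace(1.0, -0.5, 50))
    with pytest.raises(ProfileError):
        volatility_ratio(sphere_profile, bad)
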