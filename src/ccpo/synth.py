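"""Seeded synthetic-data generators for every analysis input class.

Each generator is a pure function of its parameters and seed, so the
fixtures used throughout the test-suite (and any file written from
them) regenerate bit-identically from their manifest.  The generators
emulate the measurement protocols behind the analyses:

* SAXS profiles of analytic bodies (sphere, spherical shell, thin rod)
  with heteroscedastic Gaussian noise (relative + floor), σ column set
  to the applied noise level;
* CD melting curves from the same forward equilibrium model the fitter
  uses (1 °C-spaced scan grids mirror a 1 °C/min thermal ramp);
* 1:1 ITC titrations with displacement-dilution bookkeeping
  (VP-ITC-like: 1.4 ml cell, ~µM analyte, ~10 µl injections);
* donor/acceptor emission spectra as Gaussian bands coupled by an
  energy-transfer efficiency.

What these fixtures deliberately do *not* model: instrument baselines
and buffer-subtraction artefacts, SAXS inter-particle effects,
aggregation, or photobleaching.  The noise model is Gaussian throughout.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np

from .saxs import SAXSProfile
from .thermo import (MeltingCurve, ITCSeries, EmissionSpectrum,
                     melting_signal, itc_forward_heats)

__all__ = [
    "NoiseSpec", "FixtureManifest", "gen_geometry_profile",
    "gen_melting_curve", "gen_itc_series", "gen_fret_spectra",
    "sphere_bead_model",
]


@dataclass(frozen=True)
class NoiseSpec:
    """Gaussian noise: sd = relative_sd · |signal| + floor."""

    relative_sd: float = 0.0
    floor: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.relative_sd < 0 or self.floor < 0:
            raise ValueError("noise magnitudes must be non-negative")

    def sd(self, signal: np.ndarray) -> np.ndarray:
        return self.relative_sd * np.abs(signal) + self.floor

    def apply(self, signal: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        rng = np.random.default_rng(self.seed)
        sd = self.sd(signal)
        return signal + rng.normal(size=len(signal)) * sd, sd


@dataclass(frozen=True)
class FixtureManifest:
    """Provenance of one generated fixture; regeneration is bit-identical."""

    generator: str
    parameters: dict
    seed: int
    outputs: tuple[str, ...] = ()

    def to_json(self) -> str:
        return json.dumps(asdict(self), sort_keys=True, default=str)


# ---------------------------------------------------------------------------
# SAXS geometry profiles
# ---------------------------------------------------------------------------

def _sphere_ff(q: np.ndarray, radius: float) -> np.ndarray:
    x = q * radius
    with np.errstate(invalid="ignore", divide="ignore"):
        f = 3.0 * (np.sin(x) - x * np.cos(x)) / x ** 3
    return np.where(x == 0, 1.0, f)


def _shell_ff(q: np.ndarray, r_outer: float, r_inner: float) -> np.ndarray:
    vo, vi = r_outer ** 3, r_inner ** 3
    return (vo * _sphere_ff(q, r_outer) - vi * _sphere_ff(q, r_inner)) / (vo - vi)


def _rod_intensity(q: np.ndarray, length: float) -> np.ndarray:
    from scipy.special import sici
    x = q * length
    si, _ = sici(x)
    with np.errstate(invalid="ignore", divide="ignore"):
        i = 2.0 * si / x - 4.0 * np.sin(x / 2.0) ** 2 / x ** 2
    return np.where(x == 0, 1.0, i)


def gen_geometry_profile(shape: str, q_grid: np.ndarray,
                         noise: NoiseSpec | None = None,
                         i0: float = 1.0,
                         **size) -> tuple[SAXSProfile, FixtureManifest]:
    """Analytic SAXS profile of a geometric body (q in nm⁻¹, sizes in nm).

    Shapes: ``sphere`` (radius), ``shell`` (r_outer, r_inner),
    ``rod`` (length; infinitely-thin limit).
    """
    q = np.asarray(q_grid, dtype=float)
    if shape == "sphere":
        radius = float(size["radius"])
        if radius <= 0:
            raise ValueError("radius must be positive")
        ideal = i0 * _sphere_ff(q, radius) ** 2
    elif shape == "shell":
        ro, ri = float(size["r_outer"]), float(size["r_inner"])
        if not 0 <= ri < ro:
            raise ValueError("need 0 <= r_inner < r_outer")
        ideal = i0 * _shell_ff(q, ro, ri) ** 2
    elif shape == "rod":
        length = float(size["length"])
        if length <= 0:
            raise ValueError("length must be positive")
        ideal = i0 * _rod_intensity(q, length)
    else:
        raise ValueError(f"unsupported shape {shape!r}")
    noise = noise or NoiseSpec()
    noisy, sd = noise.apply(ideal)
    sd = np.where(sd > 0, sd, np.abs(ideal) * 1e-6 + 1e-12)
    prof = SAXSProfile(q=q, intensity=noisy, sigma=sd, label=f"{shape}")
    man = FixtureManifest("gen_geometry_profile",
                          {"shape": shape, "i0": i0, **size,
                           "noise": asdict(noise)}, noise.seed)
    return prof, man


def sphere_bead_model(radius_nm: float, n_beads: int,
                      seed: int = 0) -> np.ndarray:
    """Uniform random bead filling of a sphere (coords in Å) — the
    standard oracle body for Debye/Guinier checks."""
    rng = np.random.default_rng(seed)
    out = []
    r_a = radius_nm * 10.0
    while len(out) < n_beads:
        x = rng.uniform(-r_a, r_a, size=(n_beads, 3))
        keep = x[np.linalg.norm(x, axis=1) <= r_a]
        out.extend(keep.tolist())
    return np.array(out[:n_beads])


# ---------------------------------------------------------------------------
# Melting curves
# ---------------------------------------------------------------------------

def gen_melting_curve(model: str, tms_c: Sequence[float],
                      dhs_kj: Sequence[float],
                      t_grid: np.ndarray | None = None,
                      bn: tuple[float, float] = (-25000.0, 0.0),
                      bd: tuple[float, float] = (-2000.0, 0.0),
                      s_i: float = 0.5,
                      noise: NoiseSpec | None = None,
                      ) -> tuple[MeltingCurve, FixtureManifest]:
    """Synthetic CD melting curve from the forward equilibrium model.

    Default grid is 5–92 °C at 1 °C spacing (a 1 °C/min scan read every
    minute); default baselines are a folded MRE₂₂₂ of −25,000 and an
    unfolded value of −2,000 deg cm² dmol⁻¹, flat in temperature.
    Noise sd scales with the native-to-denatured signal span.
    """
    t = (np.arange(5.0, 93.0, 1.0) if t_grid is None
         else np.asarray(t_grid, dtype=float))
    ideal = melting_signal(t, model, list(tms_c), list(dhs_kj), bn, bd, s_i)
    noise = noise or NoiseSpec()
    span = abs(bd[0] - bn[0])
    rng = np.random.default_rng(noise.seed)
    sd = noise.relative_sd * span + noise.floor
    signal = ideal + rng.normal(size=len(t)) * sd
    curve = MeltingCurve(temperature=t, signal=signal, label=model)
    man = FixtureManifest("gen_melting_curve",
                          {"model": model, "tms_c": list(tms_c),
                           "dhs_kj": list(dhs_kj), "bn": bn, "bd": bd,
                           "s_i": s_i, "noise": asdict(noise)}, noise.seed)
    return curve, man


# ---------------------------------------------------------------------------
# ITC titrations
# ---------------------------------------------------------------------------

def gen_itc_series(kd_nM: float, dh_kcal: float, n: float = 1.0,
                   cell_conc_uM: float = 1.0, syringe_conc_uM: float = 10.0,
                   n_injections: int = 28, injection_ul: float = 10.0,
                   first_injection_ul: float = 2.0,
                   cell_volume_ml: float = 1.4,
                   offset_ucal: float = 0.0,
                   noise: NoiseSpec | None = None,
                   ) -> tuple[ITCSeries, FixtureManifest]:
    """Synthetic 1:1 titration (VP-ITC-like defaults; ~28 × 10 µl
    injections of ~10 µM titrant into a 1.4 ml cell of ~1 µM analyte,
    with the customary small first injection).  Noise sd scales with
    the largest ideal injection heat."""
    vols = np.full(n_injections, injection_ul, dtype=float)
    vols[0] = first_injection_ul
    base = ITCSeries(injection_volumes_ul=vols,
                     heats_ucal=np.zeros(n_injections),
                     cell_volume_ml=cell_volume_ml,
                     syringe_conc_uM=syringe_conc_uM,
                     cell_conc_uM=cell_conc_uM)
    ideal = itc_forward_heats(base, n=n, kd_nM=kd_nM, dh_kcal=dh_kcal,
                              offset_ucal=offset_ucal)
    noise = noise or NoiseSpec()
    sd = noise.relative_sd * float(np.abs(ideal).max()) + noise.floor
    rng = np.random.default_rng(noise.seed)
    heats = ideal + rng.normal(size=n_injections) * sd
    series = ITCSeries(injection_volumes_ul=vols, heats_ucal=heats,
                       cell_volume_ml=cell_volume_ml,
                       syringe_conc_uM=syringe_conc_uM,
                       cell_conc_uM=cell_conc_uM)
    man = FixtureManifest("gen_itc_series",
                          {"kd_nM": kd_nM, "dh_kcal": dh_kcal, "n": n,
                           "cell_conc_uM": cell_conc_uM,
                           "syringe_conc_uM": syringe_conc_uM,
                           "n_injections": n_injections,
                           "injection_ul": injection_ul,
                           "first_injection_ul": first_injection_ul,
                           "cell_volume_ml": cell_volume_ml,
                           "offset_ucal": offset_ucal,
                           "noise": asdict(noise)}, noise.seed)
    return series, man


# ---------------------------------------------------------------------------
# FRET emission spectra
# ---------------------------------------------------------------------------

def gen_fret_spectra(efficiency: float,
                     donor_peak: tuple[float, float, float] = (566.0, 22.0, 1.0),
                     acceptor_peak: tuple[float, float, float] = (668.0, 26.0, 0.9),
                     bleed_through: float = 0.05,
                     grid: np.ndarray | None = None,
                     noise: NoiseSpec | None = None,
                     ) -> tuple[EmissionSpectrum, FixtureManifest]:
    """Donor/acceptor emission as Gaussian bands coupled by FRET.

    Donor amplitude is scaled by (1 − E); acceptor emission is its
    sensitised amplitude E·A plus a donor-independent bleed-through
    fraction (direct acceptor excitation).  Peaks are (centre nm,
    width nm, amplitude).  The default 548–800 nm grid matches a
    528 nm-excitation read-out.
    """
    if not 0.0 <= efficiency <= 1.0:
        raise ValueError("efficiency must be in [0, 1]")
    wl = (np.arange(548.0, 801.0, 2.0) if grid is None
          else np.asarray(grid, dtype=float))
    dc, dw, da = donor_peak
    ac, aw, aa = acceptor_peak
    donor = da * (1.0 - efficiency) * np.exp(-0.5 * ((wl - dc) / dw) ** 2)
    acceptor = aa * (efficiency + bleed_through) * np.exp(
        -0.5 * ((wl - ac) / aw) ** 2)
    ideal = donor + acceptor
    noise = noise or NoiseSpec()
    noisy, _ = noise.apply(ideal)
    spec = EmissionSpectrum(wavelength=wl, intensity=noisy,
                            label=f"fret_E{efficiency:g}")
    man = FixtureManifest("gen_fret_spectra",
                          {"efficiency": efficiency, "donor_peak": donor_peak,
                           "acceptor_peak": acceptor_peak,
                           "bleed_through": bleed_through,
                           "noise": asdict(noise)}, noise.seed)
    return spec, man
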