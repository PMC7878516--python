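"""CD helicity, thermal-melting fits, 1:1 ITC fits and the FRET ratio.

The non-SAXS solution biophysics used to characterise CCPO cages:

* fractional helicity from the mean residue ellipticity at 222 nm,
  α(%) = 100 · MRE₂₂₂ / (MRE∞ · (1 − 2.57/n)) with MRE∞ = −39,500
  deg cm² dmol⁻¹ for an infinitely long helix;
* equilibrium thermal denaturation, two-state (N ⇌ D) or sequential
  three-state (N ⇌ I ⇌ D), with van 't Hoff transitions
  ΔG = ΔH (1 − T/Tm) and linear folded/unfolded baselines;
* a 1:1 dissociation model for ITC titrations with per-injection
  displacement dilution bookkeeping;
* the acceptor/donor emission ratio F(668 nm)/F(566 nm) used to track
  cage assembly by FRET.

Temperatures are handled in kelvin internally and reported in °C.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import lmfit

__all__ = [
    "MeltingCurve", "MeltingFit", "ITCSeries", "ITCFit", "EmissionSpectrum",
    "helical_content", "mre_from_ellipticity", "fit_melting", "fit_itc",
    "fret_ratio", "itc_forward_heats", "melting_signal",
    "MRE_HELIX_INF", "FitError",
]

R_GAS = 8.314462618e-3       # kJ mol^-1 K^-1
MRE_HELIX_INF = -39500.0     # deg cm^2 dmol^-1, infinite helix at 222 nm
KELVIN = 273.15

DONOR_WAVELENGTH = 566.0     # nm (sulfo-Cy3 emission read-out)
ACCEPTOR_WAVELENGTH = 668.0  # nm (sulfo-Cy5 emission read-out)


class FitError(RuntimeError):
    """Non-convergent or ill-posed fit."""


# ---------------------------------------------------------------------------
# CD helicity
# ---------------------------------------------------------------------------

def helical_content(mre222: float, n: int) -> float:
    """Percent helicity from MRE at 222 nm for an n-residue chain.

    α = 100 · MRE₂₂₂ / (MRE∞ · (1 − 2.57/n)).  The chain-length factor
    corrects the infinite-helix reference for end effects.  Values are
    reported as computed — slightly above 100% or below 0% is possible
    with noisy data and is not clamped.
    """
    if n <= 3:
        raise ValueError("helicity correction needs n > 3 residues")
    return 100.0 * mre222 / (MRE_HELIX_INF * (1.0 - 2.57 / n))


def mre_from_ellipticity(theta_mdeg: float, conc_molar: float,
                         path_cm: float, n_residues: int) -> float:
    """Mean residue ellipticity (deg cm² dmol⁻¹) from raw ellipticity.

    MRE = θ(mdeg) / (10 · c(M) · l(cm) · n); the per-residue divisor is
    the full residue count n (toggle by passing ``n_residues - 1`` for
    the peptide-bond convention).
    """
    denom = 10.0 * conc_molar * path_cm * n_residues
    if denom == 0:
        raise ValueError("zero denominator in MRE conversion")
    return theta_mdeg / denom


# ---------------------------------------------------------------------------
# Thermal melting
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MeltingCurve:
    """CD melting data: temperature (°C) vs signal (MRE at 222 nm)."""

    temperature: np.ndarray
    signal: np.ndarray
    label: str = ""

    def __post_init__(self):
        t = np.asarray(self.temperature, dtype=float)
        y = np.asarray(self.signal, dtype=float)
        if len(t) != len(y):
            raise ValueError("temperature/signal length mismatch")
        if len(t) < 10:
            raise ValueError("melting curve needs at least 10 points")
        if np.any(np.diff(t) <= 0):
            raise ValueError("temperatures must be increasing")
        object.__setattr__(self, "temperature", t)
        object.__setattr__(self, "signal", y)


@dataclass(frozen=True)
class MeltingFit:
    model: str                       # "two_state" | "three_state"
    tm: tuple[float, ...]            # °C, one per transition
    tm_sd: tuple[float, ...]
    dh: tuple[float, ...]            # kJ/mol
    dh_sd: tuple[float, ...]
    baselines: dict
    rss: float
    tm_in_range: bool
    params: dict = field(default_factory=dict)


def _equilibrium_constants(t_k, dh, tm_k):
    dg = dh * (1.0 - t_k / tm_k)     # kJ/mol, van 't Hoff with ΔCp = 0
    return np.exp(-dg / (R_GAS * t_k))


def melting_signal(t_c: np.ndarray, model: str, tms_c: Sequence[float],
                   dhs: Sequence[float], bn: tuple[float, float],
                   bd: tuple[float, float], s_i: float = 0.5) -> np.ndarray:
    """Forward equilibrium melting signal (shared with the generator).

    ``bn``/``bd`` are (intercept, slope) of the native and denatured
    baselines in the measured signal unit vs °C; ``s_i`` places the
    intermediate's signal as a fraction between the two baselines.
    """
    t_c = np.asarray(t_c, dtype=float)
    t_k = t_c + KELVIN
    y_n = bn[0] + bn[1] * t_c
    y_d = bd[0] + bd[1] * t_c
    if model == "two_state":
        k = _equilibrium_constants(t_k, dhs[0], tms_c[0] + KELVIN)
        f_d = k / (1.0 + k)
        return y_n * (1 - f_d) + y_d * f_d
    if model == "three_state":
        k1 = _equilibrium_constants(t_k, dhs[0], tms_c[0] + KELVIN)
        k2 = _equilibrium_constants(t_k, dhs[1], tms_c[1] + KELVIN)
        f_n = 1.0 / (1.0 + k1 + k1 * k2)
        f_i = k1 * f_n
        f_d = k1 * k2 * f_n
        y_i = y_n + s_i * (y_d - y_n)
        return f_n * y_n + f_i * y_i + f_d * y_d
    raise ValueError(f"unknown melting model {model!r}")


def _transition_guesses(curve: MeltingCurve, n: int) -> list[float]:
    t, y = curve.temperature, curve.signal
    dy = np.abs(np.gradient(y, t))
    if len(dy) > 7:
        kern = np.ones(5) / 5
        dy = np.convolve(dy, kern, mode="same")
    order = np.argsort(dy)[::-1]
    picks: list[float] = []
    for idx in order:
        if all(abs(t[idx] - p) > 8.0 for p in picks):
            picks.append(float(t[idx]))
        if len(picks) == n:
            break
    while len(picks) < n:
        picks.append(float(np.median(t)))
    return sorted(picks)


def fit_melting(curve: MeltingCurve, model: str = "two_state",
                init_strategy: str = "auto", seed: int = 0,
                n_starts: int = 8) -> MeltingFit:
    """Least-squares equilibrium fit of a melting curve.

    Seeded multi-start initialisation (gradient-based Tm guesses plus
    random perturbations) guards against local minima; parameter
    uncertainties come from the covariance of the best run.
    """
    n_trans = {"two_state": 1, "three_state": 2}.get(model)
    if n_trans is None:
        raise ValueError(f"unknown melting model {model!r}")
    t, y = curve.temperature, curve.signal
    span = float(y.max() - y.min())
    if span == 0:
        raise FitError("flat curve: no visible transition")
    rng = np.random.default_rng(seed)
    guesses = (_transition_guesses(curve, n_trans) if init_strategy == "auto"
               else list(np.linspace(t.min() + 5, t.max() - 5, n_trans)))

    def residual(p):
        tms = [p[f"tm{k}"].value for k in range(n_trans)]
        dhs = [p[f"dh{k}"].value for k in range(n_trans)]
        yhat = melting_signal(
            t, model, tms, dhs,
            (p["bn0"].value, p["bn1"].value),
            (p["bd0"].value, p["bd1"].value),
            s_i=p["si"].value if "si" in p else 0.5)
        return yhat - y

    best = None
    for start in range(n_starts):
        p = lmfit.Parameters()
        for k in range(n_trans):
            tm0 = guesses[k] + (0.0 if start == 0 else rng.normal(scale=4.0))
            tm0 = float(np.clip(tm0, t.min() + 1, t.max() - 1))
            p.add(f"tm{k}", value=tm0, min=t.min() - 20, max=t.max() + 40)
            dh0 = 300.0 * (1.0 if start == 0 else
                           float(np.exp(rng.normal(scale=0.4))))
            p.add(f"dh{k}", value=dh0, min=20.0, max=3000.0)
        p.add("bn0", value=float(y[:3].mean()))
        p.add("bn1", value=0.0)
        p.add("bd0", value=float(y[-3:].mean()))
        p.add("bd1", value=0.0)
        if model == "three_state":
            p.add("si", value=0.5, min=0.0, max=1.0)
        try:
            res = lmfit.minimize(residual, p, method="leastsq")
        except Exception:
            continue
        rss = float(np.sum(res.residual ** 2))
        if best is None or rss < best[0]:
            best = (rss, res)
    if best is None:
        raise FitError("melting fit did not converge from any start")
    rss, res = best
    p = res.params
    order = np.argsort([p[f"tm{k}"].value for k in range(n_trans)])
    tms = tuple(float(p[f"tm{k}"].value) for k in order)
    tm_sds = tuple(float(p[f"tm{k}"].stderr or np.nan) for k in order)
    dhs = tuple(float(p[f"dh{k}"].value) for k in order)
    dh_sds = tuple(float(p[f"dh{k}"].stderr or np.nan) for k in order)
    in_range = all(t.min() < tm < t.max() for tm in tms)
    return MeltingFit(
        model=model, tm=tms, tm_sd=tm_sds, dh=dhs, dh_sd=dh_sds,
        baselines={"native": (p["bn0"].value, p["bn1"].value),
                   "denatured": (p["bd0"].value, p["bd1"].value)},
        rss=rss, tm_in_range=in_range,
        params={k: float(v.value) for k, v in p.items()})


# ---------------------------------------------------------------------------
# ITC
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ITCSeries:
    """One titration: per-injection volumes (µl) and integrated heats (µcal).

    ``cell_conc_uM`` is the analyte in the cell (M_t), ``syringe_conc_uM``
    the titrant (L).  ``exclude_first`` marks the customary small first
    injection whose heat is discarded before fitting.
    """

    injection_volumes_ul: np.ndarray
    heats_ucal: np.ndarray
    cell_volume_ml: float
    syringe_conc_uM: float
    cell_conc_uM: float
    exclude_first: bool = True

    def __post_init__(self):
        v = np.asarray(self.injection_volumes_ul, dtype=float)
        h = np.asarray(self.heats_ucal, dtype=float)
        if len(v) != len(h):
            raise ValueError("volumes/heats length mismatch")
        if np.any(v <= 0) or self.cell_volume_ml <= 0 \
                or self.syringe_conc_uM <= 0 or self.cell_conc_uM <= 0:
            raise ValueError("volumes and concentrations must be positive")
        object.__setattr__(self, "injection_volumes_ul", v)
        object.__setattr__(self, "heats_ucal", h)

    def molar_ratios(self) -> np.ndarray:
        """Cumulative titrant/analyte molar ratio after each injection."""
        v0 = self.cell_volume_ml * 1e-3
        f = np.cumprod(1.0 - self.injection_volumes_ul * 1e-6 / v0)
        mt = self.cell_conc_uM * f
        lt = self.syringe_conc_uM * (1.0 - f)
        return lt / mt


@dataclass(frozen=True)
class ITCFit:
    kd_nM: float
    kd_sd: float
    dh_kcal: float
    dh_sd: float
    n: float
    n_sd: float
    offset_ucal: float
    c_value: float
    c_reliable: bool
    rss: float


def itc_forward_heats(series: ITCSeries, n: float, kd_nM: float,
                      dh_kcal: float, offset_ucal: float = 0.0) -> np.ndarray:
    """Per-injection heats (µcal) of the exact 1:1 binding model.

    Bound complex from the quadratic root
    [ML] = ((nM_t + L_t + K_d) − sqrt((nM_t + L_t + K_d)² − 4 nM_t L_t))/2
    with the standard displaced-volume dilution of cell contents at each
    injection; the heat of injection i is V₀·ΔH·(ML_i − ML_{i−1}·f_i)
    plus a constant per-injection offset.
    """
    v0 = series.cell_volume_ml * 1e-3                       # L
    dv = series.injection_volumes_ul * 1e-6                 # L
    fs = 1.0 - dv / v0
    kd = kd_nM * 1e-9                                       # M
    ls = series.syringe_conc_uM * 1e-6
    m0 = series.cell_conc_uM * 1e-6
    heats = np.empty(len(dv))
    ml_prev = 0.0
    f_cum = 1.0
    for i, f in enumerate(fs):
        f_cum *= f
        mt = n * m0 * f_cum                                 # binding sites
        lt = ls * (1.0 - f_cum)
        b = mt + lt + kd
        ml = (b - math.sqrt(max(b * b - 4.0 * mt * lt, 0.0))) / 2.0
        heats[i] = v0 * dh_kcal * 1e9 * (ml - ml_prev * f) + offset_ucal
        ml_prev = ml
    return heats


def fit_itc(series: ITCSeries, seed: int = 0, n_starts: int = 6) -> ITCFit:
    """Weighted nonlinear 1:1 fit of an ITC titration.

    Free parameters: stoichiometry n, log₁₀ K_d, ΔH and a constant heat
    offset.  The first injection is excluded when the series flags it.
    The Wiseman c-value n·M_t/K_d is reported with a reliability flag
    for the customary 5–500 window (outside it the fit is returned but
    K_d is poorly constrained).
    """
    use = np.ones(len(series.heats_ucal), dtype=bool)
    if series.exclude_first:
        use[0] = False
    if np.count_nonzero(use) < 10:
        raise FitError("need at least 10 usable injections")
    y = series.heats_ucal

    def residual(p):
        kd_nM = 10.0 ** (p["log_kd"].value + 9.0)   # log_kd is log10 Kd in M
        model = itc_forward_heats(series, p["n"].value, kd_nM,
                                  p["dh"].value, p["offset"].value)
        return (model - y)[use]

    dh_guess = float(y[use][np.argmax(np.abs(y[use]))])
    v0 = series.cell_volume_ml * 1e-3
    dl = series.injection_volumes_ul.mean() * 1e-6 * series.syringe_conc_uM \
        * 1e-6 / v0
    dh_guess = dh_guess / (v0 * dl * 1e9) if dl > 0 else -10.0
    rng = np.random.default_rng(seed)
    best = None
    for start in range(n_starts):
        p = lmfit.Parameters()
        p.add("n", value=1.0 if start == 0 else
              float(np.clip(rng.normal(1.0, 0.2), 0.2, 5.0)),
              min=0.1, max=10.0)
        kd0_nM = 1.0 if start == 0 else 10.0 ** rng.uniform(-1.5, 2.5)
        p.add("log_kd", value=math.log10(kd0_nM) - 9.0, min=-13.0, max=-3.0)
        p.add("dh", value=dh_guess * (1.0 if start == 0 else
                                      float(np.exp(rng.normal(0, 0.3)))))
        p.add("offset", value=0.0)
        try:
            res = lmfit.minimize(residual, p, method="leastsq")
        except Exception:
            continue
        rss = float(np.sum(res.residual ** 2))
        if best is None or rss < best[0]:
            best = (rss, res)
    if best is None:
        raise FitError("ITC fit did not converge from any start")
    rss, res = best
    p = res.params
    kd_m = 10.0 ** p["log_kd"].value
    kd_sd = (kd_m * math.log(10) * p["log_kd"].stderr * 1e9
             if p["log_kd"].stderr else float("nan"))
    c = p["n"].value * series.cell_conc_uM * 1e-6 / kd_m
    return ITCFit(
        kd_nM=kd_m * 1e9, kd_sd=kd_sd,
        dh_kcal=float(p["dh"].value),
        dh_sd=float(p["dh"].stderr or np.nan),
        n=float(p["n"].value), n_sd=float(p["n"].stderr or np.nan),
        offset_ucal=float(p["offset"].value),
        c_value=float(c), c_reliable=bool(5.0 <= c <= 500.0),
        rss=rss)


# ---------------------------------------------------------------------------
# FRET
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class EmissionSpectrum:
    """Fluorescence emission spectrum (nm vs relative fluorescence units)."""

    wavelength: np.ndarray
    intensity: np.ndarray
    label: str = ""

    def __post_init__(self):
        w = np.asarray(self.wavelength, dtype=float)
        i = np.asarray(self.intensity, dtype=float)
        if len(w) != len(i):
            raise ValueError("wavelength/intensity length mismatch")
        object.__setattr__(self, "wavelength", w)
        object.__setattr__(self, "intensity", i)

    def at(self, wl: float) -> float:
        if not (self.wavelength.min() <= wl <= self.wavelength.max()):
            raise ValueError(f"{wl} nm outside the recorded range")
        return float(np.interp(wl, self.wavelength, self.intensity))


def fret_ratio(spectrum: EmissionSpectrum,
               acceptor_nm: float = ACCEPTOR_WAVELENGTH,
               donor_nm: float = DONOR_WAVELENGTH) -> float:
    """Acceptor/donor emission ratio F(668)/F(566) (linear interpolation)."""
    fd = spectrum.at(donor_nm)
    fa = spectrum.at(acceptor_nm)
    if fd == 0:
        raise ZeroDivisionError("donor emission is zero")
    return fa / fd
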