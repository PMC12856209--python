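"""Synthetic instrument data: two-state melting (equilibrium and kinetic) and
Gaussian-band spectra.

The generator stands in for raw spectrometer output.  It produces:

* equilibrium melting curves of a two-state folding transition of
  molecularity 1 (intramolecular), 2 (bimolecular) or 4 (tetramolecular),
  from van't Hoff thermodynamics (constant dH, dS);
* kinetic temperature-ramp curves from Arrhenius folding/unfolding rates,
  which reproduce ramp-rate-dependent hysteresis when the ramp outpaces the
  relaxation of the folding equilibrium — the behaviour shown by long
  intermolecular G4s with slow dissociation kinetics;
* CD and TDS spectra of the canonical structural classes as sums of
  Gaussian bands, and noisy two-basis mixtures at a known fraction f.

Conventions: R = 1.987 cal mol^-1 K^-1, T_K = T_C + 273.15, time in minutes
(ramp rates are degC/min), theta = fraction of strands folded (per strand,
which is what absorbance reports).  Detailed balance is enforced by deriving
the unfolding rate from the folding rate and the equilibrium constant, so
kinetic and thermodynamic descriptions can never disagree.

Default model presets mirror the qualitative regimes of WGGGW-repeat
spectroscopy — an intramolecular G4 former with no hysteresis, a bimolecular
duplex with concentration-dependent Tm, and a slow bimolecular G4 that is
hysteretic at standard ramp rates.  Their thermodynamic parameters are
fixture conventions chosen for regime matching, not measured values.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
from scipy.special import expit

from .decompose import BasisSet, calculated_spectrum
from .errors import ConfigurationError, DomainError, IntegrationError, RangeError
from .spectra import MeltingCurve, Spectrum

#: Gas constant in cal mol^-1 K^-1, the unit system of all dH/dS arithmetic.
R_CAL = 1.987

_KELVIN = 273.15


@dataclass(frozen=True)
class ArrheniusKinetics:
    """Arrhenius description of the folding (association) rate.

    ``A_fold_per_min`` has units min^-1 x M^(1-molecularity): min^-1 for
    intramolecular folding, M^-1 min^-1 for bimolecular association, and so
    on.  The unfolding rate is always derived as k_fold / K(T) (detailed
    balance), so its effective activation energy is Ea_fold - dH.
    """

    A_fold_per_min: float
    Ea_fold_kcal_mol: float


@dataclass(frozen=True)
class TwoStateModel:
    """Two-state folded/unfolded species with van't Hoff thermodynamics.

    dH < 0 and dS < 0 for the folding direction (folding is exothermic and
    ordering).  ``total_strand_conc_M`` matters only for molecularity > 1.
    Baselines are affine in temperature: value = intercept + slope * T_C.
    """

    delta_H_kcal_mol: float
    delta_S_cal_mol_K: float
    molecularity: int = 1
    total_strand_conc_M: float = 1e-6
    folded_baseline: tuple[float, float] = (0.0, 0.0)
    unfolded_baseline: tuple[float, float] = (1.0, 0.0)
    kinetics: ArrheniusKinetics | None = None

    def __post_init__(self) -> None:
        if self.molecularity not in (1, 2, 4):
            raise DomainError(f"molecularity must be 1, 2 or 4, got {self.molecularity}")
        if self.total_strand_conc_M <= 0:
            raise DomainError("total strand concentration must be positive")

    def ln_K(self, T_C: float) -> float:
        """ln of the folding equilibrium constant at T_C (mass-action units)."""
        T_K = T_C + _KELVIN
        dH = self.delta_H_kcal_mol * 1000.0
        return -dH / (R_CAL * T_K) + self.delta_S_cal_mol_K / R_CAL

    def k_fold(self, T_C: float) -> float:
        if self.kinetics is None:
            raise ConfigurationError("model has no kinetics block")
        Ea = self.kinetics.Ea_fold_kcal_mol * 1000.0
        return self.kinetics.A_fold_per_min * math.exp(-Ea / (R_CAL * (T_C + _KELVIN)))

    def k_unfold(self, T_C: float) -> float:
        """Unfolding rate from detailed balance: k_fold / K(T)."""
        if self.kinetics is None:
            raise ConfigurationError("model has no kinetics block")
        Ea = self.kinetics.Ea_fold_kcal_mol * 1000.0
        ln_kf = math.log(self.kinetics.A_fold_per_min) - Ea / (R_CAL * (T_C + _KELVIN))
        return math.exp(ln_kf - self.ln_K(T_C))


@dataclass(frozen=True)
class RampProtocol:
    """Linear temperature ramp sampled at a fixed temperature interval."""

    start_C: float
    end_C: float
    rate_C_per_min: float
    sample_interval_C: float = 0.5

    def __post_init__(self) -> None:
        if abs(self.start_C - self.end_C) < 10:
            raise DomainError("ramp must span at least 10 degC")
        if self.rate_C_per_min <= 0:
            raise DomainError("ramp rate must be positive")
        if not 0 < self.sample_interval_C <= 1:
            raise DomainError("sample interval must be in (0, 1] degC")

    @property
    def direction(self) -> str:
        return "cooling" if self.end_C < self.start_C else "heating"

    def temperatures(self) -> np.ndarray:
        span = self.end_C - self.start_C
        n = int(round(abs(span) / self.sample_interval_C)) + 1
        return self.start_C + np.sign(span) * self.sample_interval_C * np.arange(n)


@dataclass(frozen=True)
class BandModel:
    """Spectrum as a sum of Gaussian bands (center, width = sd, amplitude)."""

    bands: tuple[tuple[float, float, float], ...]
    grid: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "grid", np.asarray(self.grid, dtype=float))
        if any(w <= 0 for _, w, _ in self.bands):
            raise DomainError("band widths must be positive")
        if not np.all(np.diff(self.grid) > 0):
            raise DomainError("grid must be ascending")

    def evaluate(self) -> np.ndarray:
        out = np.zeros_like(self.grid)
        for center, width, amp in self.bands:
            out += amp * np.exp(-((self.grid - center) ** 2) / (2.0 * width**2))
        return out


_DEFAULT_GRID = np.arange(220.0, 336.0, 1.0)

#: Gaussian-band presets for the canonical spectral classes.  Band centers
#: follow the field's fingerprints: parallel G4 CD +264/-245 nm,
#: antiparallel G4 CD +295/-265 nm, the noncanonical homopurine duplex CD
#: +280/-258 nm, and the G4 TDS +243/+273/-295 nm.  Narrow (6 nm sd) bands
#: keep each extremum at its nominal center on a 1 nm grid.
BAND_PRESETS: dict[str, BandModel] = {
    "parallel_G4_CD": BandModel(((264.0, 6.0, 10.0), (245.0, 6.0, -4.0)), _DEFAULT_GRID),
    "antiparallel_G4_CD": BandModel(((295.0, 6.0, 4.0), (265.0, 6.0, -3.0)), _DEFAULT_GRID),
    "non_G4_duplex_CD": BandModel(((280.0, 6.0, 4.0), (258.0, 6.0, -5.0)), _DEFAULT_GRID),
    "G4_TDS": BandModel(
        ((243.0, 6.0, 0.04), (273.0, 6.0, 0.06), (295.0, 6.0, -0.05)), _DEFAULT_GRID
    ),
}


def _tm_K(model: TwoStateModel) -> tuple[float, float]:
    """(Tm in K, ln K at the midpoint) — helpers for the closed forms."""
    C = model.total_strand_conc_M
    if model.molecularity == 1:
        ln_Km = 0.0
    elif model.molecularity == 2:
        # 2S = D, theta = 0.5: K = theta / (2 C (1-theta)^2) = 1/C
        ln_Km = -math.log(C)
    else:
        # 4S = Q, theta = 0.5: K = theta / (4 C^3 (1-theta)^4) = 2/C^3
        ln_Km = math.log(2.0) - 3.0 * math.log(C)
    dH = model.delta_H_kcal_mol * 1000.0
    denom = model.delta_S_cal_mol_K - R_CAL * ln_Km
    if denom == 0.0 or dH == 0.0:
        raise DomainError("degenerate thermodynamics: no finite melting point")
    return dH / denom, ln_Km


def predict_tm(model: TwoStateModel) -> float:
    """Closed-form melting temperature (theta = 0.5), in degC.

    molecularity 1: Tm_K = dH/dS; molecularity m > 1 from K(Tm) equal to the
    midpoint mass-action value, e.g. K(Tm) = 1/C_T for a bimolecular duplex,
    which makes intermolecular Tm increase with strand concentration.  If
    the root falls outside [0, 110] degC a warning is issued and the nearer
    boundary returned.
    """
    tm_K, _ = _tm_K(model)
    tm_C = tm_K - _KELVIN
    if not 0.0 <= tm_C <= 110.0:
        import warnings

        clamped = min(max(tm_C, 0.0), 110.0)
        warnings.warn(
            f"predicted Tm {tm_C:.1f} degC outside [0, 110]; returning {clamped:.1f}",
            stacklevel=2,
        )
        return clamped
    return tm_C


def equilibrium_fraction_folded(model: TwoStateModel, T_C: float) -> float:
    """Fraction of strands folded at temperature T_C under mass action.

    molecularity 1: theta = K/(1+K).  molecularity 2 (2S = D):
    K = theta / (2 C_T (1-theta)^2), solved for theta on (0, 1); the
    analogous quartic relation holds for molecularity 4.  The higher-order
    cases are solved by bisection on the monotone log-form residual to
    |dtheta| < 1e-13 (the root is unique).
    """
    if not 0.0 <= T_C <= 110.0:
        raise RangeError(f"temperature {T_C} degC outside the supported [0, 110] range")
    ln_K = model.ln_K(T_C)
    if model.molecularity == 1:
        return float(expit(ln_K))
    C = model.total_strand_conc_M
    if model.molecularity == 2:
        # residual g(theta) = ln theta - ln(2C) - 2 ln(1-theta) - ln K, increasing
        const = math.log(2.0 * C) + ln_K
        power = 2.0
    else:
        const = math.log(4.0 * C**3) + ln_K
        power = 4.0

    def g(theta: float) -> float:
        return math.log(theta) - power * math.log1p(-theta) - const

    lo, hi = 1e-300, 1.0 - 1e-16
    if g(hi) < 0.0:  # numerically fully folded
        return 1.0
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if g(mid) < 0.0:
            lo = mid
        else:
            hi = mid
        if hi - lo < 1e-13:
            break
    return 0.5 * (lo + hi)


def _baseline(coefs: tuple[float, float], T_C: np.ndarray) -> np.ndarray:
    return coefs[0] + coefs[1] * T_C


def simulate_equilibrium_melt(
    model: TwoStateModel,
    protocol: RampProtocol,
    wavelength_nm: float = 295.0,
    noise_sd: float = 0.0,
    seed: int | None = None,
    sample_id: str = "sim",
) -> MeltingCurve:
    """Melting curve assuming instantaneous equilibration at every temperature.

    A(T) = theta(T) * folded_baseline(T) + (1 - theta(T)) * unfolded_baseline(T)
    plus seeded Gaussian noise.  Cooling and heating protocols over the same
    model give coincident curves (no hysteresis at equilibrium).
    """
    if noise_sd < 0:
        raise DomainError("noise_sd must be >= 0")
    temps = protocol.temperatures()
    theta = np.array([equilibrium_fraction_folded(model, float(t)) for t in temps])
    a = theta * _baseline(model.folded_baseline, temps) + (1.0 - theta) * _baseline(
        model.unfolded_baseline, temps
    )
    if noise_sd > 0:
        a = a + np.random.default_rng(seed).normal(0.0, noise_sd, size=len(a))
    return MeltingCurve(
        temperatures_C=temps,
        absorbance=a,
        wavelength_nm=wavelength_nm,
        direction=protocol.direction,
        ramp_rate_C_per_min=protocol.rate_C_per_min,
        sample_id=sample_id,
    )


def _theta_rate(model: TwoStateModel, theta: float, T_C: float) -> float:
    """dtheta/dt (per minute) at temperature T_C for the model's molecularity."""
    kf = model.k_fold(T_C)
    ku = model.k_unfold(T_C)
    C = model.total_strand_conc_M
    one_m = max(1.0 - theta, 0.0)
    if model.molecularity == 1:
        fold = kf * one_m
    elif model.molecularity == 2:
        fold = 2.0 * kf * C * one_m**2
    else:
        fold = 4.0 * kf * C**3 * one_m**4
    return fold - ku * max(theta, 0.0)


def _theta_jacobian(model: TwoStateModel, theta: float, T_C: float) -> float:
    """d(dtheta/dt)/dtheta — the local relaxation rate (negative)."""
    kf = model.k_fold(T_C)
    ku = model.k_unfold(T_C)
    C = model.total_strand_conc_M
    one_m = max(1.0 - theta, 0.0)
    if model.molecularity == 1:
        return -(kf + ku)
    if model.molecularity == 2:
        return -(4.0 * kf * C * one_m + ku)
    return -(16.0 * kf * C**3 * one_m**3 + ku)


def simulate_kinetic_ramp(
    model: TwoStateModel,
    protocol: RampProtocol,
    wavelength_nm: float = 295.0,
    noise_sd: float = 0.0,
    seed: int | None = None,
    sample_id: str = "sim",
    steps_per_C: int = 20,
) -> MeltingCurve:
    """Melting curve from finite folding/unfolding kinetics along a linear ramp.

    Integrates dtheta/dt (mass-action forward flux minus first-order
    unfolding, rates Arrhenius in T(t)) with a fixed temperature step of at
    least ``steps_per_C`` steps per sampled degree.  Each step uses
    classical 4th-order Runge-Kutta while the local relaxation rate |J|*dt
    stays below 1; where the kinetics are stiff (relaxation much faster than
    the step, which happens far above Tm where unfolding is fast) the step
    switches to the unconditionally stable exponential Rosenbrock-Euler
    update theta += expm1(J*dt)/J * F(theta), which is exact for linear
    relaxation toward the local equilibrium.  The initial theta is the
    equilibrium value at the start temperature.  Slow kinetics relative to
    the ramp rate displace the apparent transition: cooling curves lag
    below, heating curves above the equilibrium Tm — the signature of
    hysteresis.
    """
    if model.kinetics is None:
        raise ConfigurationError("kinetic simulation requires a model with kinetics")
    if noise_sd < 0:
        raise DomainError("noise_sd must be >= 0")
    temps = protocol.temperatures()
    sign = 1.0 if protocol.direction == "heating" else -1.0
    dT_rate = sign * protocol.rate_C_per_min  # degC per minute, signed

    substeps = max(1, math.ceil(steps_per_C * protocol.sample_interval_C))
    dt = protocol.sample_interval_C / protocol.rate_C_per_min / substeps

    theta = equilibrium_fraction_folded(model, float(temps[0]))
    thetas = np.empty(len(temps))
    thetas[0] = theta
    for i in range(1, len(temps)):
        T0 = float(temps[i - 1])
        for j in range(substeps):
            t_local = j * dt
            T_a = T0 + dT_rate * t_local
            T_b = T0 + dT_rate * (t_local + 0.5 * dt)
            T_c = T0 + dT_rate * (t_local + dt)
            jac = _theta_jacobian(model, theta, T_c)
            if jac * dt < -1.0:
                # stiff: exponential step, exact for linear relaxation;
                # evaluated at the end temperature so the fast-kinetics limit
                # lands on the local equilibrium
                rate = _theta_rate(model, theta, T_c)
                theta = theta + math.expm1(jac * dt) / jac * rate
            else:
                k1 = _theta_rate(model, theta, T_a)
                k2 = _theta_rate(model, theta + 0.5 * dt * k1, T_b)
                k3 = _theta_rate(model, theta + 0.5 * dt * k2, T_b)
                k4 = _theta_rate(model, theta + dt * k3, T_c)
                theta = theta + dt / 6.0 * (k1 + 2.0 * k2 + 2.0 * k3 + k4)
            if theta < -1e-6 or theta > 1.0 + 1e-6:
                raise IntegrationError(
                    f"theta = {theta:.4g} left [0, 1] at T = {T_c:.2f} degC; "
                    "increase steps_per_C"
                )
            theta = min(max(theta, 0.0), 1.0)
        thetas[i] = theta

    a = thetas * _baseline(model.folded_baseline, temps) + (1.0 - thetas) * _baseline(
        model.unfolded_baseline, temps
    )
    if noise_sd > 0:
        a = a + np.random.default_rng(seed).normal(0.0, noise_sd, size=len(a))
    return MeltingCurve(
        temperatures_C=temps,
        absorbance=a,
        wavelength_nm=wavelength_nm,
        direction=protocol.direction,
        ramp_rate_C_per_min=protocol.rate_C_per_min,
        sample_id=sample_id,
    )


def generate_band_spectrum(
    band_model: BandModel | str,
    channel: str = "CD",
    noise_sd: float = 0.0,
    seed: int | None = None,
    sample_id: str = "",
    temperature_C: float = 5.0,
) -> Spectrum:
    """Evaluate a Gaussian-band model (or preset name) plus seeded noise."""
    if isinstance(band_model, str):
        try:
            name = band_model
            band_model = BAND_PRESETS[band_model]
        except KeyError:
            raise ConfigurationError(
                f"unknown band preset {band_model!r}; choose from {sorted(BAND_PRESETS)}"
            ) from None
        if not sample_id:
            sample_id = name
    if band_model.grid[0] < 200.0 or band_model.grid[-1] > 400.0:
        raise RangeError("band grid must lie within [200, 400] nm")
    values = band_model.evaluate()
    if noise_sd > 0:
        values = values + np.random.default_rng(seed).normal(0.0, noise_sd, size=len(values))
    return Spectrum(
        wavelengths_nm=band_model.grid.copy(),
        values=values,
        temperature_C=temperature_C,
        channel=channel,
        sample_id=sample_id,
    )


def generate_mixture_spectrum(
    basis: BasisSet,
    f_true: float,
    noise_sd: float = 0.0,
    seed: int | None = None,
    sample_id: str = "mixture",
) -> Spectrum:
    """Noisy convex combination of the two basis spectra at a known fraction."""
    if not 0.0 <= f_true <= 1.0:
        raise DomainError(f"f_true must lie in [0, 1], got {f_true}")
    values = calculated_spectrum(basis, f_true)
    if noise_sd > 0:
        values = values + np.random.default_rng(seed).normal(0.0, noise_sd, size=len(values))
    return Spectrum(
        wavelengths_nm=basis.grid.copy(),
        values=values,
        temperature_C=5.0,
        channel="CD",
        sample_id=sample_id,
    )


def _bimolecular_ds(dH_kcal: float, tm_C: float, conc_M: float) -> float:
    """dS placing a bimolecular Tm at tm_C for a given dH and concentration."""
    return dH_kcal * 1000.0 / (tm_C + _KELVIN) - R_CAL * math.log(conc_M)


#: Model presets mirroring the study regimes.  "intramolecular" is a stable
#: monomolecular G4 former (Tm ~ 71 degC, no hysteresis); "bimolecular_duplex"
#: a fast-equilibrating two-strand duplex (Tm ~ 55 degC at 3 uM strands,
#: concentration-dependent); "slow_bimolecular_g4" the same thermodynamics
#: with slow kinetics — dissociation half-time ~ 14 min at Tm and a strongly
#: anti-Arrhenius association (apparent Ea ~ -15 kcal/mol, as for
#: nucleation-limited multistrand assembly) — hysteretic at ordinary ramp
#: rates (0.2-2 degC/min) and equilibrating at very slow ones.  Parameter
#: values are fixture conventions, not measurements.
def model_preset(name: str) -> TwoStateModel:
    base_bimol = dict(
        delta_H_kcal_mol=-60.0,
        delta_S_cal_mol_K=_bimolecular_ds(-60.0, 55.0, 3e-6),
        molecularity=2,
        total_strand_conc_M=3e-6,
        folded_baseline=(0.35, 0.0),
        unfolded_baseline=(0.30, 0.0),
    )
    # association prefactor from two readable quantities: the dissociation
    # rate at the midpoint (k_off = k_on * C_T there) and the apparent Ea
    ea_fold = -15.0
    k_off_at_tm = 0.05  # min^-1
    tm_K = 55.0 + _KELVIN
    a_fold = (k_off_at_tm / 3e-6) * math.exp(ea_fold * 1000.0 / (R_CAL * tm_K))
    presets = {
        "intramolecular": TwoStateModel(
            delta_H_kcal_mol=-45.0,
            delta_S_cal_mol_K=-45000.0 / (71.0 + _KELVIN),
            molecularity=1,
            total_strand_conc_M=6e-6,
            folded_baseline=(0.35, 0.0),
            unfolded_baseline=(0.30, 0.0),
        ),
        "bimolecular_duplex": TwoStateModel(**base_bimol),
        "slow_bimolecular_g4": TwoStateModel(
            **base_bimol,
            kinetics=ArrheniusKinetics(A_fold_per_min=a_fold, Ea_fold_kcal_mol=ea_fold),
        ),
    }
    try:
        return presets[name]
    except KeyError:
        raise ConfigurationError(
            f"unknown model preset {name!r}; choose from {sorted(presets)}"
        ) from None


def standard_protocol(direction: str = "cooling", rate_C_per_min: float = 0.2) -> RampProtocol:
    """The study's ramp: 95 to 5 degC (or back) at 0.2 degC/min, 0.5 degC sampling."""
    if direction == "cooling":
        return RampProtocol(95.0, 5.0, rate_C_per_min, 0.5)
    return RampProtocol(5.0, 95.0, rate_C_per_min, 0.5)
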