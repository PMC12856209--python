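"""Melting-curve and difference-spectrum analysis.

The operational pipeline mirrors standard UV-melting practice for
G-quadruplex/duplex systems:

* melting traces at analytical wavelengths (295, 273, 260, 245 nm) are
  baseline-corrected by subtracting the trace at 335 nm, where nucleic acids
  do not absorb, removing instrument drift;
* the thermal difference spectrum (TDS) is the absorbance spectrum at high
  temperature (95 degC) minus the one at low temperature (5 degC) and acts
  as a structural fingerprint;
* Tm is read as the temperature of the extremum of dA/dT, deliberately
  avoiding folded/unfolded baseline fits and any two-state assumption;
* non-coincidence of cooling and heating branches (hysteresis) flags ramps
  that outpace folding/unfolding kinetics; the midpoint
  (Tm_cooling + Tm_heating)/2 summarizes such pairs.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Mapping

import numpy as np

from .errors import (
    ChannelError,
    ConfigurationError,
    DetectionError,
    InsufficientDataError,
    PairingError,
    ParameterError,
    RangeError,
)
from .spectra import TDS_TEMPERATURE, MeltingCurve, Spectrum, common_grid, regrid

#: Signature labels the classifier can assign.
SIGNATURE_LABELS = (
    "parallel_G4",
    "antiparallel_G4",
    "hybrid_G4",
    "non_G4_duplex",
    "unstructured",
)
UNCLASSIFIED = "unclassified"


@dataclass
class MeltResult:
    """Outcome of derivative-based Tm estimation on one melting trace."""

    tm_C: float | None
    amplitude: float
    derivative: np.ndarray
    transition_detected: bool
    extremum_sign: str | None  # "max" | "min" of dA/dT at the Tm


@dataclass
class HysteresisResult:
    """Comparison of cooling- and heating-branch Tm values."""

    tm_cooling_C: float
    tm_heating_C: float
    midpoint_C: float
    hysteretic: bool
    threshold_C: float


@dataclass
class SignatureCall:
    """Template-matching result for a TDS or CD spectrum."""

    label: str
    score: float
    per_template_scores: dict[str, float]


def baseline_correct(curve: MeltingCurve, reference: MeltingCurve) -> MeltingCurve:
    """Subtract a non-absorbing reference trace (e.g. 335 nm) pointwise.

    The reference is interpolated onto the curve's temperature grid when the
    two grids differ by more than 0.1 degC.
    """
    if curve.direction != reference.direction:
        raise PairingError(
            f"cannot pair a {curve.direction} curve with a {reference.direction} reference"
        )
    t = curve.temperatures_C
    rt = reference.temperatures_C
    lo, hi = min(rt[0], rt[-1]), max(rt[0], rt[-1])
    if t.min() < lo - 1e-9 or t.max() > hi + 1e-9:
        raise RangeError(
            "reference temperature range does not cover the curve; cannot correct"
        )
    if len(rt) == len(t) and np.all(np.abs(rt - t) <= 0.1):
        ref_vals = reference.absorbance
    else:
        # np.interp needs ascending abscissae; cooling ramps are descending
        order = np.argsort(rt)
        ref_vals = np.interp(t, rt[order], reference.absorbance[order])
    return replace(curve, absorbance=curve.absorbance - ref_vals)


def compute_tds(spec_high: Spectrum, spec_low: Spectrum, normalize: bool = False) -> Spectrum:
    """Thermal difference spectrum: A(high T) - A(low T), optionally unit-normalized.

    Both inputs must be absorbance spectra; if their grids differ they are
    regridded onto the 1 nm intersection grid first.  The result carries a
    NaN temperature sentinel marking it as a difference spectrum.
    """
    if spec_high.channel != "ABS" or spec_low.channel != "ABS":
        raise ChannelError(
            f"TDS requires two ABS spectra, got {spec_high.channel}/{spec_low.channel}"
        )
    if not np.array_equal(spec_high.wavelengths_nm, spec_low.wavelengths_nm):
        grid = common_grid([spec_high, spec_low], step_nm=1.0)
        spec_high = regrid(spec_high, grid)
        spec_low = regrid(spec_low, grid)
    diff = spec_high.values - spec_low.values
    if normalize:
        peak = np.max(np.abs(diff))
        if peak > 0:
            diff = diff / peak
    return replace(spec_high, values=diff, temperature_C=TDS_TEMPERATURE)


def classify_signature(
    spec: Spectrum,
    templates: Mapping[str, Spectrum],
    kind: str = "CD",
    threshold: float = 0.80,
    window: tuple[float, float] = (220.0, 335.0),
) -> SignatureCall:
    """Assign a structural label by cosine similarity to template spectra.

    Spectrum and templates are regridded to the common 1 nm grid inside
    ``window``, mean-centered, and compared by cosine similarity, which makes
    the call invariant to signal scale.  The best label is returned when its
    score reaches ``threshold``, otherwise ``unclassified``.  ``kind`` is
    carried for reporting; TDS and CD use the same window and metric.
    """
    if not templates:
        raise ConfigurationError("template library is empty")
    grid = common_grid([spec, *templates.values()], step_nm=1.0, window=window)
    v = regrid(spec, grid).values
    v = v - v.mean()
    nv = np.linalg.norm(v)
    scores: dict[str, float] = {}
    for label, tmpl in templates.items():
        u = regrid(tmpl, grid).values
        u = u - u.mean()
        nu = np.linalg.norm(u)
        if nv == 0.0 or nu == 0.0:
            scores[label] = 0.0
        else:
            scores[label] = float(np.dot(u, v) / (nu * nv))
    best = max(scores, key=lambda k: scores[k])
    if scores[best] >= threshold:
        label = best
    else:
        label = UNCLASSIFIED
    return SignatureCall(label=label, score=scores[best], per_template_scores=scores)


def derivative_curve(
    curve: MeltingCurve, window_pts: int = 11, poly_order: int = 2
) -> np.ndarray:
    """Smoothed dA/dT by local polynomial least squares, aligned to the input grid.

    At each point, a degree-``poly_order`` polynomial is fitted to the
    ``window_pts`` surrounding samples and differentiated analytically; near
    the ends the window shrinks to the available one-sided points.  This is
    the uneven-grid generalization of a Savitzky-Golay derivative and is
    exact on polynomials up to ``poly_order``.
    """
    n = len(curve)
    if window_pts % 2 == 0 or window_pts < poly_order + 1:
        raise ParameterError(
            f"window_pts must be odd and > poly_order, got {window_pts}/{poly_order}"
        )
    if window_pts > n:
        raise ParameterError(f"window of {window_pts} points exceeds series length {n}")
    t = curve.temperatures_C
    if not (np.all(np.diff(t) > 0) or np.all(np.diff(t) < 0)):
        raise ParameterError("temperatures must be strictly monotone")
    a = curve.absorbance
    half = window_pts // 2
    out = np.empty(n)
    for i in range(n):
        lo, hi = max(0, i - half), min(n, i + half + 1)
        x = t[lo:hi] - t[i]
        deg = min(poly_order, len(x) - 1)
        coef = np.polynomial.polynomial.polyfit(x, a[lo:hi], deg)
        out[i] = coef[1] if deg >= 1 else 0.0
    return out


def estimate_tm(
    curve: MeltingCurve,
    noise_k: float = 5.0,
    window_pts: int = 11,
    poly_order: int = 2,
    edge_exclude: int = 5,
) -> MeltResult:
    """Tm as the temperature of the dA/dT extremum, with a noise-gated detection rule.

    The curve should be baseline-corrected.  A transition is declared when
    the largest interior |dA/dT| exceeds ``noise_k`` times a robust noise
    scale: 1.4826 x the median absolute deviation of dA/dT over the coolest
    and hottest 10% of points, where the trace is expected to be flat.  The
    ``edge_exclude`` outermost points on each side are never eligible as the
    extremum.  The transition amplitude is the difference between the median
    corrected absorbance of the 5 lowest- and 5 highest-temperature points;
    no baselines are fitted.
    """
    n = len(curve)
    if n < 25:
        raise InsufficientDataError(f"Tm estimation needs >= 25 points, got {n}")
    d = derivative_curve(curve, window_pts=window_pts, poly_order=poly_order)
    t = curve.temperatures_C
    a = curve.absorbance

    interior = slice(edge_exclude, n - edge_exclude)
    abs_d = np.abs(d[interior])
    peak = float(abs_d.max())

    n_edge = max(2, int(np.ceil(0.1 * n)))
    order = np.argsort(t)
    edge_idx = np.concatenate([order[:n_edge], order[-n_edge:]])
    edge_d = d[edge_idx]
    noise_scale = 1.4826 * float(np.median(np.abs(edge_d - np.median(edge_d))))

    detected = peak > noise_k * noise_scale and peak > 0.0

    low5 = a[order[:5]]
    high5 = a[order[-5:]]
    amplitude = abs(float(np.median(low5) - np.median(high5)))

    if not detected:
        return MeltResult(
            tm_C=None,
            amplitude=amplitude,
            derivative=d,
            transition_detected=False,
            extremum_sign=None,
        )
    i_best = int(np.argmax(np.abs(d[interior]))) + edge_exclude
    sign = "max" if d[i_best] > 0 else "min"
    return MeltResult(
        tm_C=float(t[i_best]),
        amplitude=amplitude,
        derivative=d,
        transition_detected=True,
        extremum_sign=sign,
    )


def hysteresis(
    cooling_result: MeltResult,
    heating_result: MeltResult,
    threshold_C: float = 1.0,
) -> HysteresisResult:
    """Compare cooling and heating Tm; midpoint Tm = (Tm_cooling + Tm_heating)/2.

    The pair is flagged hysteretic when the branches differ by more than
    ``threshold_C`` (default 1 degC, the scale of instrument Tm repeatability).
    """
    if not (cooling_result.transition_detected and heating_result.transition_detected):
        raise DetectionError(
            "hysteresis requires a detected transition on both the cooling and "
            "heating branches"
        )
    tc = float(cooling_result.tm_C)
    th = float(heating_result.tm_C)
    return HysteresisResult(
        tm_cooling_C=tc,
        tm_heating_C=th,
        midpoint_C=(tc + th) / 2.0,
        hysteretic=abs(th - tc) > threshold_C,
        threshold_C=threshold_C,
    )
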