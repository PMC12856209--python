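"""Two-basis CD decomposition and composite multi-G4 spectrum prediction.

A measured CD spectrum of a sequence that partitions between a G-quadruplex
and a competing non-G4 structure is modelled as a convex combination of two
reference spectra recorded under conditions that isolate each species:

    CD_calculated(f) = f * CD_non-G4 + (1 - f) * CD_G4

The non-G4 fraction f is the minimizer of the sum of squared residuals
SSR(f) = sum_i [CD_measured(lambda_i) - CD_calculated(f, lambda_i)]^2, which
is an exact quadratic in f.  The procedure evaluates SSR on the coarse grid
f = 0.1, 0.2, ..., 0.9 (for inspection and plotting) and additionally
refines f by the closed-form least-squares minimizer clamped to [0, 1].

The comparability assumption is the caller's responsibility: both bases and
the measurement must be recorded at the same per-strand (here, per
potential-G4-unit) concentration and pathlength, since no internal
normalization is applied.

``composite_spectrum`` implements the converse construction: the predicted
CD spectrum of a hypothetical structure of m G4 units, each contributing a
known per-unit spectrum, is the weight-averaged sum over units (spectra
assumed recorded at equal per-G4-unit concentration).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .errors import DegenerateBasisError, DomainError, GridMismatchError
from .spectra import Spectrum, regrid

DEFAULT_F_GRID = tuple(np.round(np.arange(1, 10) * 0.1, 10))


@dataclass
class BasisSet:
    """The two reference spectra (G4 and non-G4) on a shared wavelength grid."""

    grid: np.ndarray
    cd_g4: np.ndarray
    cd_non_g4: np.ndarray
    labels: tuple[str, str] = ("G4", "non-G4")

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=float)
        self.cd_g4 = np.asarray(self.cd_g4, dtype=float)
        self.cd_non_g4 = np.asarray(self.cd_non_g4, dtype=float)
        if not (len(self.grid) == len(self.cd_g4) == len(self.cd_non_g4)):
            raise GridMismatchError("basis vectors and grid must share one length")
        na = np.linalg.norm(self.cd_g4)
        nb = np.linalg.norm(self.cd_non_g4)
        if na == 0.0 or nb == 0.0:
            raise DegenerateBasisError("a basis spectrum is identically zero")
        cos = float(np.clip(np.dot(self.cd_g4, self.cd_non_g4) / (na * nb), -1.0, 1.0))
        if np.arccos(cos) <= 1e-6:
            raise DegenerateBasisError(
                "basis spectra are proportional (angle <= 1e-6 rad); "
                "two-component unmixing is ill-posed"
            )

    @classmethod
    def from_spectra(cls, g4: Spectrum, non_g4: Spectrum, grid=None) -> "BasisSet":
        """Build a basis from two CD spectra, regridding onto ``grid`` if given."""
        if grid is None:
            if not np.array_equal(g4.wavelengths_nm, non_g4.wavelengths_nm):
                raise GridMismatchError(
                    "basis spectra are on different grids; pass an explicit grid"
                )
            grid = g4.wavelengths_nm
        grid = np.asarray(grid, dtype=float)
        return cls(
            grid=grid,
            cd_g4=regrid(g4, grid).values,
            cd_non_g4=regrid(non_g4, grid).values,
            labels=(g4.sample_id or "G4", non_g4.sample_id or "non-G4"),
        )


@dataclass
class DecompositionResult:
    """Estimated non-G4 fraction with its SSR profile and residual spectrum.

    ``ssr_profile`` holds the SSR at each coarse-grid f plus at the refined
    minimizer, so its minimum equals ``ssr_min``.
    """

    f_grid_best: float
    f_refined: float
    ssr_profile: dict[float, float]
    ssr_min: float
    residual: np.ndarray
    calculated_best: np.ndarray


def calculated_spectrum(basis: BasisSet, f: float) -> np.ndarray:
    """Convex combination f * non-G4 + (1 - f) * G4 on the basis grid."""
    if not 0.0 <= f <= 1.0:
        raise DomainError(f"fraction f must lie in [0, 1], got {f}")
    return f * basis.cd_non_g4 + (1.0 - f) * basis.cd_g4


def _measured_vector(measured: Spectrum | np.ndarray, basis: BasisSet) -> np.ndarray:
    if isinstance(measured, Spectrum):
        if np.array_equal(measured.wavelengths_nm, basis.grid):
            return measured.values
        return regrid(measured, basis.grid).values
    m = np.asarray(measured, dtype=float)
    if len(m) != len(basis.grid):
        raise GridMismatchError(
            f"measured vector length {len(m)} does not match basis grid {len(basis.grid)}"
        )
    return m


def ssr_profile(
    measured: Spectrum | np.ndarray,
    basis: BasisSet,
    grid: Sequence[float] = DEFAULT_F_GRID,
) -> dict[float, float]:
    """SSR(f) over a grid of candidate fractions."""
    m = _measured_vector(measured, basis)
    out: dict[float, float] = {}
    for f in grid:
        f = float(f)
        if not 0.0 <= f <= 1.0:
            raise DomainError(f"grid fraction {f} outside [0, 1]")
        r = m - calculated_spectrum(basis, f)
        out[f] = float(np.dot(r, r))
    return out


def estimate_fraction(
    measured: Spectrum | np.ndarray,
    basis: BasisSet,
    grid: Sequence[float] = DEFAULT_F_GRID,
) -> DecompositionResult:
    """Best non-G4 fraction by SSR minimization: grid argmin plus exact refinement.

    The grid argmin (ties broken toward smaller f) reproduces the coarse
    sweep; the refined estimate is the closed-form least-squares solution of
    (measured - CD_G4) against (CD_non-G4 - CD_G4), clamped to [0, 1].
    """
    m = _measured_vector(measured, basis)
    profile = ssr_profile(m, basis, grid)

    f_grid_best = min(profile, key=lambda f: (profile[f], f))

    d = basis.cd_non_g4 - basis.cd_g4
    y = m - basis.cd_g4
    f_refined = float(np.clip(np.dot(y, d) / np.dot(d, d), 0.0, 1.0))

    calc = calculated_spectrum(basis, f_refined)
    residual = m - calc
    ssr_refined = float(np.dot(residual, residual))
    profile[f_refined] = ssr_refined

    return DecompositionResult(
        f_grid_best=float(f_grid_best),
        f_refined=f_refined,
        ssr_profile=profile,
        ssr_min=min(profile.values()),
        residual=residual,
        calculated_best=calc,
    )


def composite_spectrum(unit_spectra: Sequence[tuple[np.ndarray, int]]) -> np.ndarray:
    """Per-unit weighted mean spectrum of a structure of m G4 units.

    Each entry is ``(spectrum_vector, weight)`` with a positive integer
    weight counting the units contributing that spectrum; all vectors must
    share one grid and be normalized to equal per-G4-unit concentration.
    The result is sum(w_j * S_j) / sum(w_j) — e.g. one mixed-conformation
    unit plus m-1 parallel units gives (S_mixed + (m-1) * S_parallel) / m.
    """
    if not unit_spectra:
        raise DomainError("unit_spectra must be nonempty")
    vectors = []
    weights = []
    length = None
    for vec, w in unit_spectra:
        v = np.asarray(vec, dtype=float)
        if length is None:
            length = len(v)
        elif len(v) != length:
            raise GridMismatchError(
                "unit spectra are on different grids; regrid onto a common grid first"
            )
        if int(w) != w or w < 1:
            raise DomainError(f"weights must be positive integers, got {w}")
        vectors.append(v)
        weights.append(int(w))
    total = sum(weights)
    acc = np.zeros(length)
    for v, w in zip(vectors, weights):
        acc += w * v
    return acc / total
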