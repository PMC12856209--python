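"""Core data containers and CSV I/O for spectra and melting ramps.

Two containers cover everything the pipeline consumes:

* :class:`Spectrum` — signal versus wavelength at one temperature, either an
  absorbance spectrum (channel ``ABS``, absorbance units) or a circular
  dichroism spectrum (channel ``CD``, raw instrument millidegrees).
* :class:`MeltingCurve` — absorbance versus temperature at one wavelength,
  for one ramp direction (``cooling`` or ``heating``) at one ramp rate.

Both are exchanged as a single long-format CSV dialect (comma separator, dot
decimal, UTF-8, header required) so that fixtures are diffable and
read/write round-trips are bit-exact: floats are serialized with
``repr``-shortest formatting, which Python and pandas parse back to the
identical IEEE-754 value.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import FormatError, ParseError, RangeError

CHANNELS = ("ABS", "CD")
DIRECTIONS = ("cooling", "heating")

#: Sentinel stored in ``Spectrum.temperature_C`` for thermal difference
#: spectra, which are differences between two temperatures rather than a
#: measurement at one.
TDS_TEMPERATURE = float("nan")

_SPECTRA_COLUMNS = ["sample_id", "channel", "temperature_C", "wavelength_nm", "value"]
_SPECTRA_OPTIONAL = ["strand_conc_uM", "pathlength_cm"]
_MELT_COLUMNS = [
    "sample_id",
    "wavelength_nm",
    "direction",
    "ramp_rate_C_per_min",
    "temperature_C",
    "absorbance",
]


@dataclass
class Spectrum:
    """A signal-vs-wavelength trace at a single temperature.

    Parameters
    ----------
    wavelengths_nm : array-like
        Strictly increasing wavelengths in nm, length >= 2.
    values : array-like
        Signal at each wavelength (absorbance units for ``ABS``, mdeg for
        ``CD``); same length as ``wavelengths_nm``.
    temperature_C : float
        Acquisition temperature; NaN marks a thermal difference spectrum.
    channel : str
        ``"ABS"`` or ``"CD"``.
    """

    wavelengths_nm: np.ndarray
    values: np.ndarray
    temperature_C: float
    channel: str
    sample_id: str = ""
    strand_conc_uM: float | None = None
    pathlength_cm: float | None = None

    def __post_init__(self) -> None:
        self.wavelengths_nm = np.asarray(self.wavelengths_nm, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.channel not in CHANNELS:
            raise FormatError(f"channel must be one of {CHANNELS}, got {self.channel!r}")
        if self.wavelengths_nm.ndim != 1 or self.values.ndim != 1:
            raise FormatError("wavelengths and values must be 1-D vectors")
        if len(self.wavelengths_nm) != len(self.values):
            raise FormatError("wavelengths and values must have equal length")
        if len(self.wavelengths_nm) < 2:
            raise FormatError("a spectrum needs at least 2 points")
        if not np.all(np.diff(self.wavelengths_nm) > 0):
            raise FormatError("wavelengths must be strictly increasing")

    def __len__(self) -> int:
        return len(self.wavelengths_nm)

    def is_tds(self) -> bool:
        return math.isnan(self.temperature_C)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Spectrum):
            return NotImplemented
        same_temp = (
            self.temperature_C == other.temperature_C
            or (math.isnan(self.temperature_C) and math.isnan(other.temperature_C))
        )
        return (
            same_temp
            and self.channel == other.channel
            and self.sample_id == other.sample_id
            and _opt_eq(self.strand_conc_uM, other.strand_conc_uM)
            and _opt_eq(self.pathlength_cm, other.pathlength_cm)
            and np.array_equal(self.wavelengths_nm, other.wavelengths_nm)
            and np.array_equal(self.values, other.values)
        )


@dataclass
class MeltingCurve:
    """Absorbance versus temperature for one wavelength and one ramp.

    Temperatures must be strictly monotone in the stated direction:
    decreasing for ``cooling``, increasing for ``heating``.
    """

    temperatures_C: np.ndarray
    absorbance: np.ndarray
    wavelength_nm: float
    direction: str
    ramp_rate_C_per_min: float
    sample_id: str = ""

    def __post_init__(self) -> None:
        self.temperatures_C = np.asarray(self.temperatures_C, dtype=float)
        self.absorbance = np.asarray(self.absorbance, dtype=float)
        if self.direction not in DIRECTIONS:
            raise FormatError(f"direction must be one of {DIRECTIONS}, got {self.direction!r}")
        if len(self.temperatures_C) != len(self.absorbance):
            raise FormatError("temperatures and absorbance must have equal length")
        if len(self.temperatures_C) < 5:
            raise FormatError("a melting curve needs at least 5 points")
        if self.ramp_rate_C_per_min <= 0:
            raise FormatError("ramp rate must be positive")
        diffs = np.diff(self.temperatures_C)
        if self.direction == "cooling" and not np.all(diffs < 0):
            raise FormatError("cooling curve temperatures must be strictly decreasing")
        if self.direction == "heating" and not np.all(diffs > 0):
            raise FormatError("heating curve temperatures must be strictly increasing")

    def __len__(self) -> int:
        return len(self.temperatures_C)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, MeltingCurve):
            return NotImplemented
        return (
            self.wavelength_nm == other.wavelength_nm
            and self.direction == other.direction
            and self.ramp_rate_C_per_min == other.ramp_rate_C_per_min
            and self.sample_id == other.sample_id
            and np.array_equal(self.temperatures_C, other.temperatures_C)
            and np.array_equal(self.absorbance, other.absorbance)
        )


def _opt_eq(a: float | None, b: float | None) -> bool:
    if a is None or b is None:
        return a is b
    return a == b


def _read_csv(path, required: Sequence[str]) -> pd.DataFrame:
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    for col in required:
        if col not in df.columns:
            raise FormatError(f"missing required column {col!r} in {path}")
    return df


def _numeric(df: pd.DataFrame, col: str, path) -> np.ndarray:
    probe = pd.to_numeric(df[col], errors="coerce")
    bad = probe.isna() & (df[col].astype(str).str.strip().str.lower() != "nan")
    if bad.any():
        row = int(np.flatnonzero(bad.to_numpy())[0])
        raise ParseError(
            f"non-numeric value {df[col].iloc[row]!r} in column {col!r}, "
            f"data row {row + 1} of {path}"
        )
    # numpy's string->float conversion is correctly rounded (bit-exact
    # round trips with repr output); pandas' to_numeric is not
    return df[col].to_numpy(dtype=str).astype(float)


def read_spectra_table(path) -> list[Spectrum]:
    """Read a long-format spectra CSV into a list of :class:`Spectrum`.

    Rows are grouped by ``(sample_id, channel, temperature_C)`` in order of
    first appearance; wavelengths are sorted ascending within each group.
    """
    df = _read_csv(path, _SPECTRA_COLUMNS)
    temp = _numeric(df, "temperature_C", path)
    wl = _numeric(df, "wavelength_nm", path)
    val = _numeric(df, "value", path)
    opt: dict[str, np.ndarray | None] = {}
    for col in _SPECTRA_OPTIONAL:
        if col in df.columns:
            blank = df[col].astype(str).str.strip() == ""
            vals = pd.to_numeric(df[col].where(~blank), errors="coerce")
            bad = vals.isna() & ~blank
            if bad.any():
                row = int(np.flatnonzero(bad.to_numpy())[0])
                raise ParseError(
                    f"non-numeric value {df[col].iloc[row]!r} in column {col!r}, "
                    f"data row {row + 1} of {path}"
                )
            raw = df[col].astype(str).str.strip().where(~blank, "nan")
            opt[col] = raw.to_numpy(dtype=str).astype(float)
        else:
            opt[col] = None

    spectra: list[Spectrum] = []
    # NaN is the TDS temperature sentinel; key on its repr so NaN rows group
    keys = [
        (sid, ch, "nan" if math.isnan(t) else repr(float(t)))
        for sid, ch, t in zip(df["sample_id"], df["channel"], temp)
    ]
    seen: dict[tuple, list[int]] = {}
    for i, key in enumerate(keys):
        seen.setdefault(key, []).append(i)
    for (sample_id, channel, temp_key), idx in seen.items():
        temperature = float(temp_key)
        idx = np.asarray(idx)
        order = np.argsort(wl[idx], kind="stable")
        idx = idx[order]

        def _first(col: str) -> float | None:
            arr = opt[col]
            if arr is None:
                return None
            v = arr[idx[0]]
            return None if np.isnan(v) else float(v)

        spectra.append(
            Spectrum(
                wavelengths_nm=wl[idx],
                values=val[idx],
                temperature_C=float(temperature),
                channel=str(channel),
                sample_id=str(sample_id),
                strand_conc_uM=_first("strand_conc_uM"),
                pathlength_cm=_first("pathlength_cm"),
            )
        )
    return spectra


def write_spectra_table(spectra: Iterable[Spectrum], path) -> None:
    """Write spectra as the long-format CSV read by :func:`read_spectra_table`."""
    spectra = list(spectra)
    if not spectra:
        raise FormatError("cannot write an empty spectra list")
    rows = []
    for s in spectra:
        for lam, v in zip(s.wavelengths_nm, s.values):
            rows.append(
                {
                    "sample_id": s.sample_id,
                    "channel": s.channel,
                    "temperature_C": repr(s.temperature_C),
                    "wavelength_nm": repr(float(lam)),
                    "value": repr(float(v)),
                    "strand_conc_uM": "" if s.strand_conc_uM is None else repr(s.strand_conc_uM),
                    "pathlength_cm": "" if s.pathlength_cm is None else repr(s.pathlength_cm),
                }
            )
    pd.DataFrame(rows, columns=_SPECTRA_COLUMNS + _SPECTRA_OPTIONAL).to_csv(path, index=False)


def read_melting_table(path) -> list[MeltingCurve]:
    """Read a long-format melting CSV into a list of :class:`MeltingCurve`.

    One curve per ``(sample_id, wavelength_nm, direction, ramp_rate)``, rows
    kept in file order (the acquisition order defines the ramp).
    """
    df = _read_csv(path, _MELT_COLUMNS)
    bad_dir = ~df["direction"].isin(DIRECTIONS)
    if bad_dir.any():
        row = int(np.flatnonzero(bad_dir.to_numpy())[0])
        raise FormatError(
            f"unknown direction {df['direction'].iloc[row]!r} in data row {row + 1} of {path}; "
            f"expected one of {DIRECTIONS}"
        )
    wl = _numeric(df, "wavelength_nm", path)
    rate = _numeric(df, "ramp_rate_C_per_min", path)
    temp = _numeric(df, "temperature_C", path)
    absorb = _numeric(df, "absorbance", path)

    curves: list[MeltingCurve] = []
    keys = list(zip(df["sample_id"], wl, df["direction"], rate))
    seen: dict[tuple, list[int]] = {}
    for i, key in enumerate(keys):
        seen.setdefault(key, []).append(i)
    for (sample_id, wavelength, direction, ramp_rate), idx in seen.items():
        idx = np.asarray(idx)
        curves.append(
            MeltingCurve(
                temperatures_C=temp[idx],
                absorbance=absorb[idx],
                wavelength_nm=float(wavelength),
                direction=str(direction),
                ramp_rate_C_per_min=float(ramp_rate),
                sample_id=str(sample_id),
            )
        )
    return curves


def write_melting_table(curves: Iterable[MeltingCurve], path) -> None:
    """Write curves as the long-format CSV read by :func:`read_melting_table`."""
    curves = list(curves)
    if not curves:
        raise FormatError("cannot write an empty curve list")
    rows = []
    for c in curves:
        for t, a in zip(c.temperatures_C, c.absorbance):
            rows.append(
                {
                    "sample_id": c.sample_id,
                    "wavelength_nm": repr(c.wavelength_nm),
                    "direction": c.direction,
                    "ramp_rate_C_per_min": repr(c.ramp_rate_C_per_min),
                    "temperature_C": repr(float(t)),
                    "absorbance": repr(float(a)),
                }
            )
    pd.DataFrame(rows, columns=_MELT_COLUMNS).to_csv(path, index=False)


def regrid(spectrum: Spectrum, target_grid) -> Spectrum:
    """Linearly interpolate a spectrum onto ``target_grid`` (no extrapolation).

    Channel and sample metadata are preserved.
    """
    target = np.asarray(target_grid, dtype=float)
    if target.ndim != 1 or len(target) < 2 or not np.all(np.diff(target) > 0):
        raise FormatError("target grid must be a strictly increasing vector of length >= 2")
    lo, hi = spectrum.wavelengths_nm[0], spectrum.wavelengths_nm[-1]
    if target[0] < lo or target[-1] > hi:
        raise RangeError(
            f"target grid [{target[0]}, {target[-1]}] nm extends beyond the "
            f"source range [{lo}, {hi}] nm; extrapolation is not supported"
        )
    values = np.interp(target, spectrum.wavelengths_nm, spectrum.values)
    return replace(spectrum, wavelengths_nm=target, values=values)


def common_grid(
    spectra: Sequence[Spectrum],
    step_nm: float = 1.0,
    window: tuple[float, float] | None = None,
) -> np.ndarray:
    """Shared wavelength grid: intersection of all ranges at a fixed step.

    ``window`` optionally clips the intersection (e.g. ``(220, 335)`` for the
    analysis window used throughout).
    """
    lo = max(s.wavelengths_nm[0] for s in spectra)
    hi = min(s.wavelengths_nm[-1] for s in spectra)
    if window is not None:
        lo, hi = max(lo, window[0]), min(hi, window[1])
    if hi - lo < step_nm:
        raise RangeError("spectra share no usable wavelength overlap")
    start = math.ceil(lo / step_nm) * step_nm
    n = int(math.floor((hi - start) / step_nm)) + 1
    return start + step_nm * np.arange(n)
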