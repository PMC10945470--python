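"""Stable-isotope conversions, two-pool mixing model and uptake-rate fits.

delta13C values (permille vs VPDB) convert to 13C atom fractions via
R = (delta/1000 + 1) * R_VPDB and x = R / (1 + R).  Cell carbon is modeled
as a two-endmember mixture of an unlabeled base pool (atom fraction
``x_base``) and a labeled tracer pool (``x_tracer``); the tracer-derived
fraction is f = (x_cell - x_base) / (x_tracer - x_base).  With a cellular
carbon quota Q (nmol C/cell) and c carbon atoms per substrate molecule, a
linear-in-time enrichment f(t) = b*t implies a per-cell substrate uptake
rate of b * Q / c (nmol substrate/cell/hr).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .errors import DegenerateInputError, ValidationError

#: 13C/12C ratio of the VPDB standard (IUPAC recommended value)
R_VPDB = 0.0111802

#: default carbon count per substrate molecule (a C9 dicarboxylic acid)
DEFAULT_CARBONS_PER_MOLECULE = 9


def atom_percent(x: float) -> float:
    """Atom fraction -> atom percent."""
    return x * 100.0


def from_atom_percent(ap: float) -> float:
    """Atom percent -> atom fraction."""
    return ap / 100.0


def delta_to_atom_fraction(delta_permil, r_standard: float = R_VPDB):
    """delta (permille vs the standard) -> 13C atom fraction."""
    delta = np.asarray(delta_permil, dtype=float)
    if np.any(delta <= -1000.0):
        raise ValidationError("delta <= -1000 permille implies a negative isotope ratio")
    r = (delta / 1000.0 + 1.0) * r_standard
    x = r / (1.0 + r)
    return x if x.ndim else float(x)


def atom_fraction_to_delta(x, r_standard: float = R_VPDB):
    """13C atom fraction -> delta (permille vs the standard); exact inverse
    of :func:`delta_to_atom_fraction`."""
    x = np.asarray(x, dtype=float)
    if np.any((x <= 0.0) | (x >= 1.0)):
        raise ValidationError("atom fraction must lie in (0, 1)")
    r = x / (1.0 - x)
    delta = (r / r_standard - 1.0) * 1000.0
    return delta if delta.ndim else float(delta)


def tracer_fraction(x_cell, x_base: float, x_tracer: float):
    """Two-pool mixing: fraction of cell carbon derived from the tracer,
    f = (x_cell - x_base) / (x_tracer - x_base).

    Values outside the physically expected range trigger a warning but are
    still returned (audit decides what to do with them).
    """
    if not x_base < x_tracer:
        raise ValidationError("require x_base < x_tracer")
    x_cell = np.asarray(x_cell, dtype=float)
    f = (x_cell - x_base) / (x_tracer - x_base)
    # 5 sigma of a 0.10 permille measurement, expressed on the f scale
    slack = 5 * 0.10 / 1000.0 * R_VPDB / (x_tracer - x_base)
    if np.any((f < -slack) | (f > 1.0)):
        warnings.warn("tracer fraction outside [0, 1]; check endmembers", stacklevel=2)
    return f if f.ndim else float(f)


def uptake_rate(
    f: float,
    t_hr: float,
    carbon_quota: float,
    carbons_per_molecule: int = DEFAULT_CARBONS_PER_MOLECULE,
) -> float:
    """Single-point substrate uptake rate (nmol substrate/cell/hr) from a
    tracer-derived carbon fraction f measured at time ``t_hr``."""
    if t_hr <= 0:
        raise ValidationError("time must be positive")
    if carbon_quota <= 0:
        raise ValidationError("carbon quota must be positive")
    return f * (carbon_quota / carbons_per_molecule) / t_hr


@dataclass
class TracerSeries:
    """Timed delta13C measurements with mixing-model constants.

    ``time_min`` and ``delta_permil`` are parallel arrays (replicates appear
    as repeated timepoints).  ``x_base``/``x_tracer`` are atom fractions;
    atom-percent inputs (values > 1) are converted on construction.
    """

    time_min: np.ndarray
    delta_permil: np.ndarray
    x_base: float
    x_tracer: float
    carbon_quota: float
    carbons_per_molecule: int = DEFAULT_CARBONS_PER_MOLECULE
    cell_density: float | None = None
    warnings_log: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.time_min = np.asarray(self.time_min, dtype=float)
        self.delta_permil = np.asarray(self.delta_permil, dtype=float)
        if self.time_min.shape != self.delta_permil.shape:
            raise ValidationError("time and delta arrays must align")
        if np.any(np.diff(np.sort(self.time_min)) < 0):  # defensive; sort is safe
            raise ValidationError("timepoints must be sortable")
        if self.x_base > 1.0:
            self.x_base = from_atom_percent(self.x_base)
        if self.x_tracer > 1.0:
            self.x_tracer = from_atom_percent(self.x_tracer)
        if not 0.0 < self.x_base < self.x_tracer <= 1.0:
            raise ValidationError("require 0 < x_base < x_tracer <= 1")
        if self.carbon_quota <= 0:
            raise ValidationError("carbon quota must be positive")

    @property
    def time_hr(self) -> np.ndarray:
        return self.time_min / 60.0


@dataclass
class UptakeEstimate:
    """Origin-constrained linear fit of tracer fraction vs time."""

    rate: float  # nmol substrate/cell/hr; clipped at 0 for reporting
    rate_raw: float  # unclipped least-squares value
    slope_per_hr: float  # b in f(t) = b t
    fraction_from_tracer: np.ndarray  # f per measurement, clipped to [0, 1]
    fraction_raw: np.ndarray  # unclipped values for audit
    residual_sd_permil: float
    negative_fit: bool
    n_obs: int


def fit_uptake(series: TracerSeries) -> UptakeEstimate:
    """Convert the series to tracer fractions and fit f(t) = b * t through
    the origin by least squares; rate = b * quota / carbons_per_molecule."""
    t = series.time_hr
    if np.all(t == 0):
        raise DegenerateInputError("all timepoints at t = 0; cannot fit a rate")
    x_cell = delta_to_atom_fraction(series.delta_permil)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        f_raw = np.atleast_1d(tracer_fraction(x_cell, series.x_base, series.x_tracer))
    b = float((f_raw * t).sum() / (t**2).sum())
    rate_raw = b * series.carbon_quota / series.carbons_per_molecule
    fitted_x = series.x_base + np.clip(b * t, None, 1.0) * (
        series.x_tracer - series.x_base
    )
    fitted_x = np.clip(fitted_x, 1e-12, 1 - 1e-12)
    resid = series.delta_permil - np.atleast_1d(atom_fraction_to_delta(fitted_x))
    dof = max(len(resid) - 1, 1)
    residual_sd = float(np.sqrt((resid**2).sum() / dof))
    return UptakeEstimate(
        rate=max(rate_raw, 0.0),
        rate_raw=rate_raw,
        slope_per_hr=b,
        fraction_from_tracer=np.clip(f_raw, 0.0, 1.0),
        fraction_raw=f_raw,
        residual_sd_permil=residual_sd,
        negative_fit=rate_raw < 0,
        n_obs=int(len(resid)),
    )
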