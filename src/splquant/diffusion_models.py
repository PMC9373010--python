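"""Diffusion signal models: two-point ADC and the diffusion-kurtosis (DKI) fit.

Two signal models are supported, both expressed relative to the b=0 signal
``S0``:

* mono-exponential (Gaussian diffusion)::

      S(b) / S0 = exp(-b * ADC)

  fitted in closed form from exactly two b-values (conventionally 0 and
  1000 s/mm^2);

* diffusion kurtosis::

      S(b) / S0 = exp(-b * Dapp + (1/6) * b^2 * Dapp^2 * Kapp)

  fitted by nonlinear least squares on the signal domain over >= 3 nonzero
  b-values (conventionally 0, 500, 1000, 2000 s/mm^2), initialised from a
  log-domain quadratic solve.

``Dapp`` (mm^2/s) is the apparent diffusivity corrected for non-Gaussian
bias and ``Kapp`` (dimensionless) the apparent excess kurtosis.  The
acquisitions targeted here are trace-weighted single "direction" stacks, so
the mean diffusivity/kurtosis maps are simply the per-voxel ``Dapp``/``Kapp``
(``fit_parameter_maps`` accepts a multi-direction hook; see below).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
from scipy.optimize import curve_fit

__all__ = [
    "BValueProtocol",
    "DiffusionSignalSeries",
    "DiffusionVolumeStack",
    "ADCResult",
    "DKIFitResult",
    "ParameterMap",
    "DiffusionKurtosisModel",
    "dki_signal",
    "fit_adc",
    "fit_dki",
    "fit_parameter_maps",
    "roi_mean",
    "average_readers",
]

#: default parameter bounds; at-bound solutions are flagged, not discarded
DAPP_BOUNDS = (1e-6, 1e-2)  # mm^2/s
KAPP_BOUNDS = (0.0, 3.0)  # dimensionless


@dataclass(frozen=True)
class BValueProtocol:
    """An ordered set of diffusion sensitisations (b-values), s/mm^2.

    Must contain b=0, be strictly increasing and nonnegative.
    """

    bvalues: tuple[float, ...]

    def __init__(self, bvalues: Sequence[float]) -> None:
        bvals = tuple(float(b) for b in bvalues)
        if len(bvals) < 2:
            raise ValueError("protocol needs at least two b-values")
        if bvals[0] != 0.0:
            raise ValueError("protocol must start at b=0")
        if any(b < 0 for b in bvals):
            raise ValueError("b-values must be nonnegative")
        if any(b2 <= b1 for b1, b2 in zip(bvals, bvals[1:])):
            raise ValueError("b-values must be strictly increasing")
        object.__setattr__(self, "bvalues", bvals)

    @classmethod
    def adc_default(cls) -> "BValueProtocol":
        return cls((0.0, 1000.0))

    @classmethod
    def dki_default(cls) -> "BValueProtocol":
        return cls((0.0, 500.0, 1000.0, 2000.0))

    def __len__(self) -> int:
        return len(self.bvalues)

    def as_array(self) -> np.ndarray:
        return np.asarray(self.bvalues, dtype=float)


@dataclass(frozen=True)
class DiffusionSignalSeries:
    """Signal magnitudes S(b) aligned with a protocol's b-values; S0 = S(0)."""

    signal: tuple[float, ...]

    def __init__(self, signal: Sequence[float]) -> None:
        sig = tuple(float(s) for s in signal)
        if sig[0] <= 0:
            raise ValueError("S0 (signal at b=0) must be positive")
        if any(s < 0 for s in sig):
            raise ValueError("signals must be nonnegative")
        object.__setattr__(self, "signal", sig)

    @property
    def s0(self) -> float:
        return self.signal[0]

    def as_array(self) -> np.ndarray:
        return np.asarray(self.signal, dtype=float)


@dataclass
class DiffusionVolumeStack:
    """4D multi-b-value volume: ``data[x, y, z, i]`` is the signal at
    ``protocol.bvalues[i]``; ``voxel_size`` in mm per axis."""

    data: np.ndarray
    protocol: BValueProtocol
    voxel_size: tuple[float, float, float] = (1.0, 1.0, 1.0)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 4:
            raise ValueError("stack data must be 4D (x, y, z, b)")
        if self.data.shape[-1] != len(self.protocol):
            raise ValueError(
                f"stack has {self.data.shape[-1]} b-volumes but protocol has "
                f"{len(self.protocol)} b-values"
            )

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        return self.data.shape[:3]


@dataclass
class ADCResult:
    """Two-point apparent diffusion coefficient, mm^2/s."""

    adc: float
    fit_status: Literal["ok", "clipped_at_zero", "failed"]


@dataclass
class DKIFitResult:
    """Result of a single-voxel/ROI diffusion-kurtosis fit.

    ``nonmonotone_warning`` flags the standard DKI caveat: the fitted
    quadratic exponent has its signal minimum at b* = 3/(Dapp*Kapp); when b*
    falls below the largest acquired b the model predicts (unphysical)
    signal re-growth inside the fitted range.
    """

    dapp: float
    kapp: float
    s0_hat: float
    fit_status: Literal["ok", "clipped_at_bound", "failed"]
    residual_norm: float
    nonmonotone_warning: bool = False

    def summary(self) -> str:
        lines = [
            "Diffusion kurtosis fit",
            "----------------------",
            f"Dapp          {self.dapp:.6e} mm^2/s",
            f"Kapp          {self.kapp:.6f}",
            f"S0            {self.s0_hat:.6g}",
            f"status        {self.fit_status}",
            f"residual norm {self.residual_norm:.3e}",
        ]
        if self.nonmonotone_warning:
            lines.append("warning: model non-monotone below max acquired b")
        return "\n".join(lines)


@dataclass
class ParameterMap:
    """A named per-voxel quantity (ADC/MD in mm^2/s, MK dimensionless).

    ``values`` is NaN outside ``mask``; ``mask`` marks voxels with a valid fit.
    """

    name: Literal["ADC", "MD", "MK"]
    values: np.ndarray
    mask: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.values.shape != self.mask.shape:
            raise ValueError("values and mask shapes differ")
        inside = self.values[self.mask]
        if inside.size and not np.all(np.isfinite(inside)):
            raise ValueError("non-finite values inside mask")


def dki_signal(
    b: np.ndarray | float, s0: float, dapp: float, kapp: float
) -> np.ndarray | float:
    """Evaluate S(b) = S0 * exp(-b*Dapp + (1/6) b^2 Dapp^2 Kapp)."""
    b = np.asarray(b, dtype=float)
    out = s0 * np.exp(-b * dapp + (b**2) * (dapp**2) * kapp / 6.0)
    return out if out.ndim else float(out)


def fit_adc(
    series: DiffusionSignalSeries, protocol: BValueProtocol | None = None
) -> ADCResult:
    """Closed-form two-point ADC: ``ln(S0/S(b1)) / b1``.

    ``S(b1) >= S0`` clips to 0 (no measurable decay); ``S(b1) = 0`` fails.
    """
    protocol = protocol or BValueProtocol.adc_default()
    if len(protocol) != 2:
        raise ValueError("ADC protocol must have exactly two b-values")
    s = series.as_array()
    if s.shape[0] != 2:
        raise ValueError("series length must match the two-point protocol")
    s0, s1 = s
    b1 = protocol.bvalues[1]
    if s1 <= 0:
        return ADCResult(adc=float("nan"), fit_status="failed")
    if s1 >= s0:
        return ADCResult(adc=0.0, fit_status="clipped_at_zero")
    return ADCResult(adc=float(np.log(s0 / s1) / b1), fit_status="ok")


class DiffusionKurtosisModel:
    """Nonlinear least-squares DKI model for one signal series.

    Parameters
    ----------
    series
        Signal magnitudes aligned with ``protocol``.
    protocol
        b-values; must include b=0 and at least three distinct nonzero values
        beyond the quadratic model's validity requirement.
    dapp_bounds, kapp_bounds
        Box constraints for the optimiser; at-bound solutions are reported
        with ``fit_status='clipped_at_bound'``.

    The objective is evaluated on the signal domain (not log signals, which
    would distort the noise at low SNR); the starting point comes from the
    log-domain quadratic ``ln S = a0 + a1 b + a2 b^2`` with ``Dapp = -a1``
    and ``Kapp = 6 a2 / Dapp^2``.
    """

    def __init__(
        self,
        series: DiffusionSignalSeries,
        protocol: BValueProtocol,
        dapp_bounds: tuple[float, float] = DAPP_BOUNDS,
        kapp_bounds: tuple[float, float] = KAPP_BOUNDS,
    ) -> None:
        if len(protocol) < 4:
            raise ValueError("DKI protocol needs b=0 plus >= 3 nonzero b-values")
        s = series.as_array()
        if s.shape[0] != len(protocol):
            raise ValueError("series length must match protocol")
        if np.any(s <= 0):
            raise ValueError("DKI fit requires positive signals at all b")
        self.series = series
        self.protocol = protocol
        self.dapp_bounds = dapp_bounds
        self.kapp_bounds = kapp_bounds

    # -- initialisation ----------------------------------------------------
    def _log_quadratic_init(self) -> tuple[float, float, float]:
        b = self.protocol.as_array()
        y = np.log(self.series.as_array())
        coeffs, *_ = np.linalg.lstsq(
            np.column_stack([np.ones_like(b), b, b**2]), y, rcond=None
        )
        a0, a1, a2 = coeffs
        d0 = float(np.clip(-a1, *self.dapp_bounds))
        k0 = float(np.clip(6.0 * a2 / d0**2, *self.kapp_bounds))
        return float(np.exp(a0)), d0, k0

    def fit(self, bound_tol: float = 1e-9) -> DKIFitResult:
        b = self.protocol.as_array()
        s = self.series.as_array()
        if np.ptp(s) == 0:  # flat series: Dapp at the zero branch, Kapp undefined
            return DKIFitResult(
                dapp=float("nan"), kapp=float("nan"), s0_hat=float(s[0]),
                fit_status="failed", residual_norm=0.0,
            )
        s0_init, d_init, k_init = self._log_quadratic_init()
        lo = [1e-12, self.dapp_bounds[0], self.kapp_bounds[0]]
        hi = [np.inf, self.dapp_bounds[1], self.kapp_bounds[1]]
        p0 = [np.clip(s0_init, 1e-12, 10 * s[0]), d_init, k_init]
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                popt, _ = curve_fit(
                    dki_signal, b, s, p0=p0, bounds=(lo, hi),
                    xtol=1e-14, ftol=1e-14, gtol=1e-14, maxfev=10000,
                )
        except (RuntimeError, ValueError):
            return DKIFitResult(
                dapp=float("nan"), kapp=float("nan"), s0_hat=float("nan"),
                fit_status="failed", residual_norm=float("nan"),
            )
        s0_hat, dapp, kapp = (float(v) for v in popt)
        resid = float(np.linalg.norm(dki_signal(b, s0_hat, dapp, kapp) - s))
        at_bound = (
            dapp <= self.dapp_bounds[0] + bound_tol
            or dapp >= self.dapp_bounds[1] - bound_tol
            or kapp <= self.kapp_bounds[0] + bound_tol
            or kapp >= self.kapp_bounds[1] - bound_tol
        )
        nonmono = kapp > 0 and (3.0 / (dapp * kapp)) < b.max()
        return DKIFitResult(
            dapp=dapp, kapp=kapp, s0_hat=s0_hat,
            fit_status="clipped_at_bound" if at_bound else "ok",
            residual_norm=resid, nonmonotone_warning=bool(nonmono),
        )


def fit_dki(
    series: DiffusionSignalSeries,
    protocol: BValueProtocol,
    dapp_bounds: tuple[float, float] = DAPP_BOUNDS,
    kapp_bounds: tuple[float, float] = KAPP_BOUNDS,
) -> DKIFitResult:
    """Fit the kurtosis model to one signal series (see DiffusionKurtosisModel)."""
    return DiffusionKurtosisModel(series, protocol, dapp_bounds, kapp_bounds).fit()


def fit_parameter_maps(
    stack: DiffusionVolumeStack,
    mask: np.ndarray | None = None,
    model: Literal["adc", "dki"] = "dki",
) -> dict[str, ParameterMap]:
    """Apply a diffusion model voxelwise, returning named parameter maps.

    ``model='adc'`` yields {'ADC'}; ``model='dki'`` yields {'MD', 'MK'} with
    MD := Dapp and MK := Kapp under the trace-weighted single-direction
    convention.  Voxels with any nonpositive signal or a failed fit are
    excluded from the output masks (not clamped).  Multi-direction stacks can
    be handled by fitting each direction's stack and averaging the maps.
    """
    if mask is None:
        mask = np.ones(stack.grid_shape, dtype=bool)
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != stack.grid_shape:
        raise ValueError("mask shape must match the stack grid")

    fittable = mask & np.all(stack.data > 0, axis=-1)
    names = ["ADC"] if model == "adc" else ["MD", "MK"]
    values = {n: np.full(stack.grid_shape, np.nan) for n in names}
    out_mask = np.zeros(stack.grid_shape, dtype=bool)

    for idx in np.argwhere(fittable):
        i, j, k = idx
        series = DiffusionSignalSeries(stack.data[i, j, k])
        if model == "adc":
            res = fit_adc(series, stack.protocol)
            if res.fit_status == "failed":
                continue
            values["ADC"][i, j, k] = res.adc
        else:
            res = fit_dki(series, stack.protocol)
            if res.fit_status == "failed":
                continue
            values["MD"][i, j, k] = res.dapp
            values["MK"][i, j, k] = res.kapp
        out_mask[i, j, k] = True

    return {n: ParameterMap(name=n, values=values[n], mask=out_mask.copy()) for n in names}


def roi_mean(pmap: ParameterMap, roi: np.ndarray) -> float:
    """Arithmetic mean of the map over ROI voxels (ROI must lie in the fitted mask)."""
    roi = np.asarray(roi, dtype=bool)
    if roi.shape != pmap.values.shape:
        raise ValueError("ROI shape must match the map")
    if not roi.any():
        raise ValueError("empty ROI")
    if np.any(roi & ~pmap.mask):
        raise ValueError("ROI extends outside the fitted mask")
    return float(pmap.values[roi].mean())


def average_readers(value_reader1: float, value_reader2: float) -> float:
    """The per-lesion analysis value: the mean of the two readers' ROI means."""
    return 0.5 * (float(value_reader1) + float(value_reader2))
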