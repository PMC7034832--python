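"""Binding-assay quantification: dual-colour EMSA normalization and 1:1
isotherm K_D fitting for titration (MST-style) data.

EMSA lanes carry two channels — an ATTO550-labelled probe with the cytosine
variant under test and an ATTO647N-labelled unmodified internal control run
in the same lane.  The normalized signal

    (bound_550 / bound_647) × (total_647 / total_550)

cancels loading differences between channels; a ratio of 1 means the
modified probe binds like the control, 2 means a two-fold preference.

Titrations are summarised by nonlinear least squares of the non-depleting
1:1 isotherm ``response = baseline + amplitude · c / (c + K_D)``.  A
ligand-depletion (quadratic) variant is available behind a flag for cases
where the fixed binding-partner concentration is not negligible against K_D.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit

__all__ = [
    "EmsaLane",
    "TitrationFit",
    "FitError",
    "emsa_normalized_signal",
    "fit_kd",
    "shuffle_labels",
]


class FitError(RuntimeError):
    """K_D fit did not converge or the data are unidentifiable."""


@dataclass(frozen=True)
class EmsaLane:
    """Fluorescence signals of one gel lane (arbitrary units).

    ``bound_*`` is the shifted (complexed) band, ``total_*`` the whole lane
    of that channel; bound may not exceed total and totals must be positive.
    """

    bound_550: float
    bound_647: float
    total_550: float
    total_647: float

    def __post_init__(self):
        if self.total_550 <= 0 or self.total_647 <= 0:
            raise ValueError("total signals must be positive")
        if self.bound_550 > self.total_550 or self.bound_647 > self.total_647:
            raise ValueError("bound signal exceeds total signal")
        if self.bound_550 < 0 or self.bound_647 < 0:
            raise ValueError("bound signals must be non-negative")


def emsa_normalized_signal(lane: EmsaLane) -> float:
    """Control-normalized bound-fraction ratio of one lane.

    ``(bound_550 / bound_647) × (total_647 / total_550)`` — invariant under
    rescaling either channel.  A lane with no bound control signal has an
    undefined ratio and raises rather than imputing a value.
    """
    if lane.bound_647 == 0:
        raise ZeroDivisionError(
            "control channel has no bound signal; ratio undefined — flag the "
            "lane instead of imputing")
    return (lane.bound_550 / lane.bound_647) * (lane.total_647 / lane.total_550)


@dataclass
class TitrationFit:
    """Result of a 1:1 isotherm fit: K_D (μM) ± standard error, amplitude,
    baseline and per-point residuals."""

    kd: float
    kd_stderr: float
    amplitude: float
    baseline: float
    residuals: np.ndarray
    model: str = "hyperbolic"

    def __post_init__(self):
        if self.kd <= 0:
            raise ValueError("fitted K_D must be positive")


def _hyperbolic(c, baseline, amplitude, kd):
    return baseline + amplitude * c / (c + kd)


def _quadratic_depletion(fixed_conc):
    def model(c, baseline, amplitude, kd):
        s = c + fixed_conc + kd
        bound = (s - np.sqrt(s * s - 4 * c * fixed_conc)) / (2 * fixed_conc)
        return baseline + amplitude * bound
    return model


def fit_kd(concentrations, responses, depletion_conc: float | None = None
           ) -> TitrationFit:
    """Fit K_D from a titration by nonlinear least squares.

    Parameters
    ----------
    concentrations, responses
        ≥ 5 titration points (μM, normalized signal) spanning the binding
        transition.
    depletion_conc
        If given, fit the quadratic ligand-depletion model with this fixed
        binding-partner concentration (μM) instead of the plain hyperbola.

    The K_D start value is the concentration whose response lies nearest
    half-amplitude, making the fit deterministic given the data.  Flat or
    non-converging data raise :class:`FitError` with diagnostics.
    """
    c = np.asarray(concentrations, dtype=float)
    y = np.asarray(responses, dtype=float)
    if len(c) != len(y):
        raise ValueError("concentrations and responses differ in length")
    if len(c) < 5:
        raise ValueError("need at least 5 titration points")
    if np.any(c <= 0):
        raise ValueError("concentrations must be positive")
    span = y.max() - y.min()
    if span == 0:
        raise FitError("responses are constant; K_D is unidentifiable")

    baseline0 = float(y.min())
    amplitude0 = float(span)
    half = baseline0 + amplitude0 / 2.0
    kd0 = float(c[np.argmin(np.abs(y - half))])
    model = (_hyperbolic if depletion_conc is None
             else _quadratic_depletion(depletion_conc))
    try:
        popt, pcov = curve_fit(
            model, c, y, p0=[baseline0, amplitude0, kd0],
            bounds=([-np.inf, -np.inf, 1e-12], [np.inf, np.inf, np.inf]),
            maxfev=20000)
    except RuntimeError as exc:
        raise FitError(
            f"K_D fit did not converge (start: baseline={baseline0:.4g}, "
            f"amplitude={amplitude0:.4g}, kd={kd0:.4g} μM): {exc}") from exc
    baseline, amplitude, kd = popt
    kd_err = float(np.sqrt(pcov[2, 2])) if np.isfinite(pcov[2, 2]) else np.nan
    residuals = y - model(c, *popt)
    if kd <= 0 or not np.isfinite(kd):
        raise FitError(f"fit returned non-physical K_D = {kd!r}")
    return TitrationFit(
        kd=float(kd), kd_stderr=kd_err, amplitude=float(amplitude),
        baseline=float(baseline), residuals=residuals,
        model="hyperbolic" if depletion_conc is None else "quadratic")


def shuffle_labels(labels: list[str], seed: int) -> dict[str, str]:
    """Blinding helper: map each label to a random opaque name (seeded)."""
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(labels))
    return {labels[i]: f"blinded_{k:03d}" for k, i in enumerate(order)}
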