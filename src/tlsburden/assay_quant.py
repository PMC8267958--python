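"""Bench-assay arithmetic: gap-lesion TLS extent, ddCt fold change, and
one-phase-decay mRNA half-life fitting.

Three small, exactly-specified quantifications that accompany the cohort
analysis:

* TLS extent from the gap-lesion plasmid assay — colony-count ratio times
  the sequenced TLS fraction, as a percent.
* Relative qPCR quantification by the ddCt method (2^-ddCt), target Ct
  normalized to a reference gene in treated vs. control conditions.
* mRNA half-life after transcription shut-off (e.g. Actinomycin D),
  estimated by least-squares fit of the one-phase decay model
  y(t) = plateau + (y0 - plateau) * exp(-k t), half-life = ln 2 / k.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.optimize import curve_fit

__all__ = [
    "TlsAssayCounts",
    "CtQuad",
    "DecayFit",
    "tls_extent",
    "ddct_fold_change",
    "fit_one_phase_decay",
]


@dataclass(frozen=True)
class TlsAssayCounts:
    """Colony counts from one gap-lesion plasmid assay.

    ``kan_colonies``: transformants from the lesion-carrying plasmid (Kan^R
    plates); ``cm_colonies``: transformants from the lesion-free gapped
    control plasmid (Cm^R plates); ``tls_fraction``: fraction of sequenced
    Kan^R repair events classified as translesion synthesis (an input
    number, produced upstream by sequencing).
    """

    kan_colonies: int
    cm_colonies: int
    tls_fraction: float

    def __post_init__(self) -> None:
        if self.kan_colonies < 0:
            raise ValueError("kan_colonies must be >= 0")
        if self.cm_colonies <= 0:
            raise ValueError("cm_colonies must be > 0 (denominator)")
        if not 0.0 <= self.tls_fraction <= 1.0:
            raise ValueError("tls_fraction must be in [0, 1]")


@dataclass(frozen=True)
class CtQuad:
    """The four cycle-threshold values entering a ddCt computation."""

    ct_target_treated: float
    ct_reference_treated: float
    ct_target_control: float
    ct_reference_control: float

    def __post_init__(self) -> None:
        for name in (
            "ct_target_treated",
            "ct_reference_treated",
            "ct_target_control",
            "ct_reference_control",
        ):
            if not math.isfinite(getattr(self, name)):
                raise ValueError(f"{name} must be finite")


@dataclass
class DecayFit:
    """One-phase-decay fit result.

    ``half_life`` = ln(2) / ``rate_constant`` (hours). ``converged`` is
    False (never an exception) when the optimizer fails, the rate constant
    collapses to its lower bound, or no decay is identifiable; in that case
    ``half_life`` is NaN.
    """

    initial_level: float
    rate_constant: float
    plateau: float
    half_life: float
    converged: bool
    residual_sum_squares: float


def tls_extent(counts: TlsAssayCounts) -> float:
    """Percent TLS: 100 x (kan / cm) x tls_fraction.

    The colony ratio measures overall plasmid repair; multiplying by the
    sequenced TLS fraction isolates the translesion-synthesis events.
    """
    return 100.0 * (counts.kan_colonies / counts.cm_colonies) * counts.tls_fraction


def ddct_fold_change(q: CtQuad) -> float:
    """Fold change 2^(-ddCt), target normalized to the reference gene.

    ddCt = (Ct_target,treated - Ct_ref,treated)
         - (Ct_target,control - Ct_ref,control).
    One extra cycle of the normalized target (ddCt = +1) halves the
    estimated abundance.
    """
    ddct = (q.ct_target_treated - q.ct_reference_treated) - (
        q.ct_target_control - q.ct_reference_control
    )
    return float(2.0 ** (-ddct))


def _one_phase_decay(t, y0, k, plateau):
    return plateau + (y0 - plateau) * np.exp(-k * t)


_RATE_FLOOR = 1e-9  # below this the fit is flat: no decay identifiable


def fit_one_phase_decay(
    times: Sequence[float],
    values: Sequence[float],
    fix_plateau_zero: bool = False,
) -> DecayFit:
    """Least-squares one-phase-decay fit of a transcription-shut-off series.

    Parameters
    ----------
    times
        Hours since shut-off, non-decreasing, at least 4 points including
        t = 0. Replicates enter as separate (unweighted) points.
    values
        Expression relative to time 0 (value(0) ~ 1 by convention; any
        positive scale works — half-life is scale-invariant).
    fix_plateau_zero
        Pin the plateau at 0 (full decay) instead of fitting it as a free
        non-negative parameter.

    Notes
    -----
    Deterministic initialization, no random restarts: initial level from the
    first time point, plateau guess from the series minimum, rate constant
    from the log-linear slope of (value - plateau guess). Convergence runs
    essentially to machine precision (1e-15 step/residual tolerances, up to
    10,000 function evaluations) so noiseless series are recovered exactly;
    the plateau bound makes looser tolerances stop visibly short.
    """
    t = np.asarray(times, dtype=float)
    y = np.asarray(values, dtype=float)
    if t.shape != y.shape or t.ndim != 1:
        raise ValueError("times and values must be 1-D sequences of equal length")
    if len(t) < 4:
        raise ValueError("need at least 4 points to fit a 3-parameter decay")
    if np.any(np.diff(t) < 0):
        raise ValueError("time vector must be non-decreasing")

    y0_guess = float(y[t == t.min()].mean())
    plateau_guess = max(float(y.min()), 0.0)
    # log-linear slope on the decaying part, shrinking the plateau guess so
    # the last points stay usable
    amp = y - 0.9 * plateau_guess
    mask = amp > 0
    k_guess = 0.1
    if mask.sum() >= 2 and np.ptp(t[mask]) > 0:
        slope = np.polyfit(t[mask], np.log(amp[mask]), 1)[0]
        if slope < 0:
            k_guess = -float(slope)

    if fix_plateau_zero:
        model = lambda tt, y0, k: _one_phase_decay(tt, y0, k, 0.0)  # noqa: E731
        p0 = [y0_guess, max(k_guess, _RATE_FLOOR)]
        bounds = ([-np.inf, 0.0], [np.inf, np.inf])
    else:
        model = _one_phase_decay
        p0 = [y0_guess, max(k_guess, _RATE_FLOOR), plateau_guess]
        bounds = ([-np.inf, 0.0, 0.0], [np.inf, np.inf, np.inf])

    try:
        popt, _ = curve_fit(
            model,
            t,
            y,
            p0=p0,
            bounds=bounds,
            maxfev=10_000,
            xtol=1e-15,
            ftol=1e-15,
            gtol=1e-15,
        )
        opt_ok = True
    except (RuntimeError, ValueError):
        popt = np.asarray(p0, dtype=float)
        opt_ok = False

    if fix_plateau_zero:
        y0_fit, k_fit = (float(popt[0]), float(popt[1]))
        plateau_fit = 0.0
    else:
        y0_fit, k_fit, plateau_fit = (float(p) for p in popt)

    rss = float(np.sum((model(t, *popt) - y) ** 2))
    scale = max(abs(y0_fit), 1.0)
    identifiable = (
        k_fit > _RATE_FLOOR and (y0_fit - plateau_fit) > 1e-8 * scale
    )
    converged = bool(opt_ok and identifiable)
    half_life = math.log(2) / k_fit if converged else math.nan
    return DecayFit(
        initial_level=y0_fit,
        rate_constant=k_fit,
        plateau=plateau_fit,
        half_life=half_life,
        converged=converged,
        residual_sum_squares=rss,
    )
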