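"""Steady-state surface-plasmon-resonance binding analysis.

Covers referencing (blank subtraction), equilibrium-response extraction from
sensorgrams, one-site (Langmuir 1:1) affinity fitting with Scatchard-plot
initialization and a saturation flag, RU ↔ molar surface-density conversion,
and competition/enhancement metrics for mixture experiments.

Model: at equilibrium the bound response follows the one-site hyperbola
``Req(C) = Bmax·C / (Kd + C)``. The Scatchard linearization
``Req/C = (Bmax − Req)/Kd`` is used only to seed the nonlinear fit — fitting
the linearized form directly is known to bias parameter estimates.

Kinetic (kon/koff) fitting is deliberately out of scope: the analysis is
steady-state only; the kinetic 1:1 model lives in the synthetic-data
generator.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize

from .errors import AnalysisError, FitError
from .io_formats import Isotherm, Sensorgram

#: Response-to-mass convention on carboxymethyl-dextran chips.
PG_PER_MM2_PER_RU = 1.0


@dataclass
class EquilibriumResponse:
    """Equilibrium response extracted from one sensorgram."""

    req_RU: float
    window_start_s: float
    window_end_s: float
    slope_RU_per_s: float
    non_plateau: bool


@dataclass
class FitResult:
    """One-site steady-state fit.

    ``saturable`` is True when the measured concentrations actually reach
    saturation (max C ≥ 2·Kd); otherwise the Kd is extrapolated from the
    curve's trend and flagged ``presumed``.
    """

    Kd_M: float
    Bmax_RU: float
    Kd_se_M: float
    Bmax_se_RU: float
    rss_RU2: float
    saturable: bool
    presumed: bool
    label: str = ""

    def __post_init__(self) -> None:
        assert self.presumed == (not self.saturable)


@dataclass
class CompetitionResult:
    """Effect of a competitor on equilibrium binding (negative = inhibition)."""

    req_alone_RU: float
    req_mix_RU: float
    percent_change: float


@dataclass
class SurfaceDensity:
    immobilized_RU: float
    molar_mass_Da: float
    density_fmol_per_mm2: float


def blank_subtract(active: Sensorgram, reference: Sensorgram) -> Sensorgram:
    """Reference-surface subtraction on the active sensorgram's time grid.

    The reference trace is linearly interpolated onto the active grid; the
    reference recording must span the active one.
    """
    t0, t1 = active.time_s[0], active.time_s[-1]
    if reference.time_s[0] > t0 + 1e-12 or reference.time_s[-1] < t1 - 1e-12:
        raise AnalysisError(
            f"reference time range [{reference.time_s[0]:g}, {reference.time_s[-1]:g}] s "
            f"does not cover active range [{t0:g}, {t1:g}] s"
        )
    ref = np.interp(active.time_s, reference.time_s, reference.response_RU)
    return Sensorgram(
        time_s=active.time_s.copy(),
        response_RU=active.response_RU - ref,
        injection_start_s=active.injection_start_s,
        injection_end_s=active.injection_end_s,
        label=active.label,
    )


def extract_equilibrium(
    s: Sensorgram,
    window_fraction: float = 0.1,
    slope_tol_RU_per_s: float = 0.05,
) -> EquilibriumResponse:
    """Mean response over the final part of the injection phase.

    The window is the last ``window_fraction`` of the injection; if the
    response still drifts there (|slope| above ``slope_tol_RU_per_s``,
    least-squares slope) the result is flagged ``non_plateau``.
    """
    if s.injection_start_s is None or s.injection_end_s is None:
        raise AnalysisError("sensorgram has no injection window metadata")
    if not 0 < window_fraction <= 1:
        raise AnalysisError("window_fraction must be in (0, 1]")
    dur = s.injection_end_s - s.injection_start_s
    w0 = s.injection_end_s - window_fraction * dur
    mask = (s.time_s >= w0) & (s.time_s <= s.injection_end_s)
    if not np.any(mask):
        raise AnalysisError(
            f"no samples in equilibrium window [{w0:g}, {s.injection_end_s:g}] s"
        )
    t, r = s.time_s[mask], s.response_RU[mask]
    slope = 0.0 if t.size < 2 else float(np.polyfit(t, r, 1)[0])
    return EquilibriumResponse(
        req_RU=float(r.mean()),
        window_start_s=float(w0),
        window_end_s=float(s.injection_end_s),
        slope_RU_per_s=slope,
        non_plateau=abs(slope) > slope_tol_RU_per_s,
    )


def _scatchard_init(c: np.ndarray, r: np.ndarray) -> tuple[float, float]:
    """Initial (Kd, Bmax) from the Scatchard line Req/C = (Bmax − Req)/Kd."""
    mask = r > 0
    if mask.sum() >= 2:
        slope, intercept = np.polyfit(r[mask], r[mask] / c[mask], 1)
        if slope < 0 and intercept > 0:
            kd = -1.0 / slope
            return kd, intercept * kd
    # fallback for degenerate Scatchard geometry (e.g. noise-dominated data)
    return float(np.median(c)), float(1.5 * r.max())


def fit_steady_state(iso: Isotherm, saturation_factor: float = 2.0) -> FitResult:
    """Nonlinear least-squares one-site fit of an equilibrium isotherm.

    Req = Bmax·C/(Kd + C), initialized from the Scatchard linearization and
    bounded to positive parameters. ``saturable`` requires the highest
    measured concentration to reach ``saturation_factor × Kd``; below that
    the affinity is only a trend extrapolation (``presumed``).
    """
    if iso.n_points < 3:
        raise AnalysisError(f"isotherm needs >= 3 points, has {iso.n_points}")
    c = iso.concentration_M
    r = iso.req_RU
    kd0, bmax0 = _scatchard_init(c, r)
    kd0 = float(np.clip(kd0, c.min() / 100, c.max() * 100))
    bmax0 = max(bmax0, 1e-12)

    def model(conc, bmax, kd):
        return bmax * conc / (kd + conc)

    try:
        popt, pcov = optimize.curve_fit(
            model, c, r, p0=(bmax0, kd0),
            bounds=((0.0, 0.0), (np.inf, np.inf)),
            maxfev=20000,
        )
    except (RuntimeError, optimize.OptimizeWarning) as exc:
        raise FitError(f"steady-state fit failed to converge: {exc}") from exc
    bmax, kd = float(popt[0]), float(popt[1])
    if not (np.isfinite(bmax) and np.isfinite(kd)) or kd <= 0 or bmax <= 0:
        raise FitError(f"steady-state fit returned invalid parameters Kd={kd}, Bmax={bmax}")
    resid = r - model(c, *popt)
    rss = float(resid @ resid)
    se = np.sqrt(np.abs(np.diag(pcov)))
    saturable = bool(c.max() >= saturation_factor * kd)
    return FitResult(
        Kd_M=kd,
        Bmax_RU=bmax,
        Kd_se_M=float(se[1]),
        Bmax_se_RU=float(se[0]),
        rss_RU2=rss,
        saturable=saturable,
        presumed=not saturable,
        label=iso.label,
    )


def ru_to_density(ru: float, molar_mass_Da: float) -> SurfaceDensity:
    """Convert an immobilization level (RU) to molar surface density.

    1 RU ≈ 1 pg/mm² of bound mass on a dextran chip, so
    density [fmol/mm²] = RU × 1000 / molar mass [Da].
    """
    if ru < 0:
        raise AnalysisError("RU must be non-negative")
    if molar_mass_Da <= 0:
        raise AnalysisError("molar mass must be positive")
    density = ru * PG_PER_MM2_PER_RU * 1.0e3 / molar_mass_Da
    return SurfaceDensity(
        immobilized_RU=float(ru),
        molar_mass_Da=float(molar_mass_Da),
        density_fmol_per_mm2=float(density),
    )


def competition_metrics(req_alone_RU: float, req_mix_RU: float) -> CompetitionResult:
    """Signed percent change of equilibrium binding caused by a competitor.

    ``percent_change = 100·(Req_mix − Req_alone)/Req_alone``; −50 means the
    competitor halves the interaction (50% inhibition), positive values mean
    enhancement (additional independent binding).
    """
    if req_alone_RU <= 0:
        raise AnalysisError("Req_alone must be positive")
    return CompetitionResult(
        req_alone_RU=float(req_alone_RU),
        req_mix_RU=float(req_mix_RU),
        percent_change=float(100.0 * (req_mix_RU - req_alone_RU) / req_alone_RU),
    )
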