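"""Hertz spherical-indentation model, curve fitting, and modulus summaries.

Units are SI throughout: indentation in metres, force in newtons, modulus
in pascals. The contact relation for a rigid sphere of radius R on an
elastic half-space is

    F = (4/3) * E / (1 - nu^2) * sqrt(R) * delta^(3/2)

Fitting is separable: at a fixed contact offset the modulus enters
linearly, so the offset is optimized by bounded scalar minimization with a
closed-form modulus at every step — deterministic, no random initialization.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar
from scipy.stats import shapiro

logger = logging.getLogger(__name__)

__all__ = ["IndentationCurve", "HertzFit", "SamplingPlan", "ModulusSummary",
           "hertz_force", "fit_hertz", "build_plan", "summarize_modulus"]


def hertz_force(delta, E: float, nu: float, R: float):
    """Hertz force (N) at indentation ``delta`` (m, scalar or array).

    Raises ``ValueError`` for negative indentation or non-physical
    parameters (E <= 0, R <= 0, nu outside [0, 0.5]).
    """
    delta = np.asarray(delta, dtype=float)
    if np.any(delta < 0):
        raise ValueError("indentation must be non-negative")
    if not E > 0:
        raise ValueError("E must be > 0")
    if not (0.0 <= nu <= 0.5):
        raise ValueError("nu must lie in [0, 0.5]")
    if not R > 0:
        raise ValueError("R must be > 0")
    out = (4.0 / 3.0) * (E / (1.0 - nu**2)) * math.sqrt(R) * delta**1.5
    return float(out) if out.ndim == 0 else out


@dataclass
class IndentationCurve:
    """One approach curve: indentation depth vs applied force."""

    indentation: np.ndarray   # m, non-negative, strictly increasing
    force: np.ndarray         # N
    bead_radius: float        # m
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.indentation = np.asarray(self.indentation, dtype=float)
        self.force = np.asarray(self.force, dtype=float)
        if self.indentation.ndim != 1 or self.indentation.shape != self.force.shape:
            raise ValueError("indentation and force must be equal-length 1D arrays")
        if len(self.indentation) < 10:
            raise ValueError("curve must contain at least 10 samples")
        if np.any(self.indentation < 0):
            raise ValueError("indentation must be non-negative")
        if np.any(np.diff(self.indentation) <= 0):
            raise ValueError("indentation must be strictly increasing")
        if not self.bead_radius > 0:
            raise ValueError("bead_radius must be > 0")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"delta_m": self.indentation, "force_N": self.force})

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, bead_radius: float,
                   metadata: dict | None = None) -> "IndentationCurve":
        return cls(frame["delta_m"].to_numpy(), frame["force_N"].to_numpy(),
                   bead_radius, metadata or {})


@dataclass(frozen=True)
class HertzFit:
    """Least-squares Hertz fit of one curve."""

    E: float                 # Pa
    contact_offset: float    # m (delta0 >= 0)
    rss: float               # N^2
    converged: bool


def _closed_form(delta0: float, d: np.ndarray, f: np.ndarray):
    """Best slope k (F = k * x, x = max(d - delta0, 0)^1.5) and its RSS."""
    x = np.clip(d - delta0, 0.0, None) ** 1.5
    sxx = float(x @ x)
    if sxx <= 0:
        return 0.0, float(f @ f), 0
    k = float(x @ f) / sxx
    if k < 0:
        k = 0.0
    resid = f - k * x
    return k, float(resid @ resid), int(np.count_nonzero(x > 0))


def fit_hertz(curve: IndentationCurve, nu: float = 0.5,
              max_force: float = 4e-9,
              max_relative_error: float = 0.20) -> HertzFit:
    """Fit Young's modulus and contact offset to one indentation curve.

    The fit range is restricted to forces at or below ``max_force``. The
    contact offset ``delta0`` is clamped non-negative; the modulus is
    obtained in closed form at each trial offset. ``converged`` is False
    when the residual RMS exceeds ``max_relative_error`` of the force span
    or the modulus is non-positive.
    """
    if not (0.0 <= nu <= 0.5):
        raise ValueError("nu must lie in [0, 0.5]")
    sel = curve.force <= max_force
    d, f = curve.indentation[sel], curve.force[sel]
    if len(d) < 10:
        raise ValueError("fewer than 10 samples at or below max_force")

    hi = float(d.max()) * 0.9
    res = minimize_scalar(lambda d0: _closed_form(d0, d, f)[1],
                          bounds=(0.0, hi), method="bounded",
                          options={"xatol": 1e-12})
    candidates = [0.0, float(res.x)]
    delta0 = min(candidates, key=lambda d0: _closed_form(d0, d, f)[1])
    k, rss, n_contact = _closed_form(delta0, d, f)
    if n_contact < 10:
        raise ValueError("fewer than 10 samples above the fitted contact point")
    E = k * 3.0 * (1.0 - nu**2) / (4.0 * math.sqrt(curve.bead_radius))
    span = float(np.max(np.abs(f))) or 1.0
    rel_err = math.sqrt(rss / len(f)) / span
    return HertzFit(E=E, contact_offset=delta0, rss=rss,
                    converged=bool(E > 0 and rel_err <= max_relative_error))


@dataclass(frozen=True)
class SamplingPlan:
    """Indentation sampling layout: a square grid per region, repeated.

    Default mirrors the acquisition plan: 3 regions x 5x5 grid spanning
    100 x 100 µm² x 3 repeats = 225 curves.
    """

    n_regions: int = 3
    grid_side: int = 5
    span_um: float = 100.0
    repeats: int = 3

    def __post_init__(self) -> None:
        for name in ("n_regions", "grid_side", "repeats"):
            v = getattr(self, name)
            if not (isinstance(v, (int, np.integer)) and v > 0):
                raise ValueError(f"{name} must be a positive integer")
        if not self.span_um > 0:
            raise ValueError("span_um must be > 0")

    @property
    def spacing_um(self) -> float:
        return self.span_um / (self.grid_side - 1) if self.grid_side > 1 else 0.0

    @property
    def total(self) -> int:
        return self.n_regions * self.grid_side**2 * self.repeats

    def positions(self):
        """Yield ``(region, x_um, y_um, repeat)`` metadata for every curve."""
        coords = (np.linspace(0.0, self.span_um, self.grid_side)
                  if self.grid_side > 1 else np.array([0.0]))
        for region in range(self.n_regions):
            for y in coords:
                for x in coords:
                    for rep in range(self.repeats):
                        yield {"region": region, "x_um": float(x),
                               "y_um": float(y), "repeat": rep}


def build_plan(n_regions: int = 3, grid_side: int = 5, span_um: float = 100.0,
               repeats: int = 3) -> SamplingPlan:
    """Validated constructor for :class:`SamplingPlan`."""
    return SamplingPlan(n_regions, grid_side, span_um, repeats)


@dataclass(frozen=True)
class ModulusSummary:
    mean: float          # Pa
    sd: float            # Pa
    n: int
    normality_p: float   # Shapiro–Wilk p-value


def summarize_modulus(fits) -> ModulusSummary:
    """Gaussian summary (mean ± SD) of converged fits.

    Shapiro–Wilk normality is computed first and a warning logged when it
    rejects at 0.05; a constant sample (SD = 0) is reported with
    ``normality_p = 1.0`` since it offers no evidence of non-normality.
    """
    E = np.array([f.E for f in fits if f.converged], dtype=float)
    if len(E) < 3:
        raise ValueError("need at least 3 converged fits to summarize")
    if np.ptp(E) == 0.0:
        p = 1.0
    else:
        p = float(shapiro(E).pvalue)
    if p <= 0.05:
        logger.warning("modulus sample fails Shapiro–Wilk normality "
                       "(p = %.3g); Gaussian summary may be misleading", p)
    return ModulusSummary(mean=float(E.mean()), sd=float(E.std(ddof=1)),
                          n=len(E), normality_p=p)
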