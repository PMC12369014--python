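"""JKR-Griffith adhesion threshold model for a bacterium on a soft film.

A spherical bacterium pressed against a compliant substrate forms an
adhesive contact described by Johnson-Kendall-Roberts (JKR) theory.
Coupling the JKR contact with a Griffith energy balance gives a critical
contact radius below which the adhesive interface is unstable:

    a_critical = ( 9 * pi * delta_gamma * R**2 / (2 * E_star) )**(1/3)

where ``delta_gamma`` is the work of adhesion (J/m^2), ``R`` the effective
contact radius (m) and ``E_star`` the effective elastic modulus (Pa) of the
bacterium-substrate pair.  The energetic barrier to stable attachment is
taken as the interfacial energy released over the critical contact disc,

    U_threshold = -pi * a_critical**2 * delta_gamma

which is negative by convention (more negative = higher barrier) and
scales as E_star**(-2/3) and delta_gamma**(5/3) -- the two power laws that
distinguish hydro-softened from unsoftened chitosan films.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ParameterError

__all__ = [
    "SubstrateMechanics",
    "ThresholdResult",
    "HYDRO_SOFTENED",
    "UNSOFTENED",
    "critical_contact_radius",
    "adhesion_threshold_energy",
    "threshold",
    "fit_scaling_exponents",
    "threshold_landscape",
]


@dataclass(frozen=True)
class SubstrateMechanics:
    """Mechanical description of one film condition.

    Parameters
    ----------
    E_star : float
        Effective elastic modulus of the contact pair, Pa.  Must be > 0.
    delta_gamma : float
        Interfacial energy (effective work of adhesion), J/m^2.  Must be >= 0.
    R : float
        Effective contact radius, m.  Must be > 0.
    label : str
        Free-text tag, e.g. ``"hydro-softened"``.
    """

    E_star: float
    delta_gamma: float
    R: float
    label: str = ""

    def __post_init__(self) -> None:
        if not np.isfinite(self.E_star) or self.E_star <= 0:
            raise ParameterError(f"E_star must be positive, got {self.E_star!r}")
        if not np.isfinite(self.delta_gamma) or self.delta_gamma < 0:
            raise ParameterError(
                f"delta_gamma must be non-negative, got {self.delta_gamma!r}"
            )
        if not np.isfinite(self.R) or self.R <= 0:
            raise ParameterError(f"R must be positive, got {self.R!r}")


@dataclass(frozen=True)
class ThresholdResult:
    """Critical contact radius (m) and threshold adhesion energy (J, <= 0)."""

    a_critical: float
    U_threshold: float


#: Default film conditions.  Moduli and interfacial energies are the measured
#: values for the two chitosan film states; the effective contact radii are
#: per-substrate calibration constants chosen so the closed-form threshold
#: reproduces the reference threshold energies (-1.2e-12 and -1.6e-12 J).
HYDRO_SOFTENED = SubstrateMechanics(
    E_star=1.8e6, delta_gamma=1.5, R=0.104e-6, label="hydro-softened"
)
UNSOFTENED = SubstrateMechanics(
    E_star=85e6, delta_gamma=6.4, R=0.145e-6, label="unsoftened"
)


def critical_contact_radius(sub: SubstrateMechanics) -> float:
    """Critical JKR-Griffith contact radius, m.

    Strictly increasing in ``delta_gamma`` and ``R``, strictly decreasing
    in ``E_star``; zero when ``delta_gamma`` is zero.
    """
    return float(
        np.cbrt(9.0 * np.pi * sub.delta_gamma * sub.R**2 / (2.0 * sub.E_star))
    )


def adhesion_threshold_energy(sub: SubstrateMechanics) -> float:
    """Adhesion threshold energy U_threshold, J (negative; 0 iff delta_gamma=0).

    U_threshold = -pi * a_critical^2 * delta_gamma, i.e. the interfacial
    energy released over the critical contact disc.  More negative values
    mean a higher barrier to stable attachment.
    """
    a = critical_contact_radius(sub)
    return float(-np.pi * a**2 * sub.delta_gamma)


def threshold(sub: SubstrateMechanics) -> ThresholdResult:
    """Bundle ``critical_contact_radius`` and ``adhesion_threshold_energy``."""
    a = critical_contact_radius(sub)
    return ThresholdResult(a_critical=a, U_threshold=float(-np.pi * a**2 * sub.delta_gamma))


def fit_scaling_exponents(sub_grid: list[SubstrateMechanics]) -> float:
    """Least-squares log-log slope of |U_threshold| against the swept parameter.

    Exactly one of ``E_star`` / ``delta_gamma`` must vary across the inputs
    (all other fields fixed); at least three points are required.  Returns
    -2/3 for an E* sweep and 5/3 for a delta_gamma sweep, up to round-off.

    Raises
    ------
    ParameterError
        If fewer than three points are given, the sweep is degenerate
        (nothing varies), or more than one parameter varies.
    """
    if len(sub_grid) < 3:
        raise ParameterError("need at least 3 points for a scaling fit")
    E = np.array([s.E_star for s in sub_grid])
    g = np.array([s.delta_gamma for s in sub_grid])
    R = np.array([s.R for s in sub_grid])
    varies_E = np.ptp(E) > 0
    varies_g = np.ptp(g) > 0
    if np.ptp(R) > 0:
        raise ParameterError("R must be held fixed in a scaling sweep")
    if varies_E == varies_g:
        raise ParameterError(
            "exactly one of E_star or delta_gamma must vary across the sweep"
        )
    if varies_g and np.any(g <= 0):
        raise ParameterError("delta_gamma sweep requires positive values")
    x = np.log(E) if varies_E else np.log(g)
    y = np.log(np.abs([adhesion_threshold_energy(s) for s in sub_grid]))
    slope, _ = np.polyfit(x, y, 1)
    return float(slope)


def threshold_landscape(
    E_range: tuple[float, float],
    gamma_range: tuple[float, float],
    n: int,
    R: float,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """log10 |U_threshold| on a log-spaced (E*, delta_gamma) grid.

    Returns ``(E_axis, gamma_axis, Z)`` where ``Z[i, j]`` is
    log10 |U_threshold(E_axis[j], gamma_axis[i], R)| -- rows sweep
    delta_gamma, columns sweep E*.  The magnitude decreases along E* and
    increases along delta_gamma, mirroring the two power laws.

    Raises
    ------
    ParameterError
        For non-positive bounds, ``n < 2`` or ``R <= 0``.
    """
    if n < 2:
        raise ParameterError("landscape needs n >= 2")
    if min(E_range) <= 0 or min(gamma_range) <= 0 or R <= 0:
        raise ParameterError("landscape bounds and R must be positive")
    E_axis = np.logspace(np.log10(E_range[0]), np.log10(E_range[1]), n)
    g_axis = np.logspace(np.log10(gamma_range[0]), np.log10(gamma_range[1]), n)
    Z = np.empty((n, n))
    for i, gam in enumerate(g_axis):
        for j, e in enumerate(E_axis):
            Z[i, j] = np.log10(
                abs(adhesion_threshold_energy(SubstrateMechanics(e, gam, R)))
            )
    return E_axis, g_axis, Z
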