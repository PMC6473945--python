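"""Broken-rod Kratky model for rod cross-section scattering.

Locally cylindrical scatterers (alginate chains and Ca2+-crosslinked
junction zones) produce a cross-section signature that, in a Kratky
representation q^2*I(q) vs q, is a sum of rod terms

    q^2 I(q) = k1 * q * [J1(q*Rc1)/(q*Rc1)]^2
             + k2 * q * [J1(q*Rc2)/(q*Rc2)]^2 + const

where Rc_i is the cross-sectional radius of component i, J1 the first-order
Bessel function of the first kind, k_i an amplitude related to the weight
fraction of component i, and `const` an additive constant in Kratky space.

A single rod term peaks at the universal position q_peak * Rc = x*, with x*
the root of 2x*J0(x) = 3*J1(x) (~1.3566), so a junction zone of radius
~2.7 nm peaks near q = 0.5 nm^-1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize, special

__all__ = [
    "RC_MAX",
    "KRATKY_PEAK_X",
    "BrokenRodParams",
    "bessel_j1",
    "rod_kratky_term",
    "kratky_model",
    "intensity_model",
    "kratky_peak",
]

#: Upper bound on cross-sectional radii accepted as physically meaningful,
#: far above any junction-zone radius; guards against runaway fits.
RC_MAX = 50.0

#: Universal dimensionless Kratky-peak product q_peak * Rc for a single rod
#: term: the positive root of 2x*J0(x) = 3*J1(x).
KRATKY_PEAK_X = 1.3566020274362498


@dataclass(frozen=True)
class BrokenRodParams:
    """Parameter set of the broken-rod Kratky model.

    Parameters
    ----------
    rc1, rc2 : float
        Cross-sectional radii in nm. ``rc1 < rc2`` is enforced for
        two-component parameter sets so component labels cannot switch.
    k1, k2 : float
        Non-negative component amplitudes (intensity units x nm).
    const : float
        Additive non-negative constant in Kratky space.
    n_components : int
        1 or 2. One-component sets must have ``k2 == 0``.
    """

    rc1: float
    k1: float
    const: float = 0.0
    rc2: float = 0.0
    k2: float = 0.0
    n_components: int = 1

    def __post_init__(self) -> None:
        if self.n_components not in (1, 2):
            raise ValueError("n_components must be 1 or 2")
        if not np.isfinite([self.rc1, self.rc2, self.k1, self.k2, self.const]).all():
            raise ValueError("parameters must be finite")
        if not 0.0 < self.rc1 <= RC_MAX:
            raise ValueError(f"rc1 must lie in (0, {RC_MAX}] nm, got {self.rc1}")
        if self.k1 < 0 or self.k2 < 0:
            raise ValueError("amplitudes k1, k2 must be non-negative")
        if self.const < 0:
            raise ValueError("const must be non-negative")
        if self.n_components == 2:
            if not self.rc1 < self.rc2 <= RC_MAX:
                raise ValueError(
                    f"two-component sets need rc1 < rc2 <= {RC_MAX}, "
                    f"got rc1={self.rc1}, rc2={self.rc2}"
                )
        elif self.k2 != 0.0:
            raise ValueError("one-component sets must have k2 == 0")

    @property
    def k_total(self) -> float:
        return self.k1 + self.k2

    @classmethod
    def two_component(
        cls, rc_a: float, k_a: float, rc_b: float, k_b: float, const: float = 0.0
    ) -> "BrokenRodParams":
        """Build a two-component set from unordered (rc, k) pairs.

        The thinner component always becomes component 1, so either
        labelling of the same physical mixture yields the identical object.
        """
        if rc_b < rc_a:
            rc_a, rc_b, k_a, k_b = rc_b, rc_a, k_b, k_a
        return cls(
            rc1=rc_a, k1=k_a, rc2=rc_b, k2=k_b, const=const, n_components=2
        )


def bessel_j1(x):
    """First-order Bessel function of the first kind, J1(x).

    Thin validated front for :func:`scipy.special.j1`; raises on non-finite
    input instead of propagating NaN.
    """
    x = np.asarray(x, dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValueError("bessel_j1 requires finite input")
    return special.j1(x)


def _j1_over_x_sq(x: np.ndarray) -> np.ndarray:
    """[J1(x)/x]^2 with the x -> 0 limit (1/4) taken analytically.

    For |x| < 1e-4 the two-term series J1(x)/x = 1/2 - x^2/16 + O(x^4) is
    exact to better than 1e-17, avoiding the 0/0 at the origin.
    """
    x = np.asarray(x, dtype=float)
    out = np.empty_like(x)
    small = np.abs(x) < 1e-4
    xs = x[small]
    out[small] = (0.5 - xs * xs / 16.0) ** 2
    xl = x[~small]
    out[~small] = (special.j1(xl) / xl) ** 2
    return out


def rod_kratky_term(q, rc: float):
    """Unit-amplitude rod term q*[J1(q*rc)/(q*rc)]^2 in Kratky space.

    Parameters
    ----------
    q : array_like
        Scattering-vector magnitudes, nm^-1, q >= 0.
    rc : float
        Cross-sectional radius, nm, 0 < rc <= 50.

    Returns
    -------
    ndarray
        Kratky ordinate; 0 at q = 0 with initial slope 1/4. Obeys the
        scaling identity term(q, rc) = phi(q*rc)/rc.
    """
    if not (np.isfinite(rc) and 0.0 < rc <= RC_MAX):
        raise ValueError(f"rc must lie in (0, {RC_MAX}] nm, got {rc}")
    q = np.asarray(q, dtype=float)
    if not np.all(np.isfinite(q)) or np.any(q < 0):
        raise ValueError("q must be finite and non-negative")
    return q * _j1_over_x_sq(q * rc)


def kratky_model(q_grid, params: BrokenRodParams):
    """Evaluate the broken-rod model q^2*I(q) on a q grid.

    ``k1*rod_kratky_term(q, rc1) + k2*rod_kratky_term(q, rc2) + const``;
    equals ``const`` at q = 0 and has initial slope (k1 + k2)/4.
    """
    if not isinstance(params, BrokenRodParams):
        raise TypeError("params must be a BrokenRodParams")
    q = np.asarray(q_grid, dtype=float)
    y = params.k1 * rod_kratky_term(q, params.rc1) + params.const
    if params.n_components == 2 and params.k2 > 0:
        y = y + params.k2 * rod_kratky_term(q, params.rc2)
    return y


def intensity_model(q_grid, params: BrokenRodParams):
    """Scattered intensity I(q) = [q^2 I(q)] / q^2 implied by the model.

    The Kratky transform is exactly invertible for q > 0; q = 0 is rejected.
    """
    q = np.asarray(q_grid, dtype=float)
    if np.any(q <= 0):
        raise ValueError("intensity_model requires strictly positive q")
    return kratky_model(q, params) / (q * q)


def kratky_peak(
    params: BrokenRodParams,
    q_min: float,
    q_max: float,
    n_scan: int = 4001,
) -> float | None:
    """Locate the maximum of the background-subtracted Kratky curve.

    Scans ``kratky_model - const`` on a dense grid over [q_min, q_max]
    (>= 2000 points) and refines the maximum by bounded golden-section
    search to |dq| < 1e-4 nm^-1.

    Returns
    -------
    float or None
        Peak position in nm^-1, or None when the curve attains its maximum
        at either window edge (the peak lies outside the window).
    """
    if not (0 < q_min < q_max):
        raise ValueError("require 0 < q_min < q_max")
    n_scan = max(int(n_scan), 2000)
    q = np.linspace(q_min, q_max, n_scan)
    y = kratky_model(q, params) - params.const
    i = int(np.argmax(y))
    if i == 0 or i == n_scan - 1:
        return None
    res = optimize.minimize_scalar(
        lambda qq: -(kratky_model(qq, params) - params.const),
        bounds=(q[i - 1], q[i + 1]),
        method="bounded",
        options={"xatol": 1e-6},
    )
    return float(res.x)
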