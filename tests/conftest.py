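import numpy as np
import pytest
from scipy.integrate import quad

from liftscan import StageKinematics, standard_six_well


@pytest.fixture(scope="session")
def kin():
    """Demonstrator stage: 120 mm/s cap, 100 mm/s**2 derated acceleration."""
    return StageKinematics(v_max=120.0, a=100.0)


@pytest.fixture(scope="session")
def layout():
    return standard_six_well()


def bangbang_velocity(s, L, v_max, a):
    """Velocity at position s of a bang-bang move: the profile itself."""
    return min(v_max, np.sqrt(2.0 * a * s), np.sqrt(2.0 * a * (L - s)))


def _v_near_end(d, L, v_max, a):
    # velocity at distance d *from the stopping end*, written without the
    # L - (L - d) cancellation that loses precision for tiny d
    return min(v_max, np.sqrt(2.0 * a * d), np.sqrt(2.0 * a * (L - d)))


def numeric_move_time(L, v_max, a, upto=None):
    """Numerically integrate dt = ds / v(s) over the velocity profile.

    Independent oracle for the closed-form move time: quadrature of the
    piecewise-constant-acceleration profile, with a sqrt substitution at
    the endpoints where v -> 0.  ``upto`` integrates only to position
    ``upto`` (the time-at-distance oracle).
    """
    if L == 0:
        return 0.0
    s_end = L if upto is None else float(upto)
    m = min(v_max**2 / (2.0 * a), L / 2.0)
    t = 0.0
    # accelerating segment, substitution s = u^2
    hi = min(m, s_end)
    if hi > 0:
        c = 2.0 / np.sqrt(2.0 * a)  # limit of 2u / v(u^2) as u -> 0
        val, _ = quad(
            lambda u: c if u <= 0 else 2.0 * u / bangbang_velocity(u * u, L, v_max, a),
            0.0, np.sqrt(hi), epsabs=1e-13, epsrel=1e-13)
        t += val
    # cruise segment
    if s_end > m:
        hi = min(L - m, s_end)
        if hi > m:
            val, _ = quad(lambda s: 1.0 / bangbang_velocity(s, L, v_max, a),
                          m, hi, epsabs=1e-13, epsrel=1e-13)
            t += val
    # decelerating segment: integrate over the distance-to-end d = u^2
    if s_end > L - m:
        lo = max(L - m, 0.0)
        u_hi = np.sqrt(L - lo)
        u_lo = np.sqrt(max(L - s_end, 0.0))
        c = 2.0 / np.sqrt(2.0 * a)  # limit of 2u / v(u^2) as u -> 0

        def integrand(u):
            return c if u <= 0 else 2.0 * u / _v_near_end(u * u, L, v_max, a)

        val, _ = quad(integrand, u_lo, u_hi, epsabs=1e-13, epsrel=1e-13)
        t += val
    return t
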