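import numpy as np
import pytest

from perfbayes.kinetics import KineticParams, SampledCurve, population_aif

STRESS_DT = 0.012


@pytest.fixture(scope="session")
def times():
    """Stress-resolution time grid over 3 minutes."""
    return np.arange(251) * STRESS_DT


@pytest.fixture(scope="session")
def aif(times):
    return population_aif(times)


@pytest.fixture(scope="session")
def stress_params():
    return KineticParams(fb=3.5, vp=0.08, ve=0.16, ps=1.0)


@pytest.fixture(scope="session")
def rest_params():
    return KineticParams(fb=1.0, vp=0.08, ve=0.16, ps=1.0)


def random_valid_params(rng: np.random.Generator) -> KineticParams:
    """Draw a physiologically plausible parameter set."""
    return KineticParams(
        fb=rng.uniform(0.3, 6.0),
        vp=rng.uniform(0.02, 0.3),
        ve=rng.uniform(0.02, 0.4),
        ps=rng.uniform(0.0, 4.0),
    )


def ode_residue(params: KineticParams, times: np.ndarray) -> np.ndarray:
    """Independent oracle: residue function by direct ODE integration.

    A unit impulse deposits Cp(0+) = F_p/v_p into the plasma compartment;
    integrating the homogeneous two-compartment system and reading out
    (v_p*Cp + v_e*Ce)/F_p gives R_F without using the analytic
    eigen-decomposition under test.
    """
    from scipy.integrate import solve_ivp

    fp = params.fp
    a = np.array(
        [
            [-(fp + params.ps) / params.vp, params.ps / params.vp],
            [params.ps / params.ve, -params.ps / params.ve],
        ]
    )
    sol = solve_ivp(
        lambda t, x: a @ x,
        (0.0, times[-1]),
        [fp / params.vp, 0.0],
        t_eval=times,
        method="LSODA",
        rtol=1e-11,
        atol=1e-13,
    )
    return (params.vp * sol.y[0] + params.ve * sol.y[1]) / fp


def ode_forward(
    params: KineticParams, aif: SampledCurve, times: np.ndarray
) -> np.ndarray:
    """Independent oracle: tissue curve by integrating the forced ODEs."""
    from scipy.integrate import solve_ivp

    fp = params.fp

    def ca(t):
        return np.interp(t - params.tau0, aif.times, aif.values, left=0.0)

    def rhs(t, x):
        cp, ce = x
        return [
            (fp * (ca(t) - cp) + params.ps * (ce - cp)) / params.vp,
            params.ps * (cp - ce) / params.ve,
        ]

    sol = solve_ivp(
        rhs,
        (0.0, times[-1]),
        [0.0, 0.0],
        t_eval=times,
        method="LSODA",
        rtol=1e-10,
        atol=1e-14,
    )
    return params.vp * sol.y[0] + params.ve * sol.y[1]
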