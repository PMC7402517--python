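import numpy as np
import pytest

from roachclock import make_single_oscillator, simulate_sls


@pytest.fixture(scope="session")
def single_osc():
    return make_single_oscillator()


@pytest.fixture(scope="session")
def single_traj_500h(single_osc):
    """Event-detected 500 h trajectory of the canonical single oscillator."""
    return simulate_sls(single_osc, 500.0, sample_step=0.01)


@pytest.fixture(scope="session")
def single_cycle_length(single_traj_500h):
    """Asymptotic cycle length of the uncoupled oscillator at tau = 1 (hours)."""
    st = single_traj_500h.switch_times
    return float(np.mean(np.diff(st[-11::2])))


def dense_oracle(x0, duration, sample_step=0.01, tau=1.0):
    """Blind dense integration of the piecewise single-oscillator field.

    Independent oracle: the mode is re-selected from the protein level at
    every right-hand-side evaluation (no event detection, no matrix
    exponentials) and the system is integrated by a general-purpose adaptive
    solver at tight tolerance.
    """
    from scipy.integrate import solve_ivp

    from roachclock.sls import A_ABOVE, A_BELOW, SWITCH_THRESHOLD

    def f(_, x):
        A = A_BELOW if x[1] <= SWITCH_THRESHOLD else A_ABOVE
        return tau * (A @ x)

    ts = np.arange(0, duration + 1e-9, sample_step)
    sol = solve_ivp(f, (0.0, duration), np.asarray(x0, float), t_eval=ts,
                    rtol=1e-10, atol=1e-12, method="LSODA")
    assert sol.success
    return sol.y.T
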