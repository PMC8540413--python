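import numpy as np
import pytest
from hypothesis import settings

import levipop as lp

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def published_bundle() -> lp.ModelBundle:
    """Final published population model (fixed effects, IIV, residual)."""
    return lp.ModelBundle()


@pytest.fixture(scope="session")
def typical_individual() -> lp.IndividualParams:
    """Typical subject at CrCl 120 mL/min (no random effects)."""
    return lp.IndividualParams(
        subject_id="typ", eta=(0.0, 0.0),
        cl=lp.typical_clearance(120.0), v1=20.7, q=31.9, v2=33.5, crcl=120.0,
    )


@pytest.fixture(scope="session")
def study_27(published_bundle) -> lp.PKDataset:
    """One simulated 27-subject study under the published model."""
    return lp.generate_study(lp.StudyDesign(), published_bundle, seed=20210)


def ode_concentrations(cl, v1, q, v2, dose, tinf, times, n_doses=1, tau=12.0):
    """Independent oracle: numerically integrate the two-compartment ODE
    system with zero-order infusion input and return central concentrations."""
    from scipy.integrate import solve_ivp

    k10, k12, k21 = cl / v1, q / v1, q / v2
    rate = dose / tinf

    def rhs(t, a):
        inp = 0.0
        for i in range(n_doses):
            if i * tau <= t <= i * tau + tinf:
                inp = rate
                break
        return [inp - (k10 + k12) * a[0] + k21 * a[1], k12 * a[0] - k21 * a[1]]

    times = np.asarray(times, dtype=float)
    sol = solve_ivp(rhs, (0.0, float(times.max())), [0.0, 0.0], t_eval=times,
                    rtol=1e-10, atol=1e-12, max_step=min(tinf, tau) / 4)
    return sol.y[0] / v1
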