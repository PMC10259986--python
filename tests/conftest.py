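import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=60,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(20260928)


# ---------------------------------------------------------------------------
# independent brute-force equilibrium oracles (bisection only; no shared code
# path with htdkit.equilibria, which uses closed forms / Brent's method)


def bisect_root(f, lo, hi, iters=200):
    flo = f(lo)
    for _ in range(iters):
        mid = 0.5 * (lo + hi)
        if f(mid) * flo <= 0 and f(lo) * flo >= 0:
            hi = mid
        else:
            lo = mid
            flo = f(lo)
    return 0.5 * (lo + hi)


def oracle_homodimer(total_A, kd_homo):
    """Free monomer by bisection on the mass balance A + 2A^2/kd = total."""
    if total_A == 0:
        return 0.0, 0.0
    f = lambda a: a + 2.0 * a * a / kd_homo - total_A
    a = bisect_root(f, 0.0, total_A)
    return a, a * a / kd_homo


def oracle_competition(total_A, total_B, kd_homo, kd_het):
    """Nested 1-D bisection: outer loop over free A, inner closed forms."""
    if total_A == 0:
        return 0.0, 0.0, total_B, 0.0

    def residual(a):
        a2 = a * a / kd_homo
        b = total_B / (1.0 + a / kd_het)
        ab = a * b / kd_het
        return a + 2.0 * a2 + ab - total_A

    a = bisect_root(residual, 0.0, total_A)
    a2 = a * a / kd_homo
    b = total_B / (1.0 + a / kd_het)
    ab = a * b / kd_het
    return a, a2, b, ab


@pytest.fixture
def equilibrium_oracle():
    return oracle_competition


@pytest.fixture
def homodimer_oracle():
    return oracle_homodimer
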