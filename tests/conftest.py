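import numpy as np
import pytest

from felig import substances


@pytest.fixture(scope="session")
def library():
    """Packaged substance table, keyed by name."""
    return substances.load_substance_table()


@pytest.fixture()
def rng():
    return np.random.default_rng(20160)


def bisect_fe_prime(fe_total, L_T, logK, alpha_sa, tol=1e-16):
    """Independent oracle: bisection on the one-ligand mass-balance residual.

    residual(f) = f(1+alpha) + K f L_T/(1+K f) - Fe_T is strictly increasing
    in f, negative at 0 and positive at Fe_T, so bisection brackets the
    unique root without using the quadratic closed form.
    """
    K = 10.0 ** logK

    def residual(f):
        return f * (1 + alpha_sa) + K * f * L_T / (1 + K * f) - fe_total

    lo, hi = 0.0, fe_total
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if residual(mid) < 0:
            lo = mid
        else:
            hi = mid
        if hi - lo < tol * max(fe_total, 1e-30):
            break
    return 0.5 * (lo + hi)
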