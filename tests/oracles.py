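"""Independent brute-force oracles, written in plain Python ``math`` so they
share no code path with the package's vectorized implementations."""

import math


def hill(e0, emax, ec50, n, x):
    if x == 0:
        return e0
    r = (x / ec50) ** n
    return e0 + (emax - e0) * r / (1.0 + r)


def hill_d2_fd(e0, emax, ec50, n, x, h=None):
    """Central finite-difference second derivative of the Hill form."""
    h = h if h is not None else 1e-5 * max(x, 1.0)
    f = lambda t: hill(e0, emax, ec50, n, t)
    return (f(x + h) - 2.0 * f(x) + f(x - h)) / h**2


def expected_value(f, support, probs):
    """E[f(X)] by explicit enumeration over a finite support."""
    return math.fsum(p * f(x) for x, p in zip(support, probs))


def mean(support, probs):
    return math.fsum(p * x for x, p in zip(support, probs))


def decompose(f, xo_support, xo_probs, xr_support, xr_probs):
    """Assemble (jr, s, js, t_hat) from first principles by enumeration."""
    e_xo = mean(xo_support, xo_probs)
    e_xr = mean(xr_support, xr_probs)
    jr = expected_value(f, xr_support, xr_probs) - f(e_xr)
    s = f(e_xo) - f(e_xr)
    js = expected_value(f, xo_support, xo_probs) - f(e_xo) - jr
    return jr, s, js, jr + s + js
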