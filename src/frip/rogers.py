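"""Rogers random-predator equation for depletion-style consumption trials.

In a trial a single predator is confined with ``N_O`` prey for a period
``T`` and consumed prey are not replaced.  The expected number eaten,
``N_e``, then satisfies the implicit random-predator equation

    N_e = N_O * (1 - exp(a * (N_e * h - T)))

where ``a`` is the attack coefficient (rate of successful search per unit
prey density, per day) and ``h`` the handling time (days per prey item).
The explicit solution uses the principal branch of the Lambert W function:

    N_e = N_O - W(a * h * N_O * exp(-a * (T - h * N_O))) / (a * h)

The asymptote of the curve is ``T / h`` prey per trial, i.e. a maximum
feeding rate of ``1 / h`` prey per day.
"""

from __future__ import annotations

import numpy as np
from scipy import special

__all__ = ["lambert_w0", "rogers_expected_consumption", "rogers_residual"]

#: largest exponent for which exp() is finite in double precision
_EXP_MAX = 700.0


def lambert_w0(x):
    """Principal branch of the Lambert W function on the real axis.

    Solves ``w * exp(w) = x`` for ``x >= -1/e``; accurate to better than
    1e-10 in relative terms.  Accepts scalars or arrays.

    Raises
    ------
    ValueError
        If any element lies below ``-1/e`` (no real solution).
    """
    arr = np.asarray(x, dtype=float)
    if np.any(arr < -np.exp(-1.0) - 1e-12):
        raise ValueError("lambert_w0 requires x >= -1/e on the principal branch")
    w = np.real(special.lambertw(np.maximum(arr, -np.exp(-1.0)), k=0))
    return w if arr.ndim else float(w)


def _lambert_w0_of_exp(log_x):
    """W(exp(log_x)) without overflow, elementwise.

    For moderate arguments this delegates to ``lambert_w0``; for
    ``log_x > ~700`` (where exp overflows) it uses the convergent
    fixed-point iteration ``w <- log_x - log(w)``.
    """
    log_x = np.asarray(log_x, dtype=float)
    w = np.empty_like(log_x)
    small = log_x < _EXP_MAX
    w[small] = np.real(special.lambertw(np.exp(log_x[small]), k=0))
    if np.any(~small):
        z = log_x[~small]
        wb = z - np.log(z)
        for _ in range(100):
            wb_new = z - np.log(wb)
            if np.all(np.abs(wb_new - wb) < 1e-13 * np.abs(wb_new)):
                wb = wb_new
                break
            wb = wb_new
        w[~small] = wb
    return w


def rogers_expected_consumption(a, h, T, n_offered):
    """Expected number of prey consumed under the random-predator model.

    Parameters
    ----------
    a : float
        Attack coefficient (>= 0), per day.
    h : float
        Handling time (>= 0), days per prey item.
    T : float
        Trial duration (> 0), days.
    n_offered : int, float or array
        Initial prey density ``N_O`` (>= 0).

    Returns
    -------
    float or ndarray
        Expected consumption in ``[0, N_O]``.  When ``h == 0`` the
        depletion-only limit ``N_O * (1 - exp(-a T))`` applies; ``a == 0``
        gives zero consumption.
    """
    if not (a >= 0 and h >= 0):
        raise ValueError("attack coefficient and handling time must be non-negative")
    if not T > 0:
        raise ValueError("trial duration T must be positive")
    n0 = np.asarray(n_offered, dtype=float)
    if np.any(n0 < 0):
        raise ValueError("prey density must be non-negative")
    scalar = n0.ndim == 0
    n0 = np.atleast_1d(n0)

    if a == 0:
        ne = np.zeros_like(n0)
    elif h == 0:
        ne = n0 * (-np.expm1(-a * T))
    else:
        ne = np.zeros_like(n0)
        pos = n0 > 0
        log_arg = np.log(a * h * n0[pos]) - a * (T - h * n0[pos])
        w = _lambert_w0_of_exp(log_arg)
        ne[pos] = n0[pos] - w / (a * h)
    ne = np.clip(ne, 0.0, n0)
    return float(ne[0]) if scalar else ne


def rogers_residual(ne, a, h, T, n_offered):
    """Residual of the implicit random-predator equation at ``ne``.

    Zero (to numerical precision) when ``ne`` solves
    ``N_e = N_O (1 - exp(a (N_e h - T)))``; used to verify that the
    explicit Lambert-W solution closes the implicit form.
    """
    ne = np.asarray(ne, dtype=float)
    n0 = np.asarray(n_offered, dtype=float)
    return ne - n0 * (-np.expm1(a * (ne * h - T)))
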