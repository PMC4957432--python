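"""Hot loops for superposing diffusion kernels over many point sources.

These are deliberately plain triple loops: numba compiles them to tight
machine code, and the inner dimension walks contiguous rows of the
precomputed squared-distance matrices.  A pure-Python fallback keeps the
package importable (slowly) without numba.
"""

from __future__ import annotations

import math

import numpy as np

try:  # pragma: no cover - exercised implicitly everywhere
    from numba import njit

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    _HAVE_NUMBA = False

    def njit(*args, **kwargs):
        if args and callable(args[0]):
            return args[0]

        def wrap(f):
            return f

        return wrap


# exponent beyond which exp(-x) is below ~1e-14 and a source block can be
# skipped outright
_EXP_CUTOFF = 32.0


@njit(cache=True, fastmath=True)
def add_pulse_field(out, d2, omegas, ages, D, ks):
    """Accumulate pore-pulse fields at evaluation points.

    out    : (n_eval,) accumulator, uM*
    d2     : (n_eval, n_src) squared great-circle distances, um^2
    omegas : (n_entries, n_src) pulse amounts per history entry, uM*.um^2
    ages   : (n_entries,) entry ages at the evaluation time, s (all > 0)
    """
    n_entries = ages.shape[0]
    n_eval, n_src = d2.shape
    for e in range(n_entries):
        a = ages[e]
        if a <= 0.0:
            continue
        four_da = 4.0 * D * a
        decay = ks * a
        if decay > _EXP_CUTOFF:
            continue
        pref = math.exp(-decay) / (math.pi * four_da)
        for j in range(n_eval):
            acc = 0.0
            for k in range(n_src):
                w = omegas[e, k]
                if w != 0.0:
                    x = d2[j, k] / four_da
                    if x < _EXP_CUTOFF:
                        acc += w * math.exp(-x)
            out[j] += pref * acc


@njit(cache=True, fastmath=True)
def add_event_field(out, d2, src_idx, amounts, ages, D, ks, age_max):
    """Accumulate channel-release fields at evaluation points.

    d2      : (n_eval, n_channels) squared distances to channel positions
    src_idx : (n_events,) channel column per event
    amounts : (n_events,) released amounts, uM*.um^2
    ages    : (n_events,) event ages at the evaluation time, s
    """
    n_events = ages.shape[0]
    n_eval = out.shape[0]
    for m in range(n_events):
        a = ages[m]
        if a <= 0.0 or a > age_max:
            continue
        four_da = 4.0 * D * a
        decay = ks * a
        if decay > _EXP_CUTOFF:
            continue
        pref = amounts[m] * math.exp(-decay) / (math.pi * four_da)
        col = src_idx[m]
        for j in range(n_eval):
            x = d2[j, col] / four_da
            if x < _EXP_CUTOFF:
                out[j] += pref * math.exp(-x)
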