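"""Compiled inner loop of the evolutionary game (numba).

The kernel consumes randomness from a ``numpy.random.Generator`` in the
exact order documented in :mod:`signedgame.dynamics`, using only
``Generator.random()`` — numba draws from the same underlying bit stream
as numpy, so the compiled run is bit-identical to the pure-Python sweep
loop.  Spins and payoffs are float64 throughout (values are exact small
integers in unweighted mode).
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=False)
def run_sweeps(indptr, indices, coeff, spins, f, h0, probs, h_factor, rng):  # pragma: no cover - exercised via dynamics.run
    """Run one sweep per entry of ``probs``.

    Returns ``(hs, best_spins, best_h)``: H after each sweep, plus the
    highest-fitness end-of-sweep assignment seen (the initial state
    included).  Mutates ``spins`` and ``f`` in place.  ``h_factor`` is
    the flip response: flipping node i changes H by ``-h_factor * f_i``
    (4 for undirected fitness, 2 for the once-per-edge directed fitness).
    """
    n = spins.size
    n_sweeps = probs.size
    hs = np.empty(n_sweeps)
    h = h0
    best_h = h0
    best_spins = spins.copy()
    perm = np.empty(n, dtype=np.int64)
    for t in range(n_sweeps):
        r = probs[t]
        for i in range(n):
            perm[i] = i
        for i in range(n - 1, 0, -1):
            j = int(rng.random() * (i + 1))
            tmp = perm[i]
            perm[i] = perm[j]
            perm[j] = tmp
        for k in range(n):
            i = perm[k]
            fi = f[i]
            flip = False
            if fi < 0.0:
                flip = True
            else:
                if rng.random() < r:
                    new = 1.0 if rng.random() < 0.5 else -1.0
                    if new != spins[i]:
                        flip = True
            if flip:
                s_new = -spins[i]
                spins[i] = s_new
                h -= h_factor * fi
                f[i] = -fi
                for p in range(indptr[i], indptr[i + 1]):
                    j2 = indices[p]
                    f[j2] += 2.0 * s_new * coeff[p] * spins[j2]
        hs[t] = h
        if h > best_h:
            best_h = h
            for q in range(n):
                best_spins[q] = spins[q]
    return hs, best_spins, best_h
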