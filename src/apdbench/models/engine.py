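"""Generic fixed-step pacing drivers over a model's compiled ``step`` kernel.

Each model ships a numba-compiled ``step(y, p, istim, dt)`` advancing the
state in place by one hybrid Rush-Larsen / forward-Euler step.  The
drivers below add the 1 Hz pacing protocol around it: a per-phase step
schedule within each cycle, the stimulus window at the cycle start, and
uniform-grid recording of the membrane potential at the study's 0.05 ms
resolution.
"""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = ["make_driver"]


def make_driver(step):
    """Build (pace, record) jitted drivers specialised for ``step``."""

    @njit(cache=False)
    def pace(y, p, n_paces, cycle_length, stim_amp, stim_dur, bounds, dts):
        for _ in range(n_paces):
            for s in range(dts.size):
                dt = dts[s]
                n = int(np.round((bounds[s + 1] - bounds[s]) / dt))
                t = bounds[s]
                for _i in range(n):
                    istim = stim_amp if t < stim_dur - 1e-12 else 0.0
                    step(y, p, istim, dt)
                    t += dt
        return y

    @njit(cache=False)
    def record(y, p, cycle_length, stim_amp, stim_dur, dt_out, bounds, substeps):
        n_out = int(np.round(cycle_length / dt_out)) + 1
        out = np.empty(n_out, dtype=np.float64)
        out[0] = y[0]
        t = 0.0
        for k in range(1, n_out):
            s = 0
            while s < substeps.size - 1 and t >= bounds[s + 1] - 1e-9:
                s += 1
            m = substeps[s]
            dt = dt_out / m
            for _i in range(m):
                istim = stim_amp if t < stim_dur - 1e-12 else 0.0
                step(y, p, istim, dt)
                t += dt
            out[k] = y[0]
        return out

    return pace, record
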