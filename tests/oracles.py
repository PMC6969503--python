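"""Independent brute-force reference implementations used only by tests."""

import numpy as np


def brute_force_detrend(values, n_frames):
    """Explicit loop over every centered (edge-truncated) window mean."""
    total = len(values)
    out = np.empty(total)
    for i in range(total):
        lo = max(i - n_frames // 2, 0)
        hi = min(i - n_frames // 2 + n_frames, total)
        out[i] = values[i] - np.mean(values[lo:hi])
    return out


def grid_search_sse(t, y, tau_range=(22.0, 26.0), lam_range=(0.0, 0.05),
                    A_center=None):
    """Best sum of squared residuals on an (A, tau, phi, lam) lattice.

    Lattice steps: 5% in amplitude (±30% around ``A_center``), 0.25 h in
    period, 0.1 rad in phase, 0.01/h in damping; baseline fixed at the trace
    mean.  SSE is expanded in its quadratic form in A so every lattice point
    is still evaluated exactly.
    """
    b = y.mean()
    base = y - b
    if A_center is None:
        A_center = np.ptp(y) / 2.0
    amps = A_center * (1.0 + 0.05 * np.arange(-6, 7))
    taus = np.arange(tau_range[0], tau_range[1] + 1e-9, 0.25)
    phis = np.arange(0.0, 2 * np.pi, 0.1)
    lams = np.arange(lam_range[0], lam_range[1] + 1e-9, 0.01)
    ss_base = float(base @ base)
    best = np.inf
    for tau in taus:
        c = np.cos(2 * np.pi * t / tau)
        s = np.sin(2 * np.pi * t / tau)
        for lam in lams:
            damp = np.exp(-lam * t)
            dc, ds = damp * c, damp * s
            # carrier(phi) = cos(phi)*dc - sin(phi)*ds
            bc, bs = base @ dc, base @ ds
            cc, ssq, cs = dc @ dc, ds @ ds, dc @ ds
            for phi in phis:
                cp, sp = np.cos(phi), np.sin(phi)
                dot_bc = cp * bc - sp * bs
                norm2 = cp * cp * cc - 2 * cp * sp * cs + sp * sp * ssq
                sse = ss_base - 2 * amps * dot_bc + amps**2 * norm2
                m = float(sse.min())
                if m < best:
                    best = m
    return best
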