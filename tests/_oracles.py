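"""Independent brute-force oracles used by the test suite.

These deliberately avoid the package's quadrature/clustering code paths:
the powder average is recomputed by Monte-Carlo orientation sampling with
its own (trapezoid) cone-variance quadrature, and GHOST grouping is
recomputed as connected components of an explicitly constructed
all-pairs neighborhood graph.
"""

import numpy as np

PLANCK_H = 6.62607015e-34
BOHR_MAGNETON = 9.2740100783e-24
FIELD_PER_GHZ = PLANCK_H * 1e9 / BOHR_MAGNETON * 1e3


def _axial(par, perp, cos2):
    return np.sqrt(par**2 * cos2 + perp**2 * (1.0 - cos2))


def mc_derivative_spectrum(field, domain, tensors, freq_ghz, kappa,
                           n_samples=100_000, seed=0, chunk=2000):
    """Monte-Carlo powder average of the three-line derivative spectrum.

    Orientations are sampled uniformly in cos(theta); the wobble-cone
    variance of the resonance field is computed per orientation by a
    dense trapezoid rule. The result is baseline-corrected and scaled to
    unit absorption area with the same convention as the package.
    """
    a_iso = (tensors.A_xx + tensors.A_yy + tensors.A_zz) / 3.0
    d_a = tensors.A_zz - 0.5 * (tensors.A_xx + tensors.A_yy)
    g_iso = (tensors.g_xx + tensors.g_yy + tensors.g_zz) / 3.0
    d_g = tensors.g_zz - 0.5 * (tensors.g_xx + tensors.g_yy)
    s, pa, pg = domain.S, domain.pA, domain.pg
    apar = pa * (a_iso + 2.0 / 3.0 * s * d_a)
    aperp = pa * (a_iso - 1.0 / 3.0 * s * d_a)
    gpar = pg * (g_iso + 2.0 / 3.0 * s * d_g)
    gperp = pg * (g_iso - 1.0 / 3.0 * s * d_g)
    apar0, aperp0 = pa * tensors.A_zz, pa * 0.5 * (tensors.A_xx + tensors.A_yy)
    gpar0, gperp0 = pg * tensors.g_zz, pg * 0.5 * (tensors.g_xx + tensors.g_yy)
    cos_t0 = min(0.5 * (np.sqrt(1.0 + 8.0 * s) - 1.0), 1.0)

    rng = np.random.default_rng(seed)
    # stratified (jittered) sampling of cos(theta) on [0, 1]: unbiased
    # Monte-Carlo with strongly reduced shot noise
    u = (np.arange(n_samples) + rng.random(n_samples)) / n_samples

    # cone variance depends on orientation only through u = cos(theta):
    # evaluate it by dense trapezoid quadrature on a fine u grid and
    # interpolate to the sampled orientations (the variance is smooth)
    if cos_t0 >= 1.0 - 1e-12:
        var = np.zeros((n_samples, 3))
    else:
        n_u, n_b, n_alpha = 1024, 200, 64
        u_grid = np.linspace(0.0, 1.0, n_u)
        ub = np.linspace(cos_t0, 1.0, n_b)
        alpha = 2.0 * np.pi * (np.arange(n_alpha) + 0.5) / n_alpha
        sb = np.sqrt(np.clip(1.0 - ub**2, 0.0, None))
        sg = np.sqrt(np.clip(1.0 - u_grid**2, 0.0, None))
        ca = np.cos(alpha)
        var_grid = np.empty((n_u, 3))
        step = 128
        for lo_i in range(0, n_u, step):
            uu = u_grid[lo_i:lo_i + step, None, None]
            ss = sg[lo_i:lo_i + step, None, None]
            cpsi = uu * ub[None, :, None] + ss * sb[None, :, None] * ca[None, None, :]
            c2 = cpsi**2
            bg = FIELD_PER_GHZ * freq_ghz / _axial(gpar0, gperp0, c2)
            av = _axial(apar0, aperp0, c2)
            m_bg = bg.mean(axis=(1, 2))
            m_av = av.mean(axis=(1, 2))
            v_bg = (bg**2).mean(axis=(1, 2)) - m_bg**2
            v_av = (av**2).mean(axis=(1, 2)) - m_av**2
            cov = (bg * av).mean(axis=(1, 2)) - m_bg * m_av
            for im, mi in enumerate((-1, 0, 1)):
                var_grid[lo_i:lo_i + step, im] = np.clip(
                    v_bg + mi * mi * v_av - 2.0 * mi * cov, 0.0, None)
        var = np.column_stack([np.interp(u, u_grid, var_grid[:, im])
                               for im in range(3)])

    c2_dir = u**2
    geff = _axial(gpar, gperp, c2_dir)
    aeff = _axial(apar, aperp, c2_dir)
    bc = FIELD_PER_GHZ * freq_ghz / geff
    raw_abs = np.zeros_like(field)
    raw_der = np.zeros_like(field)
    for im, mi in enumerate((-1, 0, 1)):
        b0 = bc - mi * aeff
        gam = np.maximum(domain.W + kappa * domain.tau_c * var[:, im], 1e-6)
        for lo_i in range(0, n_samples, chunk):
            x = field[None, :] - b0[lo_i:lo_i + chunk, None]
            g = gam[lo_i:lo_i + chunk, None]
            den = x**2 + g**2
            raw_abs += (g / den).sum(axis=0)
            raw_der += (-2.0 * g * x / den**2).sum(axis=0)
    norm = 1.0 / (np.pi * 3.0 * n_samples)
    raw_abs *= norm
    raw_der *= norm
    slope = (raw_abs[-1] - raw_abs[0]) / (field[-1] - field[0])
    baseline = raw_abs[0] + slope * (field - field[0])
    corrected = raw_abs - baseline
    area = np.trapezoid(corrected, field)
    return corrected / area, (raw_der - slope) / area


def epsilon_graph_components(s_norm, sub_norm, slice_width, slice_step,
                             radius):
    """Brute-force GHOST grouping oracle.

    Builds the all-pairs graph in which two points are linked when some
    S-slice contains both and their (tau_c, W, pA) subspace distance is
    at most ``radius``; returns connected components as sorted index
    lists (unordered).
    """
    n = len(s_norm)
    starts = []
    start = 0.0
    s_max = float(np.max(s_norm))
    while True:
        starts.append(start)
        if start > s_max:
            break
        start += slice_step
    adj = [[] for _ in range(n)]
    for i in range(n):
        for j in range(i + 1, n):
            together = any(
                st <= s_norm[i] <= st + slice_width and
                st <= s_norm[j] <= st + slice_width
                for st in starts)
            if together and np.linalg.norm(sub_norm[i] - sub_norm[j]) <= radius:
                adj[i].append(j)
                adj[j].append(i)
    seen = np.zeros(n, dtype=bool)
    comps = []
    for i in range(n):
        if seen[i]:
            continue
        stack = [i]
        seen[i] = True
        comp = []
        while stack:
            a = stack.pop()
            comp.append(a)
            for b in adj[a]:
                if not seen[b]:
                    seen[b] = True
                    stack.append(b)
        comps.append(sorted(comp))
    return comps
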