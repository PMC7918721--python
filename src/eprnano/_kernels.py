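"""Numba kernels for the nitroxide lineshape forward model.

These are the hot paths of the fit: every objective evaluation rebuilds a
K-component powder-averaged spectrum from scratch. The kernels are plain
scalar loops so numba can vectorize them; all orientation/cone quadrature
nodes are precomputed in Python and passed in as arrays.

Normalization convention: each component's absorption is baseline-corrected
with the straight line through its sweep-edge values and scaled to unit
area; the analytic per-line integral and endpoint values make this possible
without sampling the absorption on the grid in the derivative-only path.
"""

import numpy as np
from numba import njit

from .constants import FIELD_PER_GHZ

INV_PI = 1.0 / np.pi


@njit(cache=True, fastmath=True)
def cone_moments(u, su, apar0, aperp0, gpar0, gperp0, cos_theta0,
                 freq_ghz, cone_x, cone_w, cone_ca):
    """Second-order moments of the instantaneous resonance field over a cone.

    The probe axis is uniform (in solid angle) inside a cone of half-angle
    theta0 around the local director; the director makes angle theta with
    the field (u = cos theta, su = sin theta). The instantaneous field uses
    the rigid, polarity-corrected tensors (apar0.., gpar0..) and splits as
    B(m_I) = Bg - m_I * a with Bg the g-shifted centre and a the hyperfine
    offset; returns (var_Bg, var_a, cov(Bg, a)) so the caller can form
    Var[B(m_I)] = var_Bg + m_I^2 var_a - 2 m_I cov for every line at once.
    """
    a2par = apar0 * apar0
    a2perp = aperp0 * aperp0
    g2par = gpar0 * gpar0
    g2perp = gperp0 * gperp0
    half = 0.5 * (1.0 - cos_theta0)
    mid = 0.5 * (1.0 + cos_theta0)
    n_alpha = cone_ca.shape[0]
    s_g = 0.0
    s_g2 = 0.0
    s_a = 0.0
    s_a2 = 0.0
    s_ga = 0.0
    wtot = 0.0
    pref = FIELD_PER_GHZ * freq_ghz
    for iu in range(cone_x.shape[0]):
        ub = half * cone_x[iu] + mid  # map GL [-1,1] -> [cos_theta0, 1]
        sb = np.sqrt(max(1.0 - ub * ub, 0.0))
        wu = cone_w[iu]
        for ia in range(n_alpha):
            cpsi = u * ub + su * sb * cone_ca[ia]
            c2 = cpsi * cpsi
            s2 = 1.0 - c2
            b_g = pref / np.sqrt(g2par * c2 + g2perp * s2)
            a_i = np.sqrt(a2par * c2 + a2perp * s2)
            s_g += wu * b_g
            s_g2 += wu * b_g * b_g
            s_a += wu * a_i
            s_a2 += wu * a_i * a_i
            s_ga += wu * b_g * a_i
            wtot += wu
    s_g /= wtot
    s_g2 /= wtot
    s_a /= wtot
    s_a2 /= wtot
    s_ga /= wtot
    var_g = max(s_g2 - s_g * s_g, 0.0)
    var_a = max(s_a2 - s_a * s_a, 0.0)
    cov = s_ga - s_g * s_a
    return var_g, var_a, cov


@njit(cache=True, fastmath=True)
def cone_variance(u, su, mi, apar0, aperp0, gpar0, gperp0, cos_theta0,
                  freq_ghz, cone_x, cone_w, cone_ca):
    """Variance of the instantaneous resonance field of line m_I over the
    wobble cone (see :func:`cone_moments`)."""
    var_g, var_a, cov = cone_moments(u, su, apar0, aperp0, gpar0, gperp0,
                                     cos_theta0, freq_ghz,
                                     cone_x, cone_w, cone_ca)
    return max(var_g + mi * mi * var_a - 2.0 * mi * cov, 0.0)


@njit(cache=True, fastmath=True)
def _line_positions_widths(u_nodes, apar, aperp, gpar, gperp,
                           apar0, aperp0, gpar0, gperp0,
                           cos_theta0, tau_c, w_res, kappa, freq_ghz,
                           cone_x, cone_w, cone_ca, b0_out, gam_out):
    """Centres and half-widths of all (theta node, m_I) Lorentzians."""
    a2par = apar * apar
    a2perp = aperp * aperp
    g2par = gpar * gpar
    g2perp = gperp * gperp
    rigid = cos_theta0 >= 1.0 - 1e-12
    for j in range(u_nodes.shape[0]):
        u = u_nodes[j]
        u2 = u * u
        su2 = 1.0 - u2
        su = np.sqrt(max(su2, 0.0))
        geff = np.sqrt(g2par * u2 + g2perp * su2)
        aeff = np.sqrt(a2par * u2 + a2perp * su2)
        bc = FIELD_PER_GHZ * freq_ghz / geff
        if rigid:
            var_g = 0.0
            var_a = 0.0
            cov = 0.0
        else:
            var_g, var_a, cov = cone_moments(u, su, apar0, aperp0,
                                             gpar0, gperp0, cos_theta0,
                                             freq_ghz, cone_x, cone_w, cone_ca)
        for im, mi in enumerate((-1, 0, 1)):
            var = max(var_g + mi * mi * var_a - 2.0 * mi * cov, 0.0)
            gam = w_res + kappa * tau_c * var
            if gam < 1e-6:
                gam = 1e-6
            b0_out[j, im] = bc - mi * aeff
            gam_out[j, im] = gam


@njit(cache=True, fastmath=True)
def component_derivative(field, u_nodes, u_weights,
                         apar, aperp, gpar, gperp,
                         apar0, aperp0, gpar0, gperp0,
                         cos_theta0, tau_c, w_res, kappa, freq_ghz,
                         cone_x, cone_w, cone_ca,
                         b0_buf, gam_buf, out_der):
    """Raw first-derivative lineshape of one component (overwrites out_der).

    Returns (area, a_left, a_right): the analytic window integral of the
    corresponding absorption and its values at the sweep edges, from which
    the caller derives the baseline-corrected unit-area normalization.
    """
    n = field.shape[0]
    for i in range(n):
        out_der[i] = 0.0
    _line_positions_widths(u_nodes, apar, aperp, gpar, gperp,
                           apar0, aperp0, gpar0, gperp0,
                           cos_theta0, tau_c, w_res, kappa, freq_ghz,
                           cone_x, cone_w, cone_ca, b0_buf, gam_buf)
    b_lo = field[0]
    b_hi = field[n - 1]
    area = 0.0
    a_left = 0.0
    a_right = 0.0
    for j in range(u_nodes.shape[0]):
        wgt = u_weights[j] / 3.0  # three equally weighted 14N lines
        for im in range(3):
            b0 = b0_buf[j, im]
            gam = gam_buf[j, im]
            g2 = gam * gam
            amp_d = wgt * 2.0 * INV_PI * gam
            for i in range(n):
                x = field[i] - b0
                inv = 1.0 / (x * x + g2)
                out_der[i] -= amp_d * x * inv * inv
            xl = b_lo - b0
            xr = b_hi - b0
            area += wgt * INV_PI * (np.arctan(xr / gam) - np.arctan(xl / gam))
            a_left += wgt * INV_PI * gam / (xl * xl + g2)
            a_right += wgt * INV_PI * gam / (xr * xr + g2)
    return area, a_left, a_right


@njit(cache=True, fastmath=True)
def component_absorption(field, u_nodes, u_weights,
                         apar, aperp, gpar, gperp,
                         apar0, aperp0, gpar0, gperp0,
                         cos_theta0, tau_c, w_res, kappa, freq_ghz,
                         cone_x, cone_w, cone_ca,
                         b0_buf, gam_buf, out_abs):
    """Raw absorption lineshape sampled on the grid (overwrites out_abs)."""
    n = field.shape[0]
    for i in range(n):
        out_abs[i] = 0.0
    _line_positions_widths(u_nodes, apar, aperp, gpar, gperp,
                           apar0, aperp0, gpar0, gperp0,
                           cos_theta0, tau_c, w_res, kappa, freq_ghz,
                           cone_x, cone_w, cone_ca, b0_buf, gam_buf)
    for j in range(u_nodes.shape[0]):
        wgt = u_weights[j] / 3.0
        for im in range(3):
            b0 = b0_buf[j, im]
            gam = gam_buf[j, im]
            g2 = gam * gam
            amp_a = wgt * INV_PI * gam
            for i in range(n):
                x = field[i] - b0
                out_abs[i] += amp_a / (x * x + g2)


@njit(cache=True, fastmath=True)
def multi_component_derivative(field, params,
                               a_xx, a_yy, a_zz, g_xx, g_yy, g_zz,
                               kappa, freq_ghz, u_nodes, u_weights,
                               cone_x, cone_w, cone_ca,
                               b0_buf, gam_buf, tmp, out):
    """Normalized K-component first-derivative spectrum (overwrites out).

    params is a (K, 6) array of rows (S, tau_c, pA, pg, W, d); each
    component is baseline-corrected, scaled to unit absorption area and
    added with weight d. Returns False if any parameter row produced a
    degenerate (non-positive-area) component.
    """
    n = field.shape[0]
    for i in range(n):
        out[i] = 0.0
    a_iso = (a_xx + a_yy + a_zz) / 3.0
    d_a = a_zz - 0.5 * (a_xx + a_yy)
    g_iso = (g_xx + g_yy + g_zz) / 3.0
    d_g = g_zz - 0.5 * (g_xx + g_yy)
    span = field[n - 1] - field[0]
    for k in range(params.shape[0]):
        s = params[k, 0]
        tau_c = params[k, 1]
        p_a = params[k, 2]
        p_g = params[k, 3]
        w_res = params[k, 4]
        d_k = params[k, 5]
        apar = p_a * (a_iso + (2.0 / 3.0) * s * d_a)
        aperp = p_a * (a_iso - (1.0 / 3.0) * s * d_a)
        gpar = p_g * (g_iso + (2.0 / 3.0) * s * d_g)
        gperp = p_g * (g_iso - (1.0 / 3.0) * s * d_g)
        apar0 = p_a * a_zz
        aperp0 = p_a * 0.5 * (a_xx + a_yy)
        gpar0 = p_g * g_zz
        gperp0 = p_g * 0.5 * (g_xx + g_yy)
        cos_t0 = 0.5 * (np.sqrt(1.0 + 8.0 * s) - 1.0)
        if cos_t0 > 1.0:
            cos_t0 = 1.0
        area, a_l, a_r = component_derivative(
            field, u_nodes, u_weights, apar, aperp, gpar, gperp,
            apar0, aperp0, gpar0, gperp0, cos_t0, tau_c, w_res, kappa,
            freq_ghz, cone_x, cone_w, cone_ca, b0_buf, gam_buf, tmp)
        slope = (a_r - a_l) / span
        area_c = area - 0.5 * (a_l + a_r) * span
        if area_c <= 0.0:
            return False
        scale = d_k / area_c
        for i in range(n):
            out[i] += scale * (tmp[i] - slope)
    return True
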