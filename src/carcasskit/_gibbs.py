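"""Numba kernels for the single- and two-trait animal-model Gibbs samplers.

Location parameters (fixed-effect levels and breeding values) are sampled
single-site in pedigree order from their scalar normal full conditionals;
variance components from scaled inverse chi-square (one trait) or
inverse-Wishart (two traits) full conditionals.  The kernels work on flat
CSR-style index arrays so the hot loops contain no Python objects:

* ``lev_indptr``/``lev_records`` — records belonging to each fixed-effect
  level (all factors concatenated);
* ``an_indptr``/``an_records`` — records belonging to each pedigree animal
  (empty for non-phenotyped animals);
* ``ai_indptr``/``ai_indices``/``ai_data`` — the sparse A-inverse.

Return status codes: 0 ok, >0 the 1-based cycle at which a non-finite
variance was produced.
"""

import numba
import numpy as np

__all__ = ["single_trait_kernel", "two_trait_kernel"]


@numba.njit(cache=True)
def single_trait_kernel(
    y,
    lev_indptr,
    lev_records,
    an_indptr,
    an_records,
    ai_indptr,
    ai_indices,
    ai_data,
    n_cycles,
    burn_in,
    thin,
    va0,
    ve0,
    nu_a,
    ss_a,
    nu_e,
    ss_e,
    seed,
    out,
):
    np.random.seed(seed)
    n = y.shape[0]
    n_levels = lev_indptr.shape[0] - 1
    q = an_indptr.shape[0] - 1
    beta = np.zeros(n_levels)
    u = np.zeros(q)
    e = y.copy()
    va, ve = va0, ve0
    kept = 0
    for cycle in range(n_cycles):
        # fixed-effect levels (dummy covariates: x'x = record count)
        for j in range(n_levels):
            lo, hi = lev_indptr[j], lev_indptr[j + 1]
            cnt = hi - lo
            if cnt == 0:
                continue
            s = 0.0
            for k in range(lo, hi):
                s += e[lev_records[k]]
            old = beta[j]
            new = s / cnt + old + np.random.standard_normal() * np.sqrt(ve / cnt)
            diff = new - old
            beta[j] = new
            for k in range(lo, hi):
                e[lev_records[k]] -= diff
        # breeding values, pedigree order
        lam = ve / va
        for i in range(q):
            aii = 0.0
            s_rel = 0.0
            for k in range(ai_indptr[i], ai_indptr[i + 1]):
                j = ai_indices[k]
                if j == i:
                    aii = ai_data[k]
                else:
                    s_rel += ai_data[k] * u[j]
            lo, hi = an_indptr[i], an_indptr[i + 1]
            cnt = hi - lo
            s = 0.0
            for k in range(lo, hi):
                s += e[an_records[k]]
            dii = cnt + lam * aii
            mean = (s + cnt * u[i] - lam * s_rel) / dii
            new = mean + np.random.standard_normal() * np.sqrt(ve / dii)
            diff = new - u[i]
            u[i] = new
            for k in range(lo, hi):
                e[an_records[k]] -= diff
        # variance components
        uau = 0.0
        for i in range(q):
            for k in range(ai_indptr[i], ai_indptr[i + 1]):
                uau += u[i] * ai_data[k] * u[ai_indices[k]]
        va = (uau + ss_a) / np.random.chisquare(q + nu_a)
        sse = 0.0
        for r in range(n):
            sse += e[r] * e[r]
        ve = (sse + ss_e) / np.random.chisquare(n + nu_e)
        if not (np.isfinite(va) and np.isfinite(ve) and va > 0.0 and ve > 0.0):
            return cycle + 1
        if cycle + 1 > burn_in and (cycle + 1 - burn_in) % thin == 0:
            out[kept, 0] = va
            out[kept, 1] = ve
            out[kept, 2] = va / (va + ve)
            kept += 1
    return 0


@numba.njit(cache=True, inline="always")
def _inv2(m, out):
    det = m[0, 0] * m[1, 1] - m[0, 1] * m[1, 0]
    out[0, 0] = m[1, 1] / det
    out[1, 1] = m[0, 0] / det
    out[0, 1] = -m[0, 1] / det
    out[1, 0] = -m[1, 0] / det


@numba.njit(cache=True)
def _inv_wishart2(df, scale):
    """Draw from IW(df, scale) for a 2x2 scale matrix (Bartlett form)."""
    sinv = np.empty((2, 2))
    _inv2(scale, sinv)
    # Cholesky of sinv
    l11 = np.sqrt(sinv[0, 0])
    l21 = sinv[1, 0] / l11
    l22 = np.sqrt(sinv[1, 1] - l21 * l21)
    a11 = np.sqrt(np.random.chisquare(df))
    a21 = np.random.standard_normal()
    a22 = np.sqrt(np.random.chisquare(df - 1.0))
    # T = L @ A (lower triangular), W = T T'
    t11 = l11 * a11
    t21 = l21 * a11 + l22 * a21
    t22 = l22 * a22
    w = np.empty((2, 2))
    w[0, 0] = t11 * t11
    w[0, 1] = t11 * t21
    w[1, 0] = t11 * t21
    w[1, 1] = t21 * t21 + t22 * t22
    out = np.empty((2, 2))
    _inv2(w, out)
    return out


@numba.njit(cache=True)
def two_trait_kernel(
    y,
    lev_indptr,
    lev_records,
    an_indptr,
    an_records,
    ai_indptr,
    ai_indices,
    ai_data,
    n_cycles,
    burn_in,
    thin,
    g_init,
    r_init,
    nu_g,
    s_g,
    nu_r,
    s_r,
    seed,
    out,
):
    np.random.seed(seed)
    n = y.shape[0]
    n_levels = lev_indptr.shape[0] - 1
    q = an_indptr.shape[0] - 1
    beta = np.zeros((n_levels, 2))
    u = np.zeros((q, 2))
    e = y.copy()
    g = g_init.copy()
    r = r_init.copy()
    ginv = np.empty((2, 2))
    rinv = np.empty((2, 2))
    _inv2(g, ginv)
    _inv2(r, rinv)
    kept = 0
    for cycle in range(n_cycles):
        for t in range(2):
            o = 1 - t
            rtt = rinv[t, t]
            rto = rinv[t, o]
            gtt = ginv[t, t]
            gto = ginv[t, o]
            for j in range(n_levels):
                lo, hi = lev_indptr[j], lev_indptr[j + 1]
                cnt = hi - lo
                if cnt == 0:
                    continue
                s1 = 0.0
                s2 = 0.0
                for k in range(lo, hi):
                    rec = lev_records[k]
                    s1 += e[rec, t]
                    s2 += e[rec, o]
                prec = cnt * rtt
                mean = (rtt * (s1 + cnt * beta[j, t]) + rto * s2) / prec
                new = mean + np.random.standard_normal() / np.sqrt(prec)
                diff = new - beta[j, t]
                beta[j, t] = new
                for k in range(lo, hi):
                    e[lev_records[k], t] -= diff
            for i in range(q):
                aii = 0.0
                s_rel_t = 0.0
                s_rel_o = 0.0
                for k in range(ai_indptr[i], ai_indptr[i + 1]):
                    jj = ai_indices[k]
                    if jj == i:
                        aii = ai_data[k]
                    else:
                        s_rel_t += ai_data[k] * u[jj, t]
                        s_rel_o += ai_data[k] * u[jj, o]
                lo, hi = an_indptr[i], an_indptr[i + 1]
                cnt = hi - lo
                s1 = 0.0
                s2 = 0.0
                for k in range(lo, hi):
                    rec = an_records[k]
                    s1 += e[rec, t]
                    s2 += e[rec, o]
                prec = cnt * rtt + gtt * aii
                rhs = (
                    rtt * (s1 + cnt * u[i, t])
                    + rto * s2
                    - gto * aii * u[i, o]
                    - gtt * s_rel_t
                    - gto * s_rel_o
                )
                new = rhs / prec + np.random.standard_normal() / np.sqrt(prec)
                diff = new - u[i, t]
                u[i, t] = new
                for k in range(lo, hi):
                    e[an_records[k], t] -= diff
        # genetic covariance: IW(q + nu_g, U'A^-1 U + S_g)
        sc = np.zeros((2, 2))
        for i in range(q):
            for k in range(ai_indptr[i], ai_indptr[i + 1]):
                jj = ai_indices[k]
                v = ai_data[k]
                sc[0, 0] += u[i, 0] * v * u[jj, 0]
                sc[0, 1] += u[i, 0] * v * u[jj, 1]
                sc[1, 1] += u[i, 1] * v * u[jj, 1]
        sc[1, 0] = sc[0, 1]
        g = _inv_wishart2(q + nu_g, sc + s_g)
        # residual covariance: IW(n + nu_r, E'E + S_r)
        se = np.zeros((2, 2))
        for rec in range(n):
            se[0, 0] += e[rec, 0] * e[rec, 0]
            se[0, 1] += e[rec, 0] * e[rec, 1]
            se[1, 1] += e[rec, 1] * e[rec, 1]
        se[1, 0] = se[0, 1]
        r = _inv_wishart2(n + nu_r, se + s_r)
        ok = (
            np.isfinite(g).all()
            and np.isfinite(r).all()
            and g[0, 0] > 0.0
            and g[1, 1] > 0.0
            and r[0, 0] > 0.0
            and r[1, 1] > 0.0
        )
        if not ok:
            return cycle + 1
        _inv2(g, ginv)
        _inv2(r, rinv)
        if cycle + 1 > burn_in and (cycle + 1 - burn_in) % thin == 0:
            out[kept, 0] = g[0, 0]
            out[kept, 1] = g[0, 1]
            out[kept, 2] = g[1, 1]
            out[kept, 3] = r[0, 0]
            out[kept, 4] = r[0, 1]
            out[kept, 5] = r[1, 1]
            out[kept, 6] = g[0, 0] / (g[0, 0] + r[0, 0])
            out[kept, 7] = g[1, 1] / (g[1, 1] + r[1, 1])
            out[kept, 8] = g[0, 1] / np.sqrt(g[0, 0] * g[1, 1])
            out[kept, 9] = r[0, 1] / np.sqrt(r[0, 0] * r[1, 1])
            out[kept, 10] = (g[0, 1] + r[0, 1]) / np.sqrt(
                (g[0, 0] + r[0, 0]) * (g[1, 1] + r[1, 1])
            )
            kept += 1
    return 0
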