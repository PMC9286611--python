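"""Numba Metropolis-within-Gibbs kernel for data-augmentation SCR models.

One compiled routine runs a single chain for any model variant: presence of
each data stream is signalled by flags, and absent streams are passed as
empty arrays.  Updates per iteration:

* z_i full conditional for augmented individuals (marginal components are
  handled through an incrementally maintained detector rate-sum T and, for
  presence-absence, a log-survival matrix LG);
* psi by its conjugate Beta full conditional;
* s_i by bivariate random walk (adaptive scale during burn-in only) for
  included individuals, and a uniform redraw from the prior for excluded
  ones (their likelihood is flat in s);
* latent group labels and their Beta-conjugate proportion;
* scalar detection parameters by random walk on log/logit scales with prior
  bounds, or by independence proposals over supplied grids (used to validate
  the sampler against exhaustive enumeration on discretized instances).
  Each proposal recomputes only the likelihood components that parameter
  enters; T and LG are rebuilt from scratch each iteration so incremental
  drift cannot accumulate beyond one sweep.

Constants of the data (binomial coefficients, factorials, operation-matrix
terms) are omitted here; they cancel in every acceptance ratio.  The wrapper
adds them back when absolute joint densities are required.
"""

import numpy as np
from numba import njit

LOG0 = -1.0e100


@njit(cache=True)
def _ilogit(x):
    if x >= 0.0:
        return 1.0 / (1.0 + np.exp(-x))
    e = np.exp(x)
    return e / (1.0 + e)


@njit(cache=True)
def _logistic_logpdf(x):
    t = abs(x)
    return -t - 2.0 * np.log1p(np.exp(-t))


@njit(cache=True, fastmath=True)
def _gen_base(a0, a1, geff, gbase):
    for gg in range(gbase.shape[0]):
        for j in range(gbase.shape[1]):
            gbase[gg, j] = _ilogit(a0[gg] + a1 * geff[j])


@njit(cache=True, fastmath=True)
def _ll_gen_row(sx, sy, gi, gx, gy, gbase, yrow, Kgen, sigma):
    s2 = 2.0 * sigma[gi] * sigma[gi]
    ll = 0.0
    for j in range(gx.shape[0]):
        d2 = (sx - gx[j]) ** 2 + (sy - gy[j]) ** 2
        p = gbase[gi, j] * np.exp(-d2 / s2)
        y = yrow[j]
        if y > 0:
            if p <= 0.0:
                return LOG0
            ll += y * np.log(p) + (Kgen - y) * np.log1p(-p)
        else:
            ll += Kgen * np.log1p(-p)
    return ll


@njit(cache=True, fastmath=True)
def _ll_mark_row(sx, sy, gi, mx, my, yrow, Kmark, markp, mark_pois, sigma):
    s2 = 2.0 * sigma[gi] * sigma[gi]
    ll = 0.0
    for j in range(mx.shape[0]):
        d2 = (sx - mx[j]) ** 2 + (sy - my[j]) ** 2
        kern = np.exp(-d2 / s2)
        y = yrow[j]
        if mark_pois:
            lam = markp[gi] * kern * Kmark
            if y > 0:
                if lam <= 0.0:
                    return LOG0
                ll += y * np.log(lam) - lam
            else:
                ll += -lam
        else:
            p = markp[gi] * kern
            if y > 0:
                if p <= 0.0:
                    return LOG0
                ll += y * np.log(p) + (Kmark - y) * np.log1p(-p)
            else:
                ll += Kmark * np.log1p(-p)
    return ll


@njit(cache=True, fastmath=True)
def _ll_res_row(sx, sy, gi, cx, cy, Yrow, Erow, lamr, sigma):
    s2 = 2.0 * sigma[gi] * sigma[gi]
    ll = 0.0
    for j in range(cx.shape[0]):
        d2 = (sx - cx[j]) ** 2 + (sy - cy[j]) ** 2
        lam = lamr[gi] * np.exp(-d2 / s2)
        if Yrow[j] > 0.0:
            if lam <= 0.0:
                return LOG0
            ll += Yrow[j] * np.log(lam) - lam * Erow[j]
        else:
            ll += -lam * Erow[j]
    return ll


@njit(cache=True, fastmath=True)
def _ll_tel_row(sx, sy, gi, tn, tsx, tsy, tss, sigma):
    if tn <= 0.0:
        return 0.0
    s2 = sigma[gi] * sigma[gi]
    r2 = tss - 2.0 * (sx * tsx + sy * tsy) + tn * (sx * sx + sy * sy)
    return -tn * np.log(2.0 * np.pi * s2) - r2 / (2.0 * s2)


@njit(cache=True, fastmath=True)
def _cam_kvec(sx, sy, gi, cx, cy, lamr, sigma, out):
    s2 = 2.0 * sigma[gi] * sigma[gi]
    l0 = lamr[gi]
    for j in range(cx.shape[0]):
        d2 = (sx - cx[j]) ** 2 + (sy - cy[j]) ** 2
        out[j] = l0 * np.exp(-d2 / s2)


@njit(cache=True, fastmath=True)
def _cnt_ll(T, ncnt, Opj):
    ll = 0.0
    for j in range(T.shape[0]):
        if ncnt[j] > 0.0:
            if T[j] <= 0.0:
                return LOG0
            ll += ncnt[j] * np.log(T[j])
        ll += -T[j] * Opj[j]
    return ll


@njit(cache=True, fastmath=True)
def _spa_rowfill(sx, sy, gi, cx, cy, opmat, p0spa, sigma, out):
    s2 = 2.0 * sigma[gi] * sigma[gi]
    for j in range(cx.shape[0]):
        d2 = (sx - cx[j]) ** 2 + (sy - cy[j]) ** 2
        p = p0spa[gi] * np.exp(-d2 / s2)
        for k in range(opmat.shape[1]):
            out[j, k] = np.log1p(-p * opmat[j, k])


@njit(cache=True, fastmath=True)
def _spa_ll(LG, yspa):
    ll = 0.0
    for j in range(LG.shape[0]):
        for k in range(LG.shape[1]):
            if yspa[j, k] > 0:
                if LG[j, k] >= 0.0:
                    return LOG0
                ll += np.log(-np.expm1(LG[j, k]))
            else:
                ll += LG[j, k]
    return ll


# -- component totals --------------------------------------------------------


@njit(cache=True, fastmath=True)
def _tot_gen(z, s, g, gx, gy, gbase, ygen, Kgen, sigma):
    ll = 0.0
    for i in range(z.shape[0]):
        if z[i] == 1:
            ll += _ll_gen_row(s[i, 0], s[i, 1], g[i], gx, gy, gbase, ygen[i], Kgen, sigma)
    return ll


@njit(cache=True, fastmath=True)
def _tot_mark(z, s, g, mx, my, ymark, Kmark, markp, mark_pois, sigma):
    ll = 0.0
    for i in range(z.shape[0]):
        if z[i] == 1:
            ll += _ll_mark_row(s[i, 0], s[i, 1], g[i], mx, my, ymark[i], Kmark, markp, mark_pois, sigma)
    return ll


@njit(cache=True, fastmath=True)
def _tot_res(res_mask, s, g, cx, cy, Yres, Eres, lamr, sigma):
    ll = 0.0
    for i in range(res_mask.shape[0]):
        if res_mask[i]:
            ll += _ll_res_row(s[i, 0], s[i, 1], g[i], cx, cy, Yres[i], Eres[i], lamr, sigma)
    return ll


@njit(cache=True, fastmath=True)
def _tot_tel(s, g, tn, tsx, tsy, tss, sigma):
    ll = 0.0
    for i in range(tn.shape[0]):
        if tn[i] > 0.0:
            ll += _ll_tel_row(s[i, 0], s[i, 1], g[i], tn[i], tsx[i], tsy[i], tss[i], sigma)
    return ll


@njit(cache=True, fastmath=True)
def _build_T(z, s, g, in_pool, cx, cy, lamr, sigma, T):
    T[:] = 0.0
    for i in range(z.shape[0]):
        if z[i] == 1 and in_pool[i]:
            s2 = 2.0 * sigma[g[i]] * sigma[g[i]]
            l0 = lamr[g[i]]
            for j in range(cx.shape[0]):
                d2 = (s[i, 0] - cx[j]) ** 2 + (s[i, 1] - cy[j]) ** 2
                T[j] += l0 * np.exp(-d2 / s2)


@njit(cache=True, fastmath=True)
def _build_LG(z, s, g, in_pool, cx, cy, opmat, p0spa, sigma, LG, rowbuf):
    LG[:, :] = 0.0
    for i in range(z.shape[0]):
        if z[i] == 1 and in_pool[i]:
            _spa_rowfill(s[i, 0], s[i, 1], g[i], cx, cy, opmat, p0spa, sigma, rowbuf)
            for j in range(cx.shape[0]):
                for k in range(opmat.shape[1]):
                    LG[j, k] += rowbuf[j, k]


@njit(cache=True, fastmath=True)
def _row_ll(
    i, sx, sy, gi,
    has_gen, gx, gy, gbase, ygen, Kgen,
    has_mark, mark_pois, mx, my, ymark, Kmark, markp,
    has_res, res_mask, cx, cy, Yres, Eres, lamr,
    has_tel, tn, tsx, tsy, tss,
    sigma,
):
    """Individual i's likelihood rows (excluding marginal count/spa terms)."""
    ll = 0.0
    if has_gen:
        ll += _ll_gen_row(sx, sy, gi, gx, gy, gbase, ygen[i], Kgen, sigma)
    if has_mark:
        ll += _ll_mark_row(sx, sy, gi, mx, my, ymark[i], Kmark, markp, mark_pois, sigma)
    if has_res and res_mask[i]:
        ll += _ll_res_row(sx, sy, gi, cx, cy, Yres[i], Eres[i], lamr, sigma)
    if has_tel:
        ll += _ll_tel_row(sx, sy, gi, tn[i], tsx[i], tsy[i], tss[i], sigma)
    return ll


@njit(cache=True)
def run_chain(
    seed, n_iter, n_burn,
    M, G,
    z, s, g, z_fixed, g_obs, in_pool, res_mask,
    xmin, xmax, ymin, ymax,
    has_gen, gx, gy, geff, ygen, Kgen,
    has_mark, mark_pois, mx, my, ymark, Kmark,
    has_res, cx, cy, Yres, Eres,
    has_cnt, ncnt, Opj,
    has_spa, yspa, opmat,
    has_tel, tn, tsx, tsy, tss,
    psi, sigma, lamr, markp, a0, a1v, p0spa, pi,
    sigma_max, lam_max, a1_sd,
    upd_lamr, upd_mark, upd_gen, upd_a1, upd_spa, upd_g,
    s_grid, sigma_grid, a0_grid,
    s_scales, sigma_scale, lamr_scale, mark_scale, a0_scale, a1_scale, spa_scale,
):
    """Run one chain; returns (draws, s_accept_rate, z, s, g, final_data_ll)."""
    np.random.seed(seed)
    Jc = cx.shape[0]
    Jg = gx.shape[0]
    Kocc = opmat.shape[1]
    T = np.zeros(Jc)
    T2 = np.zeros(Jc)
    LG = np.zeros((Jc, Kocc))
    LG2 = np.zeros((Jc, Kocc))
    rowbuf = np.zeros((Jc, Kocc))
    rowbuf2 = np.zeros((Jc, Kocc))
    kvec = np.zeros(Jc)
    kvec2 = np.zeros(Jc)
    gbase = np.zeros((G, Jg))
    gbase2 = np.zeros((G, Jg))
    use_sgrid = s_grid.shape[0] > 0
    use_siggrid = sigma_grid.shape[0] > 0
    use_a0grid = a0_grid.shape[0] > 0
    a1 = a1v
    _gen_base(a0, a1, geff, gbase)

    P = 5 * G + 4
    out = np.zeros((n_iter, P))

    s_acc = 0.0
    s_try = 0.0
    s_acc_w = np.zeros(M)
    s_try_w = np.zeros(M)
    # scalar-parameter adaptation: rows = sigma, lamr, markp, a0, a1, spa
    p_acc = np.zeros((6, G))
    p_try = np.zeros((6, G))

    ll_gen = ll_mark = ll_res = ll_cnt = ll_spa = ll_tel = 0.0

    for it in range(n_iter):
        # --- z updates (augmented slots only) ---------------------------------
        for i in range(M):
            if z_fixed[i]:
                continue
            if z[i] == 1:
                if has_cnt and in_pool[i]:
                    _cam_kvec(s[i, 0], s[i, 1], g[i], cx, cy, lamr, sigma, kvec)
                    for j in range(Jc):
                        T[j] -= kvec[j]
                        if T[j] < 0.0:
                            T[j] = 0.0
                if has_spa and in_pool[i]:
                    _spa_rowfill(s[i, 0], s[i, 1], g[i], cx, cy, opmat, p0spa, sigma, rowbuf)
                    for j in range(Jc):
                        for k in range(Kocc):
                            LG[j, k] -= rowbuf[j, k]
            ll1 = _row_ll(
                i, s[i, 0], s[i, 1], g[i],
                has_gen, gx, gy, gbase, ygen, Kgen,
                has_mark, mark_pois, mx, my, ymark, Kmark, markp,
                has_res, res_mask, cx, cy, Yres, Eres, lamr,
                has_tel, tn, tsx, tsy, tss, sigma,
            )
            if has_cnt and in_pool[i]:
                _cam_kvec(s[i, 0], s[i, 1], g[i], cx, cy, lamr, sigma, kvec)
                for j in range(Jc):
                    T2[j] = T[j] + kvec[j]
                ll1 += _cnt_ll(T2, ncnt, Opj) - _cnt_ll(T, ncnt, Opj)
            if has_spa and in_pool[i]:
                _spa_rowfill(s[i, 0], s[i, 1], g[i], cx, cy, opmat, p0spa, sigma, rowbuf)
                for j in range(Jc):
                    for k in range(Kocc):
                        rowbuf2[j, k] = LG[j, k] + rowbuf[j, k]
                ll1 += _spa_ll(rowbuf2, yspa) - _spa_ll(LG, yspa)
            eta = np.log(psi) - np.log1p(-psi) + ll1
            if eta > 35.0:
                znew = 1
            elif eta < -35.0:
                znew = 0
            else:
                znew = 1 if np.random.random() < _ilogit(eta) else 0
            z[i] = znew
            if znew == 1:
                if has_cnt and in_pool[i]:
                    for j in range(Jc):
                        T[j] += kvec[j]
                if has_spa and in_pool[i]:
                    for j in range(Jc):
                        for k in range(Kocc):
                            LG[j, k] += rowbuf[j, k]

        # --- psi conjugate update ---------------------------------------------
        n1 = 0
        for i in range(M):
            n1 += z[i]
        psi = np.random.beta(1.0 + n1, 1.0 + M - n1)

        # --- s updates --------------------------------------------------------
        for i in range(M):
            if z[i] == 0:
                if use_sgrid:
                    r = np.random.randint(0, s_grid.shape[0])
                    s[i, 0] = s_grid[r, 0]
                    s[i, 1] = s_grid[r, 1]
                else:
                    s[i, 0] = xmin + (xmax - xmin) * np.random.random()
                    s[i, 1] = ymin + (ymax - ymin) * np.random.random()
                continue
            if use_sgrid:
                r = np.random.randint(0, s_grid.shape[0])
                px = s_grid[r, 0]
                py = s_grid[r, 1]
            else:
                px = s[i, 0] + s_scales[i] * np.random.normal()
                py = s[i, 1] + s_scales[i] * np.random.normal()
                if px < xmin or px > xmax or py < ymin or py > ymax:
                    s_try_w[i] += 1.0
                    if it >= n_burn:
                        s_try += 1.0
                    continue
            dll = _row_ll(
                i, px, py, g[i],
                has_gen, gx, gy, gbase, ygen, Kgen,
                has_mark, mark_pois, mx, my, ymark, Kmark, markp,
                has_res, res_mask, cx, cy, Yres, Eres, lamr,
                has_tel, tn, tsx, tsy, tss, sigma,
            ) - _row_ll(
                i, s[i, 0], s[i, 1], g[i],
                has_gen, gx, gy, gbase, ygen, Kgen,
                has_mark, mark_pois, mx, my, ymark, Kmark, markp,
                has_res, res_mask, cx, cy, Yres, Eres, lamr,
                has_tel, tn, tsx, tsy, tss, sigma,
            )
            cnt_move = has_cnt and in_pool[i]
            spa_move = has_spa and in_pool[i]
            if cnt_move:
                _cam_kvec(s[i, 0], s[i, 1], g[i], cx, cy, lamr, sigma, kvec)
                _cam_kvec(px, py, g[i], cx, cy, lamr, sigma, kvec2)
                for j in range(Jc):
                    T2[j] = T[j] - kvec[j] + kvec2[j]
                    if T2[j] < 0.0:
                        T2[j] = 0.0
                dll += _cnt_ll(T2, ncnt, Opj) - _cnt_ll(T, ncnt, Opj)
            if spa_move:
                _spa_rowfill(s[i, 0], s[i, 1], g[i], cx, cy, opmat, p0spa, sigma, rowbuf)
                _spa_rowfill(px, py, g[i], cx, cy, opmat, p0spa, sigma, rowbuf2)
                for j in range(Jc):
                    for k in range(Kocc):
                        rowbuf2[j, k] = LG[j, k] - rowbuf[j, k] + rowbuf2[j, k]
                dll += _spa_ll(rowbuf2, yspa) - _spa_ll(LG, yspa)
            s_try_w[i] += 1.0
            if it >= n_burn:
                s_try += 1.0
            if np.log(np.random.random()) < dll:
                s[i, 0] = px
                s[i, 1] = py
                if cnt_move:
                    for j in range(Jc):
                        T[j] = T2[j]
                if spa_move:
                    for j in range(Jc):
                        for k in range(Kocc):
                            LG[j, k] = rowbuf2[j, k]
                s_acc_w[i] += 1.0
                if it >= n_burn:
                    s_acc += 1.0
        if (not use_sgrid) and it < n_burn and (it + 1) % 100 == 0:
            for i in range(M):
                if s_try_w[i] >= 20.0:
                    rate = s_acc_w[i] / s_try_w[i]
                    if rate < 0.2:
                        s_scales[i] *= 0.7
                    elif rate > 0.5:
                        s_scales[i] *= 1.4
                    if s_scales[i] < 1.0:
                        s_scales[i] = 1.0
                    if s_scales[i] > (xmax - xmin):
                        s_scales[i] = xmax - xmin
                s_acc_w[i] = 0.0
                s_try_w[i] = 0.0

        # --- latent group labels ----------------------------------------------
        if upd_g and G > 1:
            for i in range(M):
                if g_obs[i] >= 0:
                    g[i] = g_obs[i]
                    continue
                if z[i] == 0:
                    g[i] = 1 if np.random.random() < pi else 0
                    continue
                gcur = g[i]
                galt = 1 - gcur
                dll = _row_ll(
                    i, s[i, 0], s[i, 1], galt,
                    has_gen, gx, gy, gbase, ygen, Kgen,
                    has_mark, mark_pois, mx, my, ymark, Kmark, markp,
                    has_res, res_mask, cx, cy, Yres, Eres, lamr,
                    has_tel, tn, tsx, tsy, tss, sigma,
                ) - _row_ll(
                    i, s[i, 0], s[i, 1], gcur,
                    has_gen, gx, gy, gbase, ygen, Kgen,
                    has_mark, mark_pois, mx, my, ymark, Kmark, markp,
                    has_res, res_mask, cx, cy, Yres, Eres, lamr,
                    has_tel, tn, tsx, tsy, tss, sigma,
                )
                cnt_move = has_cnt and in_pool[i]
                spa_move = has_spa and in_pool[i]
                if cnt_move:
                    _cam_kvec(s[i, 0], s[i, 1], gcur, cx, cy, lamr, sigma, kvec)
                    _cam_kvec(s[i, 0], s[i, 1], galt, cx, cy, lamr, sigma, kvec2)
                    for j in range(Jc):
                        T2[j] = T[j] - kvec[j] + kvec2[j]
                        if T2[j] < 0.0:
                            T2[j] = 0.0
                    dll += _cnt_ll(T2, ncnt, Opj) - _cnt_ll(T, ncnt, Opj)
                if spa_move:
                    _spa_rowfill(s[i, 0], s[i, 1], gcur, cx, cy, opmat, p0spa, sigma, rowbuf)
                    _spa_rowfill(s[i, 0], s[i, 1], galt, cx, cy, opmat, p0spa, sigma, rowbuf2)
                    for j in range(Jc):
                        for k in range(Kocc):
                            rowbuf2[j, k] = LG[j, k] - rowbuf[j, k] + rowbuf2[j, k]
                    dll += _spa_ll(rowbuf2, yspa) - _spa_ll(LG, yspa)
                if galt == 1:
                    eta = np.log(pi) - np.log1p(-pi) + dll
                else:
                    eta = np.log1p(-pi) - np.log(pi) + dll
                take_alt = False
                if eta > 35.0:
                    take_alt = True
                elif eta >= -35.0:
                    take_alt = np.random.random() < _ilogit(eta)
                if take_alt:
                    g[i] = galt
                    if cnt_move:
                        for j in range(Jc):
                            T[j] = T2[j]
                    if spa_move:
                        for j in range(Jc):
                            for k in range(Kocc):
                                LG[j, k] = rowbuf2[j, k]
            ng1 = 0
            for i in range(M):
                ng1 += g[i]
            pi = np.random.beta(1.0 + ng1, 1.0 + M - ng1)

        # --- scalar detection parameters --------------------------------------
        # refresh component totals and marginal structures exactly
        if has_gen:
            ll_gen = _tot_gen(z, s, g, gx, gy, gbase, ygen, Kgen, sigma)
        if has_mark:
            ll_mark = _tot_mark(z, s, g, mx, my, ymark, Kmark, markp, mark_pois, sigma)
        if has_res:
            ll_res = _tot_res(res_mask, s, g, cx, cy, Yres, Eres, lamr, sigma)
        if has_cnt:
            _build_T(z, s, g, in_pool, cx, cy, lamr, sigma, T)
            ll_cnt = _cnt_ll(T, ncnt, Opj)
        if has_spa:
            _build_LG(z, s, g, in_pool, cx, cy, opmat, p0spa, sigma, LG, rowbuf)
            ll_spa = _spa_ll(LG, yspa)
        if has_tel:
            ll_tel = _tot_tel(s, g, tn, tsx, tsy, tss, sigma)

        for gg in range(G):
            # -- sigma: enters every component --
            old = sigma[gg]
            if use_siggrid:
                new = sigma_grid[np.random.randint(0, sigma_grid.shape[0])]
                lratio = 0.0
                ok = True
            else:
                new = old * np.exp(sigma_scale[gg] * np.random.normal())
                lratio = np.log(new) - np.log(old)
                ok = 0.0 < new < sigma_max
            if ok and new != old:
                sigma[gg] = new
                d = lratio
                n_gen = n_mark = n_res = n_cnt = n_spa = n_tel = 0.0
                if has_gen:
                    n_gen = _tot_gen(z, s, g, gx, gy, gbase, ygen, Kgen, sigma)
                    d += n_gen - ll_gen
                if has_mark:
                    n_mark = _tot_mark(z, s, g, mx, my, ymark, Kmark, markp, mark_pois, sigma)
                    d += n_mark - ll_mark
                if has_res:
                    n_res = _tot_res(res_mask, s, g, cx, cy, Yres, Eres, lamr, sigma)
                    d += n_res - ll_res
                if has_cnt:
                    _build_T(z, s, g, in_pool, cx, cy, lamr, sigma, T2)
                    n_cnt = _cnt_ll(T2, ncnt, Opj)
                    d += n_cnt - ll_cnt
                if has_spa:
                    _build_LG(z, s, g, in_pool, cx, cy, opmat, p0spa, sigma, LG2, rowbuf)
                    n_spa = _spa_ll(LG2, yspa)
                    d += n_spa - ll_spa
                if has_tel:
                    n_tel = _tot_tel(s, g, tn, tsx, tsy, tss, sigma)
                    d += n_tel - ll_tel
                p_try[0, gg] += 1.0
                if np.log(np.random.random()) < d:
                    p_acc[0, gg] += 1.0
                    ll_gen, ll_mark, ll_res, ll_cnt, ll_spa, ll_tel = (
                        n_gen if has_gen else ll_gen,
                        n_mark if has_mark else ll_mark,
                        n_res if has_res else ll_res,
                        n_cnt if has_cnt else ll_cnt,
                        n_spa if has_spa else ll_spa,
                        n_tel if has_tel else ll_tel,
                    )
                    if has_cnt:
                        for j in range(Jc):
                            T[j] = T2[j]
                    if has_spa:
                        for j in range(Jc):
                            for k in range(Kocc):
                                LG[j, k] = LG2[j, k]
                else:
                    sigma[gg] = old

            # -- lambda0.resight: resight + marginal counts --
            if upd_lamr:
                old = lamr[gg]
                new = old * np.exp(lamr_scale[gg] * np.random.normal())
                if 0.0 < new < lam_max:
                    lamr[gg] = new
                    d = np.log(new) - np.log(old)
                    n_res = n_cnt = 0.0
                    if has_res:
                        n_res = _tot_res(res_mask, s, g, cx, cy, Yres, Eres, lamr, sigma)
                        d += n_res - ll_res
                    if has_cnt:
                        _build_T(z, s, g, in_pool, cx, cy, lamr, sigma, T2)
                        n_cnt = _cnt_ll(T2, ncnt, Opj)
                        d += n_cnt - ll_cnt
                    p_try[1, gg] += 1.0
                    if np.log(np.random.random()) < d:
                        p_acc[1, gg] += 1.0
                        if has_res:
                            ll_res = n_res
                        if has_cnt:
                            ll_cnt = n_cnt
                            for j in range(Jc):
                                T[j] = T2[j]
                    else:
                        lamr[gg] = old

            # -- marking probability / rate --
            if upd_mark:
                old = markp[gg]
                if mark_pois:
                    new = old * np.exp(mark_scale[gg] * np.random.normal())
                    ok = 0.0 < new < lam_max
                    lratio = np.log(new) - np.log(old) if ok else 0.0
                else:
                    eta = np.log(old) - np.log1p(-old) + mark_scale[gg] * np.random.normal()
                    new = _ilogit(eta)
                    ok = 0.0 < new < 1.0
                    lratio = (
                        np.log(new) + np.log1p(-new) - np.log(old) - np.log1p(-old)
                    ) if ok else 0.0
                if ok:
                    markp[gg] = new
                    n_mark = _tot_mark(z, s, g, mx, my, ymark, Kmark, markp, mark_pois, sigma)
                    p_try[2, gg] += 1.0
                    if np.log(np.random.random()) < n_mark - ll_mark + lratio:
                        p_acc[2, gg] += 1.0
                        ll_mark = n_mark
                    else:
                        markp[gg] = old

            # -- genetic baseline intercept --
            if upd_gen:
                old = a0[gg]
                if use_a0grid:
                    new = a0_grid[np.random.randint(0, a0_grid.shape[0])]
                    dprior = 0.0
                else:
                    new = old + a0_scale[gg] * np.random.normal()
                    dprior = _logistic_logpdf(new) - _logistic_logpdf(old)
                if new != old:
                    a0[gg] = new
                    _gen_base(a0, a1, geff, gbase2)
                    n_gen = _tot_gen(z, s, g, gx, gy, gbase2, ygen, Kgen, sigma)
                    p_try[3, gg] += 1.0
                    if np.log(np.random.random()) < n_gen - ll_gen + dprior:
                        p_acc[3, gg] += 1.0
                        ll_gen = n_gen
                        for q in range(G):
                            for j in range(Jg):
                                gbase[q, j] = gbase2[q, j]
                    else:
                        a0[gg] = old

            # -- presence-absence baseline --
            if upd_spa:
                old = p0spa[gg]
                eta = np.log(old) - np.log1p(-old) + spa_scale[gg] * np.random.normal()
                new = _ilogit(eta)
                if 0.0 < new < 1.0:
                    p0spa[gg] = new
                    _build_LG(z, s, g, in_pool, cx, cy, opmat, p0spa, sigma, LG2, rowbuf)
                    n_spa = _spa_ll(LG2, yspa)
                    lratio = np.log(new) + np.log1p(-new) - np.log(old) - np.log1p(-old)
                    p_try[5, gg] += 1.0
                    if np.log(np.random.random()) < n_spa - ll_spa + lratio:
                        p_acc[5, gg] += 1.0
                        ll_spa = n_spa
                        for j in range(Jc):
                            for k in range(Kocc):
                                LG[j, k] = LG2[j, k]
                    else:
                        p0spa[gg] = old

        # -- genetic effort slope (shared across groups) --
        if upd_a1:
            old = a1
            new = old + a1_scale * np.random.normal()
            dprior = -0.5 * ((new / a1_sd) ** 2 - (old / a1_sd) ** 2)
            a1 = new
            _gen_base(a0, a1, geff, gbase2)
            n_gen = _tot_gen(z, s, g, gx, gy, gbase2, ygen, Kgen, sigma)
            p_try[4, 0] += 1.0
            if np.log(np.random.random()) < n_gen - ll_gen + dprior:
                p_acc[4, 0] += 1.0
                ll_gen = n_gen
                for q in range(G):
                    for j in range(Jg):
                        gbase[q, j] = gbase2[q, j]
            else:
                a1 = old

        # adapt scalar proposal scales during burn-in
        if it < n_burn and (it + 1) % 100 == 0:
            for gg in range(G):
                for pidx in range(6):
                    if p_try[pidx, gg] >= 20.0:
                        rate = p_acc[pidx, gg] / p_try[pidx, gg]
                        fac = 1.0
                        if rate < 0.2:
                            fac = 0.7
                        elif rate > 0.5:
                            fac = 1.4
                        if pidx == 0:
                            sigma_scale[gg] *= fac
                        elif pidx == 1:
                            lamr_scale[gg] *= fac
                        elif pidx == 2:
                            mark_scale[gg] *= fac
                        elif pidx == 3:
                            a0_scale[gg] *= fac
                        elif pidx == 5:
                            spa_scale[gg] *= fac
                    p_acc[pidx, gg] = 0.0
                    p_try[pidx, gg] = 0.0

        # --- store draw -------------------------------------------------------
        out[it, 0] = psi
        for gg in range(G):
            out[it, 1 + gg] = sigma[gg]
            out[it, 1 + G + gg] = lamr[gg]
            out[it, 1 + 2 * G + gg] = markp[gg]
            out[it, 1 + 3 * G + gg] = a0[gg]
            out[it, 2 + 4 * G + gg] = p0spa[gg]
        out[it, 1 + 4 * G] = a1
        out[it, 2 + 5 * G] = pi
        nz = 0
        for i in range(M):
            nz += z[i]
        out[it, 3 + 5 * G] = nz

    final_ll = ll_gen + ll_mark + ll_res + ll_cnt + ll_spa + ll_tel
    rate = s_acc / s_try if s_try > 0 else 0.0
    return out, rate, z, s, g, final_ll
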