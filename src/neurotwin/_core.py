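"""Compiled compute core for the hierarchical variational RNN.

Implements one forward pass (top-down generation driven by posterior
samples, with prior parameters computed alongside for the KL terms) and the
matching backward pass (backpropagation through time) over a time window.
Gradients are produced with respect to every weight matrix and every
adaptive posterior state.  The region loop is explicit, so the kernels
cover any number of region modules.

Conventions
-----------
* Level 1 = local region modules (latent ``z1``, deterministic ``d1``,
  time constant ``tau1``), one module per region.
* Level 2 = functional-network module (``z2``, ``d2``, ``tau2``).
* Level 3 = global state (``z3`` only, constant over the window; no
  deterministic units).
* Pre-activations of all sigma outputs are clamped to ``[-SIGMA_CLIP,
  SIGMA_CLIP]`` before ``exp`` as a numerical guard; the backward pass
  zeroes the gradient outside the clamp.
* ``is_start`` marks a window beginning at the sequence start: the t=0
  priors are then the unit Gaussian and the global KL term is included.
"""
from __future__ import annotations

import numpy as np
from numba import njit

SIGMA_CLIP = 10.0


@njit(cache=True)
def _mv(A, x, out):
    """out = A @ x for small dense matrices (explicit loops beat BLAS here)."""
    n, m = A.shape
    for i in range(n):
        s = 0.0
        for j in range(m):
            s += A[i, j] * x[j]
        out[i] = s


@njit(cache=True)
def _mtv(A, x, out):
    """out = A.T @ x."""
    n, m = A.shape
    for j in range(m):
        out[j] = 0.0
    for i in range(n):
        xi = x[i]
        if xi != 0.0:
            for j in range(m):
                out[j] += A[i, j] * xi


@njit(cache=True)
def _outer_acc(out, g, v, scale):
    """out += scale * outer(g, v)."""
    n = g.shape[0]
    m = v.shape[0]
    for i in range(n):
        gi = g[i] * scale
        for j in range(m):
            out[i, j] += gi * v[j]


@njit(cache=True)
def _clip(a):
    if a > SIGMA_CLIP:
        return SIGMA_CLIP
    if a < -SIGMA_CLIP:
        return -SIGMA_CLIP
    return a


@njit(cache=True)
def forward(
    tau1, tau2, is_start,
    W2pm, W2ps, Wd2d2, Wd2z2, Wd2z3, b2,
    W1pm, W1ps, Wd1d1, Wd1z1, Wd1d2, b1, Wout,
    a3m, a3s, a2m, a2s, a1m, a1s,
    x, eps3, eps2, eps1,
    h2_0, d2_0, h1_0, d1_0,
    mu2p, sg2p, mu2q, sg2q, z2, h2, d2,
    mu1p, sg1p, mu1q, sg1q, z1, h1, d1,
    xhat, mu3q, sg3q, z3, fsteps,
):
    """Top-down pass over a window; fills trajectory arrays in place.

    Returns ``(recon, kl1, kl2, kl3)`` summed over the window, where
    ``recon`` is the half squared prediction error and ``kl*`` are the
    per-level KL divergences (unit-summed, unweighted).  ``fsteps`` gets
    the per-step ``(recon_t, kl1_t, kl2_t)`` breakdown.
    """
    T, R, C = x.shape
    L2 = a2m.shape[1]
    L1 = a1m.shape[2]
    L3 = a3m.shape[0]
    D2 = b2.shape[0]
    D1 = b1.shape[1]
    r1 = 1.0 / tau1
    r2 = 1.0 / tau2

    # global posterior (constant over the window)
    for i in range(L3):
        mu3q[i] = np.tanh(a3m[i])
        sg3q[i] = np.exp(_clip(a3s[i]))
        z3[i] = mu3q[i] + sg3q[i] * eps3[i]
    kl3 = 0.0
    if is_start:
        for i in range(L3):
            sq = sg3q[i]
            mq = mu3q[i]
            kl3 += -np.log(sq) + 0.5 * (sq * sq + mq * mq) - 0.5

    u2m = np.empty(L2)
    u2s = np.empty(L2)
    u1m = np.empty(L1)
    u1s = np.empty(L1)
    accA = np.empty(D2)
    accB = np.empty(D2)
    accC = np.empty(D2)
    acc1 = np.empty(D1)
    acc2 = np.empty(D1)
    acc3 = np.empty(D1)
    accO = np.empty(C)

    recon_tot = 0.0
    kl1_tot = 0.0
    kl2_tot = 0.0
    for t in range(T):
        if t == 0:
            d2p = d2_0
            h2p = h2_0
        else:
            d2p = d2[t - 1]
            h2p = h2[t - 1]

        # ---- network level: prior, posterior, sample, dynamics
        if t == 0 and is_start:
            for i in range(L2):
                mu2p[t, i] = 0.0
                sg2p[t, i] = 1.0
        else:
            _mv(W2pm, d2p, u2m)
            _mv(W2ps, d2p, u2s)
            for i in range(L2):
                mu2p[t, i] = np.tanh(u2m[i])
                sg2p[t, i] = np.exp(_clip(u2s[i]))
        kl2_t = 0.0
        for i in range(L2):
            mu2q[t, i] = np.tanh(a2m[t, i])
            sg2q[t, i] = np.exp(_clip(a2s[t, i]))
            z2[t, i] = mu2q[t, i] + sg2q[t, i] * eps2[t, i]
            mp = mu2p[t, i]
            sp = sg2p[t, i]
            mq = mu2q[t, i]
            sq = sg2q[t, i]
            kl2_t += np.log(sp / sq) + (sq * sq + (mq - mp) ** 2) / (2.0 * sp * sp) - 0.5
        _mv(Wd2d2, d2p, accA)
        _mv(Wd2z2, z2[t], accB)
        _mv(Wd2z3, z3, accC)
        for i in range(D2):
            h2[t, i] = r2 * (accA[i] + accB[i] + accC[i] + b2[i]) + (1.0 - r2) * h2p[i]
            d2[t, i] = np.tanh(h2[t, i])

        # ---- region level
        recon_t = 0.0
        kl1_t = 0.0
        for r in range(R):
            if t == 0:
                d1p = d1_0[r]
                h1p = h1_0[r]
            else:
                d1p = d1[t - 1, r]
                h1p = h1[t - 1, r]
            if t == 0 and is_start:
                for i in range(L1):
                    mu1p[t, r, i] = 0.0
                    sg1p[t, r, i] = 1.0
            else:
                _mv(W1pm[r], d1p, u1m)
                _mv(W1ps[r], d1p, u1s)
                for i in range(L1):
                    mu1p[t, r, i] = np.tanh(u1m[i])
                    sg1p[t, r, i] = np.exp(_clip(u1s[i]))
            for i in range(L1):
                mu1q[t, r, i] = np.tanh(a1m[t, r, i])
                sg1q[t, r, i] = np.exp(_clip(a1s[t, r, i]))
                z1[t, r, i] = mu1q[t, r, i] + sg1q[t, r, i] * eps1[t, r, i]
                mp = mu1p[t, r, i]
                sp = sg1p[t, r, i]
                mq = mu1q[t, r, i]
                sq = sg1q[t, r, i]
                kl1_t += np.log(sp / sq) + (sq * sq + (mq - mp) ** 2) / (2.0 * sp * sp) - 0.5
            _mv(Wd1d1[r], d1p, acc1)
            _mv(Wd1z1[r], z1[t, r], acc2)
            _mv(Wd1d2[r], d2[t], acc3)
            for i in range(D1):
                h1[t, r, i] = r1 * (acc1[i] + acc2[i] + acc3[i] + b1[r, i]) + (1.0 - r1) * h1p[i]
                d1[t, r, i] = np.tanh(h1[t, r, i])
            _mv(Wout[r], d1[t, r], accO)
            for c in range(C):
                xhat[t, r, c] = np.tanh(accO[c])
                diff = x[t, r, c] - xhat[t, r, c]
                recon_t += 0.5 * diff * diff
        fsteps[t, 0] = recon_t
        fsteps[t, 1] = kl1_t
        fsteps[t, 2] = kl2_t
        recon_tot += recon_t
        kl1_tot += kl1_t
        kl2_tot += kl2_t

    return recon_tot, kl1_tot, kl2_tot, kl3


@njit(cache=True)
def backward(
    tau1, tau2, is_start, w1, w2, w3,
    W2pm, W2ps, Wd2d2, Wd2z2, Wd2z3, b2,
    W1pm, W1ps, Wd1d1, Wd1z1, Wd1d2, b1, Wout,
    a3s, a2s, a1s,
    x, eps3, eps2, eps1,
    d2_0, d1_0,
    mu2p, sg2p, mu2q, sg2q, z2, h2, d2,
    mu1p, sg1p, mu1q, sg1q, z1, h1, d1,
    xhat, mu3q, sg3q, z3,
    gW2pm, gW2ps, gWd2d2, gWd2z2, gWd2z3, gb2,
    gW1pm, gW1ps, gWd1d1, gWd1z1, gWd1d2, gb1, gWout,
    ga3m, ga3s, ga2m, ga2s, ga1m, ga1s,
):
    """Accumulate gradients of the meta-prior-weighted window free energy.

    The loss differentiated is ``recon + w1*kl1 + w2*kl2 + w3*kl3`` as
    produced by :func:`forward`.  All ``g*`` arrays are accumulated into
    (callers zero them beforehand when a plain gradient is wanted).
    """
    T, R, C = x.shape
    L2 = a2s.shape[1]
    L1 = a1s.shape[2]
    L3 = ga3m.shape[0]
    D2 = b2.shape[0]
    D1 = b1.shape[1]
    r1 = 1.0 / tau1
    r2 = 1.0 / tau2

    gh2n = np.zeros(D2)
    gd2c = np.zeros(D2)
    gh1n = np.zeros((R, D1))
    gd1c = np.zeros((R, D1))
    gz3s = np.zeros(L3)

    gpo = np.empty(C)
    gd1t = np.empty(D1)
    gh1 = np.empty(D1)
    gz1 = np.empty(L1)
    ncar1 = np.empty(D1)
    gd2_local = np.empty(D2)
    gd2t = np.empty(D2)
    gh2 = np.empty(D2)
    gz2 = np.empty(L2)
    ncar2 = np.empty(D2)
    tmpD1 = np.empty(D1)
    tmpD2 = np.empty(D2)
    tmpL3 = np.empty(L3)

    for t in range(T - 1, -1, -1):
        if t == 0:
            d2p = d2_0
        else:
            d2p = d2[t - 1]
        for i in range(D2):
            gd2_local[i] = 0.0
        prior_fixed = t == 0 and is_start

        for r in range(R):
            if t == 0:
                d1p = d1_0[r]
            else:
                d1p = d1[t - 1, r]
            # output layer
            for c in range(C):
                gx = xhat[t, r, c] - x[t, r, c]
                gpo[c] = gx * (1.0 - xhat[t, r, c] * xhat[t, r, c])
            _outer_acc(gWout[r], gpo, d1[t, r], 1.0)
            _mtv(Wout[r], gpo, gd1t)
            for i in range(D1):
                gd1t[i] += gd1c[r, i]
            # deterministic unit
            for i in range(D1):
                gh1[i] = gd1t[i] * (1.0 - d1[t, r, i] * d1[t, r, i]) \
                    + gh1n[r, i] * (1.0 - r1)
            _outer_acc(gWd1d1[r], gh1, d1p, r1)
            _outer_acc(gWd1z1[r], gh1, z1[t, r], r1)
            _outer_acc(gWd1d2[r], gh1, d2[t], r1)
            for i in range(D1):
                gb1[r, i] += r1 * gh1[i]
            _mtv(Wd1z1[r], gh1, gz1)
            _mtv(Wd1d2[r], gh1, tmpD2)
            for i in range(D2):
                gd2_local[i] += r1 * tmpD2[i]
            _mtv(Wd1d1[r], gh1, tmpD1)
            for i in range(D1):
                ncar1[i] = r1 * tmpD1[i]
            # latent posterior / prior
            for i in range(L1):
                mq = mu1q[t, r, i]
                sq = sg1q[t, r, i]
                mp = mu1p[t, r, i]
                sp = sg1p[t, r, i]
                gz = gz1[i] * r1
                gkl_mq = w1 * (mq - mp) / (sp * sp)
                gkl_sq = w1 * (-1.0 / sq + sq / (sp * sp))
                ga1m[t, r, i] += (gz + gkl_mq) * (1.0 - mq * mq)
                if -SIGMA_CLIP < a1s[t, r, i] < SIGMA_CLIP:
                    ga1s[t, r, i] += (gz * eps1[t, r, i] + gkl_sq) * sq
                if not prior_fixed:
                    gkl_mp = -w1 * (mq - mp) / (sp * sp)
                    gkl_sp = w1 * (1.0 / sp - (sq * sq + (mq - mp) ** 2) / (sp * sp * sp))
                    gum = gkl_mp * (1.0 - mp * mp)
                    ls = np.log(sp)
                    if -SIGMA_CLIP < ls < SIGMA_CLIP:
                        gus = gkl_sp * sp
                    else:
                        gus = 0.0
                    for j in range(D1):
                        gW1pm[r, i, j] += gum * d1p[j]
                        gW1ps[r, i, j] += gus * d1p[j]
                        ncar1[j] += gum * W1pm[r, i, j] + gus * W1ps[r, i, j]
            for i in range(D1):
                gh1n[r, i] = gh1[i]
                gd1c[r, i] = ncar1[i]

        # ---- network level
        for i in range(D2):
            gd2t[i] = gd2_local[i] + gd2c[i]
            gh2[i] = gd2t[i] * (1.0 - d2[t, i] * d2[t, i]) + gh2n[i] * (1.0 - r2)
        _outer_acc(gWd2d2, gh2, d2p, r2)
        _outer_acc(gWd2z2, gh2, z2[t], r2)
        _outer_acc(gWd2z3, gh2, z3, r2)
        for i in range(D2):
            gb2[i] += r2 * gh2[i]
        _mtv(Wd2z2, gh2, gz2)
        _mtv(Wd2z3, gh2, tmpL3)
        for i in range(L3):
            gz3s[i] += r2 * tmpL3[i]
        _mtv(Wd2d2, gh2, tmpD2)
        for i in range(D2):
            ncar2[i] = r2 * tmpD2[i]
        for i in range(L2):
            mq = mu2q[t, i]
            sq = sg2q[t, i]
            mp = mu2p[t, i]
            sp = sg2p[t, i]
            gz = gz2[i] * r2
            gkl_mq = w2 * (mq - mp) / (sp * sp)
            gkl_sq = w2 * (-1.0 / sq + sq / (sp * sp))
            ga2m[t, i] += (gz + gkl_mq) * (1.0 - mq * mq)
            if -SIGMA_CLIP < a2s[t, i] < SIGMA_CLIP:
                ga2s[t, i] += (gz * eps2[t, i] + gkl_sq) * sq
            if not prior_fixed:
                gkl_mp = -w2 * (mq - mp) / (sp * sp)
                gkl_sp = w2 * (1.0 / sp - (sq * sq + (mq - mp) ** 2) / (sp * sp * sp))
                gum = gkl_mp * (1.0 - mp * mp)
                ls = np.log(sp)
                if -SIGMA_CLIP < ls < SIGMA_CLIP:
                    gus = gkl_sp * sp
                else:
                    gus = 0.0
                for j in range(D2):
                    gW2pm[i, j] += gum * d2p[j]
                    gW2ps[i, j] += gus * d2p[j]
                    ncar2[j] += gum * W2pm[i, j] + gus * W2ps[i, j]
        for i in range(D2):
            gh2n[i] = gh2[i]
            gd2c[i] = ncar2[i]

    # ---- global level (posterior constant; prior N(0,1) at sequence start)
    for i in range(L3):
        mq = mu3q[i]
        sq = sg3q[i]
        if is_start:
            gkl_mq = w3 * mq
            gkl_sq = w3 * (-1.0 / sq + sq)
        else:
            gkl_mq = 0.0
            gkl_sq = 0.0
        ga3m[i] += (gz3s[i] + gkl_mq) * (1.0 - mq * mq)
        if -SIGMA_CLIP < a3s[i] < SIGMA_CLIP:
            ga3s[i] += (gz3s[i] * eps3[i] + gkl_sq) * sq
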