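"""Jit-compiled inner loops.

All randomness is pre-generated by numpy Generators in the calling code and
passed in as arrays, so results are reproducible and independent of the jit
runtime.  Each kernel mutates its label/field arguments in place and returns
only counters.
"""

import numpy as np
from numba import njit


@njit(cache=True)
def metropolis_sweep_inplace(labels, obs, beta, temperature, mu, sigma,
                             prop_offset, unif):
    """One raster-order single-site Metropolis sweep; returns accept count.

    ``prop_offset[i, j]`` in [0, K-2] selects a uniformly random label other
    than the current one; ``unif[i, j]`` is the accept/reject draw.
    """
    H, W = labels.shape
    accepted = 0
    for i in range(H):
        for j in range(W):
            cur = labels[i, j]
            new = prop_offset[i, j]
            if new >= cur:
                new += 1
            same_cur = 0
            same_new = 0
            for di in range(-1, 2):
                for dj in range(-1, 2):
                    if di == 0 and dj == 0:
                        continue
                    ii = i + di
                    jj = j + dj
                    if 0 <= ii < H and 0 <= jj < W:
                        r = labels[ii, jj]
                        if r == cur:
                            same_cur += 1
                        if r == new:
                            same_new += 1
            dU = 2.0 * beta * (same_cur - same_new)
            y = obs[i, j]
            ll_new = -np.log(sigma[new]) - (y - mu[new]) ** 2 / (2.0 * sigma[new] ** 2)
            ll_cur = -np.log(sigma[cur]) - (y - mu[cur]) ** 2 / (2.0 * sigma[cur] ** 2)
            dE = dU / temperature - (ll_new - ll_cur)
            if dE <= 0.0 or unif[i, j] < np.exp(-dE):
                labels[i, j] = new
                accepted += 1
    return accepted


@njit(cache=True)
def icm_sweep_inplace(labels, obs, beta, temperature, mu, sigma):
    """One raster-order ICM sweep (greedy local-conditional argmax).

    Returns the number of sites whose label changed.  Ties break toward the
    lowest class index.
    """
    H, W = labels.shape
    K = mu.size
    changed = 0
    for i in range(H):
        for j in range(W):
            best_l = 0
            best_e = 1e300
            y = obs[i, j]
            for l in range(K):
                same = 0
                n = 0
                for di in range(-1, 2):
                    for dj in range(-1, 2):
                        if di == 0 and dj == 0:
                            continue
                        ii = i + di
                        jj = j + dj
                        if 0 <= ii < H and 0 <= jj < W:
                            n += 1
                            if labels[ii, jj] == l:
                                same += 1
                pair_e = beta * (n - 2 * same)
                ll = -np.log(sigma[l]) - (y - mu[l]) ** 2 / (2.0 * sigma[l] ** 2)
                e = pair_e / temperature - ll
                if e < best_e:
                    best_e = e
                    best_l = l
            if best_l != labels[i, j]:
                labels[i, j] = best_l
                changed += 1
    return changed


@njit(cache=True)
def potts_gibbs_sweeps_inplace(labels, K, beta, unif):
    """Gibbs-sample the pure Potts prior in place.

    ``unif`` has shape (sweeps, H, W); each sweep visits sites in raster order
    and draws the new label from its full conditional by inverse CDF.
    """
    sweeps = unif.shape[0]
    H, W = labels.shape
    probs = np.empty(K)
    for t in range(sweeps):
        for i in range(H):
            for j in range(W):
                total = 0.0
                for l in range(K):
                    same = 0
                    n = 0
                    for di in range(-1, 2):
                        for dj in range(-1, 2):
                            if di == 0 and dj == 0:
                                continue
                            ii = i + di
                            jj = j + dj
                            if 0 <= ii < H and 0 <= jj < W:
                                n += 1
                                if labels[ii, jj] == l:
                                    same += 1
                    probs[l] = np.exp(-beta * (n - 2 * same))
                    total += probs[l]
                u = unif[t, i, j] * total
                acc = 0.0
                pick = K - 1
                for l in range(K):
                    acc += probs[l]
                    if u < acc:
                        pick = l
                        break
                labels[i, j] = pick


@njit(cache=True)
def block_chain(padded, H, W, radius, s0_r, s0_c, disp, unif, C):
    """Metropolis chain over d x d block locations in a reflect-padded image.

    ``disp`` holds the chain's pre-generated Gaussian displacements, shape
    (steps, 2); ``unif`` the accept draws.  Similarity to the reference block
    at ``(s0_r, s0_c)`` is phi = exp(-sum((F' - F)^2) / C).  Rejected moves
    repeat the current state.  Returns per-step (row, col, phi) arrays of the
    chain path, including the start state at index 0.
    """
    d = 2 * radius + 1
    steps = disp.shape[0]
    rows = np.empty(steps + 1, dtype=np.int64)
    cols = np.empty(steps + 1, dtype=np.int64)
    phis = np.empty(steps + 1)

    ref = padded[s0_r:s0_r + d, s0_c:s0_c + d]

    cur_r, cur_c = s0_r, s0_c
    cur_phi = 1.0
    rows[0] = cur_r
    cols[0] = cur_c
    phis[0] = cur_phi
    for k in range(steps):
        pr = cur_r + int(np.rint(disp[k, 0]))
        pc = cur_c + int(np.rint(disp[k, 1]))
        if pr < 0:
            pr = 0
        elif pr > H - 1:
            pr = H - 1
        if pc < 0:
            pc = 0
        elif pc > W - 1:
            pc = W - 1
        ssd = 0.0
        for a in range(d):
            for b in range(d):
                diff = padded[pr + a, pc + b] - ref[a, b]
                ssd += diff * diff
        phi = np.exp(-ssd / C)
        # min{1, phi' / phi_prev}
        if phi >= cur_phi or unif[k] * cur_phi < phi:
            cur_r, cur_c, cur_phi = pr, pc, phi
        rows[k + 1] = cur_r
        cols[k + 1] = cur_c
        phis[k + 1] = cur_phi
    return rows, cols, phis
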