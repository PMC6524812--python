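"""Vectorized Metropolis-within-Gibbs engine for the growth models.

Both estimators share the latent multiplicative-growth process

    N[i, t] = N[i, t-1] * lam[i, t],   lam[i, t] ~ Gamma(r, beta)

with r = lb^2/sg^2, beta = lb/sg^2 (so lam has mean lb and SD sg),
lb ~ Gamma(0.1, 0.1), sg ~ Gamma(3, 1), and a scale-invariant log-uniform
prior on the initial abundance N[i, 1] over [1e-3, U] (a flat prior on N1
makes the N-mixture's detection/abundance ridge degenerate: its prior
volume grows linearly with the abundance scale and pushes p to the
boundary).

The sampler works on theta = log N.  In theta-space the joint density picks
up the change-of-variables terms; the (lam -> N), (N -> theta) and N1-prior
Jacobians collapse to theta[i, T-1] - theta[i, 0] per site, which the
update rules below carry explicitly.

Observation layers:
  state-space  y[i, t] ~ Poisson(N[i, t])                (y = max count)
  N-mixture    X[i, t] ~ Poisson(N[i, t]) integer latent,
               y[i, j, t] ~ Binomial(X[i, t], p),  p ~ Beta(1, 1)

Moves per sweep: checkerboard log-normal random-walk updates of the theta
columns (odd/even years are conditionally independent given the other
parity), a per-site level shift, per-site and global trend tilts, scalar
random-walk updates of (lb, sg), and an occasional prior-independence
rejuvenation of (lb, sg, lam).  The N-mixture adds a collapsed block
(:class:`_NmixKernel`): Metropolis moves of p and of the global
abundance/detection scale under the X-marginalized bivariate-Poisson
likelihood, followed by an exact conditional redraw of X.  Step sizes adapt
by Robbins-Monro during warmup only.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import gammaln

_EXP_CAP = 600.0  # cap on exponents; proposals beyond are effectively rejected
_THETA_HI = 550.0  # protects exp() on the abundance scale
_THETA_LO = -1.0e30  # log N may fall arbitrarily low (extinct trajectories)

# hyperpriors (shape, rate)
_LB_PRIOR = (0.10, 0.10)
_SG_PRIOR = (3.0, 1.0)


def _cexp(z: np.ndarray) -> np.ndarray:
    return np.exp(np.minimum(z, _EXP_CAP))


@dataclass
class ChainDraws:
    lambda_bar: np.ndarray  # (D,)
    sigma_lambda: np.ndarray  # (D,)
    n_total: np.ndarray  # (D, T)
    p_year: np.ndarray | None  # (D, T) for the N-mixture
    x_total: np.ndarray | None  # (D, T)
    n_full: np.ndarray | None  # (D, I, T) when store_latent == "full"
    accept_rates: dict


def _site_logpost(theta, obs, mask, r, beta, log_l, log_u):
    """Per-site log posterior (up to constants shared across sites): (I,)."""
    d = np.diff(theta, axis=1)
    ll = np.where(mask, obs * theta - _cexp(theta), 0.0).sum(axis=1)
    ll = ll + ((r - 1.0) * d - beta * _cexp(d)).sum(axis=1)
    # log-uniform N1 prior and the lam -> N -> theta change of variables
    ll = ll + theta[:, -1] - theta[:, 0]
    ok = (theta[:, 0] > log_l) & (theta[:, 0] < log_u)
    return np.where(ok, ll, -np.inf)


def _update_columns(theta, obs, mask, r, beta, step, rng, log_l, log_u, parity):
    """Metropolis update of every parity-matching year column, all sites at once."""
    I, T = theta.shape
    cols = np.arange(parity, T, 2)
    x = theta[:, cols]
    xp = x + rng.normal(0.0, 1.0, x.shape) * step[:, cols]
    prev = np.concatenate([np.zeros((I, 1)), theta[:, :-1]], axis=1)[:, cols]
    nxt = np.concatenate([theta[:, 1:], np.zeros((I, 1))], axis=1)[:, cols]
    has_prev = (cols >= 1)[None, :]
    has_next = (cols <= T - 2)[None, :]

    dlp = np.where(mask[:, cols], obs[:, cols] * (xp - x) - (_cexp(xp) - _cexp(x)), 0.0)
    dlp += np.where(
        has_prev,
        (r - 1.0) * (xp - x) - beta * (_cexp(xp - prev) - _cexp(x - prev)),
        0.0,
    )
    dlp += np.where(
        has_next,
        -(r - 1.0) * (xp - x) - beta * (_cexp(nxt - xp) - _cexp(nxt - x)),
        0.0,
    )
    dlp += np.where((cols == T - 1)[None, :], xp - x, 0.0)
    dlp -= np.where((cols == 0)[None, :], xp - x, 0.0)
    bad = (xp > _THETA_HI) | (xp < _THETA_LO)
    bad |= (cols == 0)[None, :] & ((xp >= log_u) | (xp <= log_l))
    dlp = np.where(bad, -np.inf, dlp)

    acc = np.log(rng.random(x.shape)) < dlp
    theta[:, cols] = np.where(acc, xp, x)
    return cols, acc


def _sitewise_move(theta, obs, mask, r, beta, log_l, log_u, delta, rng):
    """Accept/reject a per-site proposal theta + delta (delta: (I, T))."""
    lp0 = _site_logpost(theta, obs, mask, r, beta, log_l, log_u)
    prop = theta + delta
    bad = (prop.max(axis=1) > _THETA_HI) | (prop.min(axis=1) < _THETA_LO)
    lp1 = _site_logpost(prop, obs, mask, r, beta, log_l, log_u)
    lp1 = np.where(bad, -np.inf, lp1)
    acc = np.log(rng.random(theta.shape[0])) < lp1 - lp0
    theta[acc] = prop[acc]
    return acc


def _hyper_logpost(lb, sg, s1, s2, m):
    r = lb * lb / (sg * sg)
    beta = lb / (sg * sg)
    lp = m * (r * np.log(beta) - gammaln(r)) + (r - 1.0) * s1 - beta * s2
    a, b = _LB_PRIOR
    lp += (a - 1.0) * np.log(lb) - b * lb
    a, b = _SG_PRIOR
    lp += (a - 1.0) * np.log(sg) - b * sg
    # log-scale random-walk Jacobians
    lp += np.log(lb) + np.log(sg)
    return lp


def _log_gamma_draw(shape, rate, size, rng):
    """log of Gamma(shape, rate) draws, stable for arbitrarily small shape.

    Uses the boosting identity G(a) = G(a + 1) * U^(1/a), which stays finite
    in log space where a direct draw would underflow to zero.
    """
    g = rng.gamma(shape + 1.0, 1.0, size=size)
    u = rng.random(size=size)
    return np.log(g) + np.log(u) / shape - np.log(rate)


def _prior_rejuvenation(theta, lb, sg, obs, mask, rng):
    """Independence move: propose (lb, sg, all growth rates) from the prior.

    Acceptance is the observation-likelihood ratio alone (prior and proposal
    cancel), so with missing data the move samples the prior exactly; with
    informative data it is almost always rejected and merely guards against
    the random-walk moves getting trapped far from the prior's mass.
    """
    I, T = theta.shape
    lb_p = float(np.exp(_log_gamma_draw(_LB_PRIOR[0], _LB_PRIOR[1], None, rng)))
    sg_p = float(rng.gamma(_SG_PRIOR[0], 1.0 / _SG_PRIOR[1]))
    if not (np.isfinite(lb_p) and lb_p > 0 and sg_p > 0):
        return theta, lb, sg, False
    r_p = lb_p * lb_p / (sg_p * sg_p)
    be_p = lb_p / (sg_p * sg_p)
    if T > 1:
        log_lam = _log_gamma_draw(r_p, be_p, (I, T - 1), rng)
        if not np.isfinite(log_lam).all():
            return theta, lb, sg, False
        prop = np.empty_like(theta)
        prop[:, 0] = theta[:, 0]
        prop[:, 1:] = theta[:, :1] + np.cumsum(log_lam, axis=1)
    else:
        prop = theta.copy()
    if prop.max() > _THETA_HI or prop.min() < _THETA_LO:
        return theta, lb, sg, False
    dll = float(
        (
            np.where(mask, obs * prop - _cexp(prop), 0.0)
            - np.where(mask, obs * theta - _cexp(theta), 0.0)
        ).sum()
    )
    if np.log(rng.random()) < dll:
        return prop, lb_p, sg_p, True
    return theta, lb, sg, False


def _update_hypers(lb, sg, theta, steps, rng, n_reps=8):
    d = np.diff(theta, axis=1)
    s1 = float(d.sum())
    s2 = float(_cexp(d).sum())
    m = d.size
    lp = _hyper_logpost(lb, sg, s1, s2, m)
    acc = np.zeros(2)
    for _ in range(n_reps):
        lb_p = lb * np.exp(rng.normal(0.0, steps[0]))
        lp_p = _hyper_logpost(lb_p, sg, s1, s2, m)
        if np.log(rng.random()) < lp_p - lp:
            lb, lp = lb_p, lp_p
            acc[0] += 1
        sg_p = sg * np.exp(rng.normal(0.0, steps[1]))
        lp_p = _hyper_logpost(lb, sg_p, s1, s2, m)
        if np.log(rng.random()) < lp_p - lp:
            sg, lp = sg_p, lp_p
            acc[1] += 1
    return lb, sg, acc / n_reps


class _NmixKernel:
    """Collapsed-X machinery for the two-occasion N-mixture layer.

    With X ~ Poisson(N) and two conditionally independent Binomial(X, p)
    counts, the marginal of (y1, y2) is bivariate Poisson:

        y1 = A + C,  y2 = B + C,
        A, B ~ Poisson(N p (1-p)),  C ~ Poisson(N p^2)  independent,

    and the unobserved remainder is D ~ Poisson(N (1-p)^2) with
    X = y1 + y2 - C + D.  This yields (a) a closed-form likelihood of the
    counts with X integrated out, used for Metropolis updates of p on the
    logit scale, and (b) an exact draw of X from its full conditional
    (categorical over the shared component C via Gumbel-max, plus the
    Poisson remainder D) — no random-walk on X, and no detection/abundance
    ridge for the sampler to crawl along.
    """

    def __init__(self, y_occ: np.ndarray):
        if y_occ.shape[2] != 2:
            raise ValueError("the N-mixture sampler expects exactly two occasions")
        self.shape = y_occ.shape[:2]
        y1 = y_occ[:, :, 0].astype(np.int64).ravel()
        y2 = y_occ[:, :, 1].astype(np.int64).ravel()
        self.y1 = y1.reshape(self.shape)
        self.y2 = y2.reshape(self.shape)
        self.sy = (y1 + y2).reshape(self.shape)
        sy = y1 + y2
        ymin = np.minimum(y1, y2)
        # group cells by the length of their C-summation: in a declining
        # population most site-years have tiny counts, so small groups keep
        # the (cells x k) work arrays compact
        self._groups = []
        bounds = [0, 4, 16, int(ymin.max())]
        lo = -1
        for hi in bounds:
            if hi < lo:
                continue
            idx = np.flatnonzero((ymin > lo) & (ymin <= hi))
            lo = hi
            if idx.size == 0:
                continue
            k = np.arange(hi + 1)
            g_y1, g_y2, g_min = y1[idx], y2[idx], ymin[idx]
            base = -(
                gammaln(g_y1[:, None] - k + 1.0)
                + gammaln(g_y2[:, None] - k + 1.0)
                + gammaln(k + 1.0)
            )
            self._groups.append(
                {
                    "idx": idx,
                    "base": np.where(k <= g_min[:, None], base, -np.inf),
                    "coef_n": (sy[idx, None] - k).astype(float),
                    "coef_1mp": (sy[idx, None] - 2 * k).astype(float),
                    "sy": sy[idx],
                }
            )

    def _lse_and_c(self, theta, pmat, rng=None):
        """Flat per-cell logsumexp over C (and a C draw when rng is given)."""
        th = theta.ravel()
        l1 = np.log1p(-pmat).ravel()
        out = np.empty(th.size)
        c_draw = np.empty(th.size, dtype=np.int64) if rng is not None else None
        for g in self._groups:
            a = g["base"] + g["coef_n"] * th[g["idx"], None]
            a += g["coef_1mp"] * l1[g["idx"], None]
            amax = a.max(axis=1)
            out[g["idx"]] = amax + np.log(np.exp(a - amax[:, None]).sum(axis=1))
            if rng is not None:
                gumbel = -np.log(-np.log(rng.random(a.shape)))
                c_draw[g["idx"]] = np.argmax(a + gumbel, axis=1)
        return out, c_draw

    def marginal_loglik(self, theta, pmat):
        """Per-cell log P(y1, y2 | N = e^theta, p), X integrated out."""
        with np.errstate(divide="ignore", invalid="ignore"):
            lse, _ = self._lse_and_c(theta, pmat)
            ll = lse.reshape(self.shape) + self.sy * np.log(pmat)
        n = _cexp(theta)
        return ll - n * (1.0 - (1.0 - pmat) ** 2)

    def update_p(self, theta, pmat, structure, step, rng):
        """Metropolis update of p under the collapsed likelihood."""
        I, T = theta.shape
        if structure == "shared":
            p = pmat[:1, :1]
            axes: tuple[int, ...] = (0, 1)
        elif structure == "by_year":
            p = pmat[:1, :]
            axes = (0,)
        else:
            p = pmat
            axes = ()
        delta = rng.normal(0.0, 1.0, p.shape) * step
        p2 = 1.0 / (1.0 + np.exp(-(np.log(p) - np.log1p(-p) + delta)))
        p2 = np.clip(p2, 1e-9, 1.0 - 1e-9)
        ll0 = self.marginal_loglik(theta, np.broadcast_to(p, (I, T)))
        ll1 = self.marginal_loglik(theta, np.broadcast_to(p2, (I, T)))
        d = ll1 - ll0
        block = d.sum(axis=axes, keepdims=True) if axes else d
        # Beta(1,1) prior is flat in p; logit random walk needs the Jacobian
        block = block + np.log(p2 * (1.0 - p2)) - np.log(p * (1.0 - p))
        acc = np.log(rng.random(block.shape)) < block
        new_p = np.where(acc, p2, p)
        return np.broadcast_to(new_p, (I, T)).copy(), float(acc.mean())

    def draw_x(self, theta, pmat, rng):
        """Exact draw of X from its conditional given N, p and the counts."""
        with np.errstate(divide="ignore", invalid="ignore"):
            _, c = self._lse_and_c(theta, pmat, rng=rng)
        d = rng.poisson(_cexp(theta) * (1.0 - pmat) ** 2)
        return self.sy - c.reshape(self.shape) + d


def run_chain(
    *,
    model: str,
    y: np.ndarray,
    y_occ: np.ndarray | None,
    p_structure: str,
    warmup: int,
    draws: int,
    rng: np.random.Generator,
    init_upper_factor: float = 10.0,
    store_latent: str = "total",
) -> ChainDraws:
    """Run one MCMC chain; ``y`` is the (I, T) table of per-year max counts
    (entries < 0 are treated as missing), ``y_occ`` the (I, T, J) occasion
    table for the N-mixture."""
    I, T = y.shape
    mask = y >= 0
    y_f = np.where(mask, y, 0).astype(float)
    upper = init_upper_factor * (float(y_f.max()) + 1.0)
    log_u = np.log(upper)
    log_l = np.log(1e-3)  # lower support of the log-uniform N1 prior

    # --- initialization (mildly dispersed across chains via rng) ---
    fill = float(y_f[mask].mean()) if mask.any() else 1.0
    level = np.where(mask, y_f, fill)
    if model == "nmixture":
        kernel = _NmixKernel(y_occ)
        # moment init: Var(y1 - y2 | X) = 2 X p (1 - p), E[y] = X p
        # => 1 - p ~ mean((y1 - y2)^2) / (2 mean(y))
        ybar = float(y_occ.mean())
        disp = float(((kernel.y1 - kernel.y2) ** 2).mean())
        p0 = 1.0 - disp / max(2.0 * ybar, 1e-9) if ybar > 0 else 0.5
        p0 = float(np.clip(p0 + rng.normal(0.0, 0.05), 0.05, 0.95))
        pmat = np.clip(np.full((I, T), p0), 1e-9, 1.0 - 1e-9)
        theta = np.log(y_occ.max(axis=2) / p0 + 0.5) + rng.normal(0.0, 0.1, (I, T))
        x = kernel.draw_x(theta, pmat, rng)
    else:
        kernel = None
        x = None
        pmat = None
        theta = np.log(level + 0.5) + rng.normal(0.0, 0.1, (I, T))
    theta = np.clip(theta, log_l + 0.05, log_u - 0.05)
    lb = float(np.exp(rng.normal(np.log(0.9), 0.1)))
    sg = float(np.exp(rng.normal(np.log(0.5), 0.2)))

    # --- adaptive step sizes ---
    step_cols = np.full((I, T), 0.5)
    step_row = np.full(I, 0.3)
    step_tilt = np.full(I, 0.04)
    step_gtilt = 0.01
    step_px = 0.1
    step_gpx = 0.1
    step_crow = np.full(I, 0.2)
    step_hyp = np.array([0.05, 0.05])
    t_idx = np.arange(T, dtype=float)
    t_centered = t_idx - t_idx.mean()

    out_lb = np.empty(draws)
    out_sg = np.empty(draws)
    out_nt = np.empty((draws, T))
    out_p = np.empty((draws, T)) if model == "nmixture" else None
    out_xt = np.empty((draws, T)) if model == "nmixture" else None
    out_full = np.empty((draws, I, T)) if store_latent == "full" else None
    acc_tally = {
        "cols": 0.0, "row": 0.0, "tilt": 0.0, "gtilt": 0.0,
        "hyper": np.zeros(2), "px": 0.0, "gpx": 0.0, "prior": 0.0,
    }

    total = warmup + draws
    for it in range(total):
        adapting = it < warmup
        gamma = min(0.25, 4.0 / np.sqrt(it + 10.0)) if adapting else 0.0
        r = lb * lb / (sg * sg)
        beta = lb / (sg * sg)

        if model == "nmixture":
            update_block = it % 2 == 0 or it < 100
            if update_block:
                # collapsed per-site level shift: with X integrated out the
                # overall abundance scale can trade off against p; a level move
                # against Poisson(X) alone would stay pinned to the current X.
                # The whole detection block runs on alternate sweeps (every
                # sweep early on, while adaptation settles) — X and p are
                # nuisance layers whose slower refresh leaves the theta moves,
                # which dominate cost, untouched
                run_crow = it % 4 == 0
                delta = rng.normal(0.0, 1.0, I) * step_crow
                prop = theta + delta[:, None]
                if run_crow:
                    dlp = (
                        kernel.marginal_loglik(prop, pmat)
                        - kernel.marginal_loglik(theta, pmat)
                    ).sum(axis=1)
                    bad = (
                        (prop[:, 0] >= log_u)
                        | (prop[:, 0] <= log_l)
                        | (prop.max(axis=1) > _THETA_HI)
                        | (prop.min(axis=1) < _THETA_LO)
                    )
                    dlp = np.where(bad, -np.inf, dlp)
                    acc = np.log(rng.random(I)) < dlp
                    theta[acc] = prop[acc]
                    if adapting:
                        step_crow *= np.exp(gamma * (acc - 0.30))

                pmat, acc_p = kernel.update_p(theta, pmat, p_structure, step_px, rng)
                if adapting:
                    step_px *= np.exp(gamma * (acc_p - 0.35))

                # joint global scale move: nudge every p on the logit scale and
                # translate all theta to keep N * p (the expected counts) fixed —
                # the one direction the data constrain only weakly
                if p_structure == "shared":
                    p_free = pmat[:1, :1]
                elif p_structure == "by_year":
                    p_free = pmat[:1, :]
                else:
                    p_free = pmat
                run_gpx = not run_crow
                dg = rng.normal(0.0, step_gpx)
                if run_gpx:
                    p2_free = 1.0 / (
                        1.0 + np.exp(-(np.log(p_free) - np.log1p(-p_free) + dg))
                    )
                    p2_free = np.clip(p2_free, 1e-9, 1.0 - 1e-9)
                    c = float(np.mean(np.log(p_free) - np.log(p2_free)))
                    prop = theta + c
                    p2mat = np.broadcast_to(p2_free, (I, T)).copy()
                    dlp_g = (
                        kernel.marginal_loglik(prop, p2mat)
                        - kernel.marginal_loglik(theta, pmat)
                    ).sum()
                    dlp_g += float(
                        (
                            np.log(p2_free * (1.0 - p2_free))
                            - np.log(p_free * (1.0 - p_free))
                        ).sum()
                    )
                    if (
                        (prop[:, 0] >= log_u).any()
                        or (prop[:, 0] <= log_l).any()
                        or prop.max() > _THETA_HI
                        or prop.min() < _THETA_LO
                    ):
                        acc_g = False
                    else:
                        acc_g = bool(np.log(rng.random()) < dlp_g)
                    if acc_g:
                        theta = prop
                        pmat = p2mat
                    if adapting:
                        step_gpx *= np.exp(gamma * (float(acc_g) - 0.30))
                    acc_tally["gpx"] += float(acc_g) / 2.0

                x = kernel.draw_x(theta, pmat, rng)
            obs = x.astype(float)
            obs_mask = np.ones_like(mask)
            acc_tally["px"] += acc_p
        else:
            obs = y_f
            obs_mask = mask

        for parity in (0, 1, 0, 1):
            cols, acc = _update_columns(
                theta, obs, obs_mask, r, beta, step_cols, rng, log_l, log_u, parity
            )
            if adapting:
                step_cols[:, cols] *= np.exp(gamma * (acc - 0.44))
            acc_tally["cols"] += acc.mean() / 2.0

        delta_row = rng.normal(0.0, 1.0, I) * step_row
        acc = _sitewise_move(
            theta, obs, obs_mask, r, beta, log_l, log_u, delta_row[:, None] * np.ones(T), rng
        )
        if adapting:
            step_row *= np.exp(gamma * (acc - 0.30))
        acc_tally["row"] += acc.mean()

        delta_tilt = rng.normal(0.0, 1.0, I) * step_tilt
        acc = _sitewise_move(
            theta, obs, obs_mask, r, beta, log_l, log_u, delta_tilt[:, None] * t_centered, rng
        )
        if adapting:
            step_tilt *= np.exp(gamma * (acc - 0.30))
        acc_tally["tilt"] += acc.mean()

        # global trend tilt: one shared slope perturbation, helps lambda_bar mix
        delta_g = rng.normal(0.0, step_gtilt)
        lp0 = _site_logpost(theta, obs, obs_mask, r, beta, log_l, log_u).sum()
        prop = theta + delta_g * t_centered
        lp1 = _site_logpost(prop, obs, obs_mask, r, beta, log_l, log_u).sum()
        in_bounds = prop.max() <= _THETA_HI and prop.min() >= _THETA_LO
        acc_g = np.log(rng.random()) < lp1 - lp0 and in_bounds
        if acc_g:
            theta = prop
        if adapting:
            step_gtilt *= np.exp(gamma * (float(acc_g) - 0.30))
        acc_tally["gtilt"] += float(acc_g)

        lb, sg, acc_h = _update_hypers(lb, sg, theta, step_hyp, rng)
        if adapting:
            step_hyp *= np.exp(gamma * (acc_h - 0.44))
        acc_tally["hyper"] += acc_h

        if it % 5 == 0:
            theta, lb, sg, acc_prior = _prior_rejuvenation(
                theta, lb, sg, obs, obs_mask, rng
            )
            acc_tally["prior"] += float(acc_prior) / 5.0

        if not adapting:
            k = it - warmup
            out_lb[k] = lb
            out_sg[k] = sg
            n_mat = _cexp(theta)
            out_nt[k] = n_mat.sum(axis=0)
            if model == "nmixture":
                out_p[k] = pmat.mean(axis=0)
                out_xt[k] = x.sum(axis=0)
            if out_full is not None:
                out_full[k] = n_mat

    for key in ("cols", "row", "tilt", "gtilt", "px", "gpx", "prior"):
        acc_tally[key] /= total
    acc_tally["hyper"] = acc_tally["hyper"] / total
    return ChainDraws(
        lambda_bar=out_lb,
        sigma_lambda=out_sg,
        n_total=out_nt,
        p_year=out_p,
        x_total=out_xt,
        n_full=out_full,
        accept_rates=acc_tally,
    )
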