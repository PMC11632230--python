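"""Mixed-effects location-scale regression for measurement-burst FI data.

Observation model for person i, burst b, wave t::

    y_ibt ~ Normal(mu_ibt, sigma_ibt^2)
    mu_ibt      = x' beta + u_i + w_ib + s_ib * wave_c
    log sigma_ibt = z' gamma + a_i + c_ib

with jointly Gaussian random effects: person-level (u_i, a_i) with SDs
(tau_u, tau_a) and correlation rho_P, and person-burst-level (w_ib, s_ib,
c_ib) with SDs (tau_w, tau_s, tau_c), free correlations loc-wave and
loc-scale, and the wave-scale correlation fixed at zero.  Scale-submodel
coefficients are reported exponentiated (multiplicative on the residual SD).

Estimation integrates the random effects out of the likelihood with a
block-wise Laplace approximation: each person's random-effect block is
independent given the parameters, so the joint mode and curvature are found
by a vectorised per-person Newton solve, and the marginal likelihood is the
sum of per-person Laplace terms.  An adaptive Gauss-Hermite scheme over the
same blocks is available for small problems (``method="aghq"``); Laplace is
its order-1 special case.  The default engine maximises the marginal
posterior (weakly-informative priors) and draws approximate posterior
samples from a Gaussian centred at the mode; an ``emcee`` ensemble-sampler
engine over the same marginal posterior is available as the MCMC option.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from numpy.polynomial.hermite import hermgauss
from scipy.optimize import minimize
from scipy.special import logsumexp
from sklearn.base import BaseEstimator

from .design import Design, MelsmSpec, build_design
from .frailty import fi_frame
from .panel import DeficitPanel

_LOG2PI = np.log(2.0 * np.pi)


# ---------------------------------------------------------------------------
# parameter packing


@dataclass
class ParamIndex:
    loc_names: tuple[str, ...]
    sc_names: tuple[str, ...]
    sd_names: tuple[str, ...]
    cor_names: tuple[str, ...]

    @property
    def n(self) -> int:
        return len(self.loc_names) + len(self.sc_names) + len(self.sd_names) + len(self.cor_names)

    @property
    def slices(self) -> dict[str, slice]:
        p, q = len(self.loc_names), len(self.sc_names)
        k, c = len(self.sd_names), len(self.cor_names)
        return {
            "beta": slice(0, p),
            "gamma": slice(p, p + q),
            "logsd": slice(p + q, p + q + k),
            "zcor": slice(p + q + k, p + q + k + c),
        }

    @property
    def names(self) -> list[str]:
        return (
            [f"loc_{t}" for t in self.loc_names]
            + [f"sc_{t}" for t in self.sc_names]
            + [f"log_{t}" for t in self.sd_names]
            + [f"z_{t}" for t in self.cor_names]
        )

    def unpack(self, theta: np.ndarray) -> dict:
        s = self.slices
        return {
            "beta": np.asarray(theta[s["beta"]], dtype=float),
            "gamma": np.asarray(theta[s["gamma"]], dtype=float),
            "sds": dict(zip(self.sd_names, np.exp(theta[s["logsd"]]))),
            "cors": dict(zip(self.cor_names, np.tanh(theta[s["zcor"]]))),
        }

    def pack(self, params: dict) -> np.ndarray:
        sds = params["sds"]
        cors = params.get("cors", {})
        return np.concatenate(
            [
                np.asarray(params["beta"], dtype=float),
                np.asarray(params["gamma"], dtype=float),
                np.log([sds[n] for n in self.sd_names]),
                np.arctanh([cors.get(n, 0.0) for n in self.cor_names]),
            ]
        )

    @classmethod
    def from_spec(cls, spec: MelsmSpec) -> "ParamIndex":
        return cls(
            loc_names=spec.location_fixed,
            sc_names=spec.scale_fixed,
            sd_names=spec.sd_names,
            cor_names=spec.cor_names,
        )


def sigma_block(spec: MelsmSpec, sds: dict, cors: dict) -> np.ndarray:
    """Random-effect covariance of one person block (person + two burst slots)."""
    blocks = []
    if spec.has_scale_re:
        su, sa = sds["sd_person_loc"], sds["sd_person_sc"]
        rp = cors["cor_person_loc_sc"]
        blocks.append(np.array([[su**2, rp * su * sa], [rp * su * sa, sa**2]]))
    else:
        blocks.append(np.array([[sds["sd_person_loc"] ** 2]]))

    names = list(spec.burst_effects)
    nb = len(names)
    s = np.array(
        [
            {"loc_int": sds["sd_burst_loc"], "wave": sds.get("sd_burst_wave", 0.0), "sc_int": sds.get("sd_burst_sc", 0.0)}[n]
            for n in names
        ]
    )
    R = np.eye(nb)
    if "wave" in names:
        i, j = names.index("loc_int"), names.index("wave")
        R[i, j] = R[j, i] = cors["cor_burst_loc_wave"]
    if "sc_int" in names:
        i, j = names.index("loc_int"), names.index("sc_int")
        R[i, j] = R[j, i] = cors["cor_burst_loc_sc"]
    Sb = (s[:, None] * R) * s[None, :]
    for _ in range(2):
        blocks.append(Sb)
    d = sum(b.shape[0] for b in blocks)
    S = np.zeros((d, d))
    off = 0
    for b in blocks:
        k = b.shape[0]
        S[off : off + k, off : off + k] = b
        off += k
    return S


# ---------------------------------------------------------------------------
# observation families
#
# Each family returns per-row derivatives of the observation log density
# l(eta, lambda) with eta the location and lambda the log residual SD:
# order 0: "l"; order 2 adds first/second partials (ge, gl, hee, hel, hll);
# order 3 adds the partials of the Hessian weights needed for the exact
# gradient of the Laplace log-determinant.


def _normal_obs(y, eta, lam, order=0):
    s2 = np.exp(-2.0 * lam)
    e = y - eta
    out = {"l": -0.5 * _LOG2PI - lam - 0.5 * e**2 * s2}
    if order >= 2:
        out.update(
            ge=e * s2,
            gl=e**2 * s2 - 1.0,
            hee=-s2,
            hel=-2.0 * e * s2,
            hll=-2.0 * e**2 * s2,
        )
    if order >= 3:
        out.update(
            dhee_de=np.zeros_like(e),
            dhee_dl=2.0 * s2,
            dhel_de=2.0 * s2,
            dhel_dl=4.0 * e * s2,
            dhll_de=4.0 * e * s2,
            dhll_dl=4.0 * e**2 * s2,
        )
    return out


def _trunc_tail_ratios(eta, lam):
    """Stable log Z and hazard-type ratios for Normal truncated to [0, 1]."""
    from scipy.special import log_ndtr

    s = np.exp(-np.clip(lam, -20.0, 20.0))
    a = np.clip((0.0 - eta) * s, -3e3, 3e3)
    b = np.clip((1.0 - eta) * s, -3e3, 3e3)
    lower = log_ndtr(a)
    upper = log_ndtr(b)
    neg_lower = log_ndtr(-a)
    neg_upper = log_ndtr(-b)
    with np.errstate(divide="ignore", invalid="ignore"):
        left = upper + np.log1p(-np.exp(np.minimum(lower - upper, -1e-300)))
        right = neg_lower + np.log1p(-np.exp(np.minimum(neg_upper - neg_lower, -1e-300)))
    logZ = np.where(a + b < 0.0, left, right)
    logZ = np.maximum(np.nan_to_num(logZ, nan=-700.0, neginf=-700.0), -700.0)
    logphi_a = -0.5 * _LOG2PI - 0.5 * a**2
    logphi_b = -0.5 * _LOG2PI - 0.5 * b**2
    ra = np.exp(np.minimum(logphi_a - logZ, 30.0))
    rb = np.exp(np.minimum(logphi_b - logZ, 30.0))
    return s, a, b, logZ, ra, rb


def _trunc_F_derivs(eta, lam):
    """First and second partials of F = log Z(eta, lambda)."""
    s, a, b, logZ, ra, rb = _trunc_tail_ratios(eta, lam)
    Fe = s * (ra - rb)
    Fl = a * ra - b * rb
    F_aa = a * ra - ra**2
    F_ab = ra * rb
    F_bb = -b * rb - rb**2
    F_a, F_b = -ra, rb
    Fee = s**2 * (F_aa + 2.0 * F_ab + F_bb)
    Fel = s * (a * F_aa + (a + b) * F_ab + b * F_bb + F_a + F_b)
    Fll = a**2 * F_aa + 2.0 * a * b * F_ab + b**2 * F_bb + a * F_a + b * F_b
    return logZ, Fe, Fl, Fee, Fel, Fll


def _truncnorm_obs(y, eta, lam, order=0):
    out = _normal_obs(y, eta, lam, order)
    logZ, Fe, Fl, Fee, Fel, Fll = _trunc_F_derivs(eta, lam)
    out["l"] = out["l"] - logZ
    if order >= 2:
        out["ge"] = out["ge"] - Fe
        out["gl"] = out["gl"] - Fl
        out["hee"] = out["hee"] - Fee
        out["hel"] = out["hel"] - Fel
        out["hll"] = out["hll"] - Fll
    if order >= 3:
        # third partials of F by central differences of its analytic second
        # partials (the Gaussian part stays closed-form)
        de = 1e-4 * np.exp(np.clip(lam, -20.0, 20.0)) + 1e-9
        dl = 1e-4
        _, _, _, Fee_ep, Fel_ep, Fll_ep = _trunc_F_derivs(eta + de, lam)
        _, _, _, Fee_em, Fel_em, Fll_em = _trunc_F_derivs(eta - de, lam)
        _, _, _, Fee_lp, Fel_lp, Fll_lp = _trunc_F_derivs(eta, lam + dl)
        _, _, _, Fee_lm, Fel_lm, Fll_lm = _trunc_F_derivs(eta, lam - dl)
        out["dhee_de"] = out["dhee_de"] - (Fee_ep - Fee_em) / (2.0 * de)
        out["dhel_de"] = out["dhel_de"] - (Fel_ep - Fel_em) / (2.0 * de)
        out["dhll_de"] = out["dhll_de"] - (Fll_ep - Fll_em) / (2.0 * de)
        out["dhee_dl"] = out["dhee_dl"] - (Fee_lp - Fee_lm) / (2.0 * dl)
        out["dhel_dl"] = out["dhel_dl"] - (Fel_lp - Fel_lm) / (2.0 * dl)
        out["dhll_dl"] = out["dhll_dl"] - (Fll_lp - Fll_lm) / (2.0 * dl)
    return out


_OBS_FAMILIES = {"normal": _normal_obs, "truncated_normal": _truncnorm_obs}


# ---------------------------------------------------------------------------
# grouped data layout


class _Grouped:
    """Per-person padded arrays for the vectorised Laplace solve."""

    def __init__(self, design: Design):
        spec = design.spec
        self.design = design
        self.spec = spec
        codes = design.person_codes
        n = design.n_obs
        P = design.n_persons
        counts = np.bincount(codes, minlength=P)
        J = int(counts.max())
        order = np.argsort(codes, kind="stable")
        jj = np.empty(n, dtype=int)
        starts = np.r_[0, np.cumsum(counts[:-1])]
        jj[order] = np.arange(n) - np.repeat(starts, counts)
        self.p_idx, self.j_idx = codes, jj
        self.P, self.J = P, J

        p, q = design.X.shape[1], design.Z.shape[1]
        self.Y = np.zeros((P, J))
        self.M = np.zeros((P, J), dtype=bool)
        self.X = np.zeros((P, J, p))
        self.Z = np.zeros((P, J, q))
        self.Y[codes, jj] = design.y
        self.M[codes, jj] = True
        self.X[codes, jj] = design.X
        self.Z[codes, jj] = design.Z

        # random-effect block layout: person effects first, then burst slots
        npe = len(spec.person_effects)
        be = list(spec.burst_effects)
        nbe = len(be)
        self.d = npe + 2 * nbe
        AL = np.zeros((P, J, self.d))
        AS = np.zeros((P, J, self.d))
        AL[codes, jj, 0] = 1.0  # person location intercept
        if spec.has_scale_re:
            AS[codes, jj, 1] = 1.0  # person scale intercept
        bpos = design.burst - 1
        for b in (0, 1):
            rows = bpos == b
            off = npe + b * nbe
            AL[codes[rows], jj[rows], off + be.index("loc_int")] = 1.0
            if "wave" in be:
                AL[codes[rows], jj[rows], off + be.index("wave")] = design.wave_c[rows]
            if "sc_int" in be:
                AS[codes[rows], jj[rows], off + be.index("sc_int")] = 1.0
        self.AL, self.AS = AL, AS

    # -- penalized joint density ---------------------------------------

    def _linpred(self, beta, gamma, r):
        mu = self.X @ beta + np.einsum("pjd,...pd->...pj", self.AL, r)
        lam = self.Z @ gamma + np.einsum("pjd,...pd->...pj", self.AS, r)
        return mu, np.clip(lam, -20.0, 20.0)

    @property
    def _obs(self):
        return _OBS_FAMILIES[self.spec.family]

    def penalized(self, beta, gamma, r, Sinv, logdetS, obs=None):
        """log p(y | r) + log p(r) per person (supports leading batch dims on r)."""
        mu, lam = self._linpred(beta, gamma, r)
        ll = (obs or self._obs)(self.Y, mu, lam, 0)["l"]
        obs_sum = np.sum(np.where(self.M, ll, 0.0), axis=-1)
        quad = np.einsum("...pd,de,...pe->...p", r, Sinv, r)
        prior = -0.5 * (quad + logdetS + self.d * _LOG2PI)
        return obs_sum + prior

    def grad_hess(self, beta, gamma, r, Sinv, obs=None):
        mu, lam = self._linpred(beta, gamma, r)
        o = (obs or self._obs)(self.Y, mu, lam, 2)
        m = self.M
        gL = np.where(m, o["ge"], 0.0)
        gS = np.where(m, o["gl"], 0.0)
        grad = (
            np.einsum("pj,pjd->pd", gL, self.AL)
            + np.einsum("pj,pjd->pd", gS, self.AS)
            - r @ Sinv
        )
        w1 = np.where(m, o["hee"], 0.0)
        w2 = np.where(m, o["hel"], 0.0)
        w3 = np.where(m, o["hll"], 0.0)
        H = (
            np.einsum("pj,pjk,pjl->pkl", w1, self.AL, self.AL)
            + np.einsum("pj,pjk,pjl->pkl", w2, self.AL, self.AS)
            + np.einsum("pj,pjk,pjl->pkl", w2, self.AS, self.AL)
            + np.einsum("pj,pjk,pjl->pkl", w3, self.AS, self.AS)
            - Sinv[None, :, :]
        )
        return grad, H

    def solve_modes(self, beta, gamma, Sinv, logdetS, r0=None, tol=5e-8, maxit=100):
        """Batched saddle-free Newton ascent to the per-person conditional modes.

        The joint density is not concave everywhere in the scale coordinates,
        so the Hessian is repaired per person (eigenvalues clipped below a
        negative floor) before solving; with step halving this is a globally
        ascending iteration.  Cold starts under the truncated family are
        homotoped: the modes of the benign plain-normal model initialise the
        truncated solve, avoiding its quasi-degenerate boundary ridges.
        """
        if r0 is None and self.spec.family == "truncated_normal":
            r0, _, _ = self._newton(
                beta, gamma, Sinv, logdetS, None, 1e-6, 50, obs=_normal_obs
            )
        return self._newton(beta, gamma, Sinv, logdetS, r0, tol, maxit)

    def _newton(self, beta, gamma, Sinv, logdetS, r0, tol, maxit, obs=None):
        r = np.zeros((self.P, self.d)) if r0 is None else r0.copy()
        f = self.penalized(beta, gamma, r, Sinv, logdetS, obs=obs)
        H = None
        stall = 0
        damp = np.zeros(self.P)  # per-person Levenberg damping for stiff blocks
        for _ in range(maxit):
            grad, H = self.grad_hess(beta, gamma, r, Sinv, obs=obs)
            gmax = np.max(np.abs(grad), axis=1)
            if np.max(gmax) < tol:
                break
            evals, evecs = np.linalg.eigh(H)
            emax = np.max(np.abs(evals), axis=1, keepdims=True)
            floor = -1e-8 * (1.0 + emax)
            evals = np.minimum(evals, floor) - damp[:, None]
            gproj = np.einsum("pdk,pd->pk", evecs, grad)
            delta = np.einsum("pdk,pk->pd", evecs, gproj / evals)
            alpha = np.ones(self.P)
            f_try = f
            for _ in range(40):
                r_try = r - alpha[:, None] * delta
                f_try = self.penalized(beta, gamma, r_try, Sinv, logdetS, obs=obs)
                bad = ~(f_try >= f - 1e-13)
                if not bad.any():
                    break
                alpha[bad] *= 0.5
            improved = f_try >= f - 1e-13
            gain = float(np.max(np.where(improved, f_try - f, 0.0), initial=0.0))
            r = np.where(improved[:, None], r_try, r)
            f = np.where(improved, f_try, f)
            # persons whose step was rejected or heavily halved get damping;
            # smooth progress relaxes it again
            rough = (~improved) | (alpha < 1e-3)
            damp = np.where(rough, np.maximum(damp * 10.0, 1e-4 * emax[:, 0]), damp * 0.3)
            if not improved.any():
                break
            # floating-point stall: objective no longer moves measurably
            stall = stall + 1 if gain < 1e-12 else 0
            if stall >= 2:
                break
        # polish: full undamped Newton steps for persons already in the
        # quadratic regime; extremely stiff blocks (boundary-pinned data)
        # otherwise stall with gradient residuals large enough to break the
        # envelope property of the outer gradient
        for _ in range(4):
            grad, H = self.grad_hess(beta, gamma, r, Sinv, obs=obs)
            if np.max(np.abs(grad)) < tol:
                break
            try:
                delta = np.linalg.solve(H, grad[..., None])[..., 0]
            except np.linalg.LinAlgError:
                break
            dec = np.einsum("pd,pd->p", grad, delta)  # < 0 iff locally concave
            safe = (dec < 0) & (np.max(np.abs(delta), axis=1) < 0.05)
            r_try = r - np.where(safe[:, None], delta, 0.0)
            f_try = self.penalized(beta, gamma, r_try, Sinv, logdetS, obs=obs)
            keep = safe & (f_try >= f - 1e-11)
            r = np.where(keep[:, None], r_try, r)
            f = np.where(keep, f_try, f)
            if not keep.any():
                break
        _, H = self.grad_hess(beta, gamma, r, Sinv, obs=obs)
        return r, f, H

    def laplace_value_grad(self, beta, gamma, Sinv, logdetS, dSigmas, r0=None):
        """Laplace marginal log-likelihood and its exact gradient.

        The gradient combines the envelope term (the conditional modes are
        stationary), the direct derivative of the log-determinant correction
        (third derivatives of the joint density, available in closed form for
        the Gaussian location-scale likelihood), and the indirect term through
        the movement of the modes.  ``dSigmas`` is the list of derivatives of
        the random-effect covariance block with respect to each variance
        parameter (log-SD / atanh-correlation scale).
        """
        r, f, H = self.solve_modes(beta, gamma, Sinv, logdetS, r0=r0)
        evals, evecs = np.linalg.eigh(-H)  # (P, d), (P, d, d)
        emax = evals.max(axis=1, keepdims=True)
        if np.any(evals.min(axis=1) < -1e-5 * emax[:, 0]):
            # genuinely indefinite curvature: not at a maximum
            raise np.linalg.LinAlgError("conditional-mode Hessian not negative definite")
        # floating-point stalls can leave tiny negative eigenvalues; clip
        evals = np.maximum(evals, 1e-9 * emax)
        logdet_negH = np.sum(np.log(evals), axis=1)
        value = float(np.sum(f + 0.5 * self.d * _LOG2PI - 0.5 * logdet_negH))

        C = np.einsum("pdk,pk,pek->pde", evecs, 1.0 / evals, evecs)  # (-H)^-1
        mu, lam = self._linpred(beta, gamma, r)
        o = self._obs(self.Y, mu, lam, 3)
        m = self.M
        gL = np.where(m, o["ge"], 0.0)
        gS = np.where(m, o["gl"], 0.0)
        hee = np.where(m, o["hee"], 0.0)
        hel = np.where(m, o["hel"], 0.0)
        hll = np.where(m, o["hll"], 0.0)

        CAL = np.einsum("pde,pje->pjd", C, self.AL)
        CAS = np.einsum("pde,pje->pjd", C, self.AS)
        QLL = np.einsum("pjd,pjd->pj", self.AL, CAL)
        QLS = np.einsum("pjd,pjd->pj", self.AL, CAS)
        QSS = np.einsum("pjd,pjd->pj", self.AS, CAS)
        # per-row trace terms: tr(C dH_j/d eta_j) and tr(C dH_j/d lambda_j)
        Teta = np.where(m, o["dhee_de"], 0.0) * QLL + 2.0 * np.where(
            m, o["dhel_de"], 0.0
        ) * QLS + np.where(m, o["dhll_de"], 0.0) * QSS
        Tlam = np.where(m, o["dhee_dl"], 0.0) * QLL + 2.0 * np.where(
            m, o["dhel_dl"], 0.0
        ) * QLS + np.where(m, o["dhll_dl"], 0.0) * QSS
        D = np.einsum("pj,pjk->pk", Teta, self.AL) + np.einsum("pj,pjk->pk", Tlam, self.AS)
        CD = np.einsum("pde,pe->pd", C, D)

        # beta: envelope + direct logdet + indirect through the modes
        env_b = np.einsum("pj,pjm->m", gL, self.X)
        dir_b = 0.5 * np.einsum("pj,pjm->m", Teta, self.X)
        Gb = np.einsum("pj,pjk,pjm->pkm", hee, self.AL, self.X) + np.einsum(
            "pj,pjk,pjm->pkm", hel, self.AS, self.X
        )
        ind_b = 0.5 * np.einsum("pk,pkm->m", CD, Gb)
        grad_beta = env_b + dir_b + ind_b

        env_g = np.einsum("pj,pjm->m", gS, self.Z)
        dir_g = 0.5 * np.einsum("pj,pjm->m", Tlam, self.Z)
        Gg = np.einsum("pj,pjk,pjm->pkm", hel, self.AL, self.Z) + np.einsum(
            "pj,pjk,pjm->pkm", hll, self.AS, self.Z
        )
        ind_g = 0.5 * np.einsum("pk,pkm->m", CD, Gg)
        grad_gamma = env_g + dir_g + ind_g

        grad_phi = np.empty(len(dSigmas))
        trC = np.sum(C, axis=0)
        for i, dS in enumerate(dSigmas):
            A = Sinv @ dS @ Sinv  # = dH/dphi = -d(Sigma^-1)/dphi
            env = 0.5 * float(np.einsum("pk,kl,pl->", r, A, r)) - 0.5 * self.P * float(
                np.trace(Sinv @ dS)
            )
            direct = 0.5 * float(np.einsum("kl,lk->", trC, A))
            rA = r @ A  # A symmetric
            indirect = 0.5 * float(np.einsum("pk,pk->", CD, rA))
            grad_phi[i] = env + direct + indirect
        return value, grad_beta, grad_gamma, grad_phi, r

    def pointwise(self, beta, gamma, r):
        """Conditional per-row log densities in the original row order."""
        mu, lam = self._linpred(beta, gamma, r)
        ll = self._obs(self.Y, mu, lam, 0)["l"]
        return ll[self.p_idx, self.j_idx]


def _cov_from_params(spec: MelsmSpec, params: dict):
    S = sigma_block(spec, params["sds"], params["cors"])
    # Cholesky, not slogdet: an indefinite correlation block can still have a
    # positive determinant (negative eigenvalues come in pairs here)
    L = np.linalg.cholesky(S)
    logdetS = 2.0 * float(np.sum(np.log(np.diag(L))))
    return np.linalg.inv(S), logdetS


def marginal_loglik(
    design: Design,
    params: dict,
    method: str = "laplace",
    order: int = 9,
    grouped: _Grouped | None = None,
    r0: np.ndarray | None = None,
):
    """Marginal log-likelihood of the data with random effects integrated out.

    ``params`` holds ``beta``, ``gamma``, ``sds`` and ``cors`` (see
    :class:`ParamIndex`).  ``method="laplace"`` uses the block Laplace
    approximation (exact when no scale random effects are present);
    ``method="aghq"`` refines it with an adaptive Gauss-Hermite tensor grid of
    the given order per dimension (small problems only).  Returns the scalar
    log-likelihood and the per-person conditional modes.
    """
    g = grouped or _Grouped(design)
    Sinv, logdetS = _cov_from_params(g.spec, params)
    beta, gamma = np.asarray(params["beta"], float), np.asarray(params["gamma"], float)
    r, f, H = g.solve_modes(beta, gamma, Sinv, logdetS, r0=r0)
    sign, logdet_negH = np.linalg.slogdet(-H)
    if np.any(sign <= 0) and r0 is not None:
        # a warm start can stall at a saddle; retry from the prior mean
        r, f, H = g.solve_modes(beta, gamma, Sinv, logdetS, r0=None)
        sign, logdet_negH = np.linalg.slogdet(-H)
    if np.any(sign <= 0):
        # repair residual indefiniteness (floating-point stalls) by clipping
        evals = np.linalg.eigvalsh(-H)
        logdet_negH = np.sum(np.log(np.clip(evals, 1e-10, None)), axis=1)
        warnings.warn("conditional-mode curvature repaired for some persons", stacklevel=2)
    laplace = f + 0.5 * g.d * _LOG2PI - 0.5 * logdet_negH

    if method == "laplace":
        return float(np.sum(laplace)), r
    if method != "aghq":
        raise ValueError(f"unknown integration method {method!r}")

    # integrate only "active" coordinates per person: coordinates of an
    # unattended burst carry no data, are independent of the rest in the
    # block covariance, and integrate to one exactly
    x, w = hermgauss(order)
    total = 0.0
    S = np.linalg.inv(Sinv)
    for i in range(g.P):
        used = np.abs(g.AL[i][g.M[i]]).sum(axis=0) + np.abs(g.AS[i][g.M[i]]).sum(axis=0)
        act = np.flatnonzero(used > 0)
        inact = np.flatnonzero(used == 0)
        da = len(act)
        if order**da > 2_000_000:
            raise ValueError("aghq tensor grid too large; use Laplace for this problem size")
        grids = np.meshgrid(*([x] * da), indexing="ij")
        Zn = np.stack([gr.ravel() for gr in grids], axis=-1)
        wgrids = np.meshgrid(*([np.log(w)] * da), indexing="ij")
        logw = np.sum(np.stack([wg.ravel() for wg in wgrids], axis=-1), axis=1)
        Ha = H[i][np.ix_(act, act)]
        L = np.linalg.cholesky(np.linalg.inv(-Ha))
        nodes = r[i][act] + np.sqrt(2.0) * Zn @ L.T
        rr = np.zeros((nodes.shape[0], g.P, g.d))
        rr[:, i, act] = nodes
        fk = g.penalized(beta, gamma, rr, Sinv, logdetS)[:, i]
        # remove the prior density of the zeroed inactive coordinates
        if len(inact):
            Sin = S[np.ix_(inact, inact)]
            _, ld_in = np.linalg.slogdet(Sin)
            fk = fk + 0.5 * (len(inact) * _LOG2PI + ld_in)
        li = logsumexp(logw + fk + np.sum(Zn**2, axis=1)) + 0.5 * da * np.log(2.0) + np.sum(
            np.log(np.diag(L))
        )
        total += li
    return float(total), r


def joint_loglik(design: Design, params: dict, random_effects: np.ndarray) -> float:
    """Joint log density of data and random effects at a given point.

    ``random_effects`` has shape (n_persons, block_dim) in the block layout
    (person effects, then burst-1 and burst-2 effects).
    """
    g = _Grouped(design)
    Sinv, logdetS = _cov_from_params(g.spec, params)
    f = g.penalized(
        np.asarray(params["beta"], float),
        np.asarray(params["gamma"], float),
        np.asarray(random_effects, float),
        Sinv,
        logdetS,
    )
    return float(np.sum(f))


# ---------------------------------------------------------------------------
# posterior objective


class _NegLogPost:
    """Negative marginal log-posterior with warm-started inner modes."""

    def __init__(self, grouped: _Grouped, idx: ParamIndex, intercept_prior_sd: float = 5.0):
        self.g = grouped
        self.idx = idx
        self.intercept_prior_sd = intercept_prior_sd
        self.r_cache: np.ndarray | None = None
        self.n_eval = 0

    def log_prior(self, theta: np.ndarray) -> float:
        s = self.idx.slices
        lp = 0.0
        for block, names in (("beta", self.idx.loc_names), ("gamma", self.idx.sc_names)):
            vals = theta[s[block]]
            sds = np.where(np.array(names) == "intercept", self.intercept_prior_sd, 1.0)
            lp += float(np.sum(-0.5 * (vals / sds) ** 2))
        logsd = theta[s["logsd"]]
        tau = np.exp(logsd)
        lp += float(np.sum(-0.5 * tau**2 + logsd))  # half-Normal(0,1) + log Jacobian
        z = theta[s["zcor"]]
        rho = np.tanh(z)
        cors = dict(zip(self.idx.cor_names, rho))
        lp += float(np.sum(np.log1p(-(rho**2))))  # atanh Jacobian
        # LKJ(2) density on each correlation block: log det(R)
        if "cor_person_loc_sc" in cors:
            det = 1.0 - cors["cor_person_loc_sc"] ** 2
            if det <= 1e-12:
                return -np.inf
            lp += np.log(det)
        det_b = 1.0 - cors.get("cor_burst_loc_wave", 0.0) ** 2 - cors.get("cor_burst_loc_sc", 0.0) ** 2
        if det_b <= 1e-12:
            return -np.inf
        lp += np.log(det_b)
        return lp

    def _log_prior_grad(self, theta: np.ndarray) -> np.ndarray:
        s = self.idx.slices
        grad = np.zeros_like(theta)
        for block, names in (("beta", self.idx.loc_names), ("gamma", self.idx.sc_names)):
            sds = np.where(np.array(names) == "intercept", self.intercept_prior_sd, 1.0)
            grad[s[block]] = -theta[s[block]] / sds**2
        tau = np.exp(theta[s["logsd"]])
        grad[s["logsd"]] = 1.0 - tau**2
        z = theta[s["zcor"]]
        rho = np.tanh(z)
        gz = -2.0 * rho  # atanh Jacobian term, d log(1 - rho^2) / dz
        cors = dict(zip(self.idx.cor_names, rho))
        for i, name in enumerate(self.idx.cor_names):
            if name == "cor_person_loc_sc":
                gz[i] += -2.0 * rho[i]  # LKJ(2) on the 2x2 person block
        det_b = 1.0 - cors.get("cor_burst_loc_wave", 0.0) ** 2 - cors.get("cor_burst_loc_sc", 0.0) ** 2
        for i, name in enumerate(self.idx.cor_names):
            if name in ("cor_burst_loc_wave", "cor_burst_loc_sc"):
                gz[i] += -2.0 * rho[i] * (1.0 - rho[i] ** 2) / det_b  # LKJ on burst block
        grad[s["zcor"]] = gz
        return grad

    def _dSigmas(self, theta: np.ndarray, h: float = 1e-6) -> list[np.ndarray]:
        s = self.idx.slices
        out = []
        for off in list(range(*s["logsd"].indices(len(theta)))) + list(
            range(*s["zcor"].indices(len(theta)))
        ):
            tp, tm = theta.copy(), theta.copy()
            tp[off] += h
            tm[off] -= h
            pp, pm = self.idx.unpack(tp), self.idx.unpack(tm)
            Sp = sigma_block(self.g.spec, pp["sds"], pp["cors"])
            Sm = sigma_block(self.g.spec, pm["sds"], pm["cors"])
            out.append((Sp - Sm) / (2.0 * h))
        return out

    def value_and_grad(self, theta: np.ndarray) -> tuple[float, np.ndarray]:
        self.n_eval += 1
        lp = self.log_prior(theta)
        if not np.isfinite(lp):
            return 1e12, np.zeros_like(theta)
        params = self.idx.unpack(theta)
        try:
            Sinv, logdetS = _cov_from_params(self.g.spec, params)
            value, gb, gg, gphi, r = self.g.laplace_value_grad(
                params["beta"], params["gamma"], Sinv, logdetS, self._dSigmas(theta), r0=self.r_cache
            )
        except np.linalg.LinAlgError:
            return 1e12, np.zeros_like(theta)
        self.r_cache = r
        grad = -(np.concatenate([gb, gg, gphi]) + self._log_prior_grad(theta))
        return -(value + lp), grad

    def __call__(self, theta: np.ndarray) -> float:
        self.n_eval += 1
        lp = self.log_prior(theta)
        if not np.isfinite(lp):
            return 1e12
        params = self.idx.unpack(theta)
        try:
            Sinv, logdetS = _cov_from_params(self.g.spec, params)
            r, f, H = self.g.solve_modes(
                params["beta"], params["gamma"], Sinv, logdetS, r0=self.r_cache
            )
            sign, logdet_negH = np.linalg.slogdet(-H)
            if np.any(sign <= 0):
                return 1e12
            ll = float(np.sum(f + 0.5 * self.g.d * _LOG2PI - 0.5 * logdet_negH))
        except np.linalg.LinAlgError:
            return 1e12
        self.r_cache = r
        return -(ll + lp)

    def logpost(self, theta: np.ndarray) -> float:
        v = self(theta)
        return -v if v < 1e11 else -np.inf


def _numerical_hessian(value_and_grad, x, steps):
    """Hessian by central differences of the analytic gradient (2n evals).

    ``steps`` carries one step per coordinate, scaled to its curvature, so
    gradient differences stay far above the floating-point noise left by the
    inner mode solves.
    """
    n = len(x)
    H = np.empty((n, n))
    for i in range(n):
        ei = np.zeros(n)
        ei[i] = steps[i]
        _, gp = value_and_grad(x + ei)
        _, gm = value_and_grad(x - ei)
        H[i] = (gp - gm) / (2.0 * steps[i])
    return (H + H.T) / 2.0


# ---------------------------------------------------------------------------
# estimator


class LocationScaleMixedRegression(BaseEstimator):
    """Mixed-effects location-scale regression on a long FI panel.

    Parameters
    ----------
    model : str
        Ladder model id, one of ``M0``..``M4``.
    engine : str
        ``"map"`` (marginal posterior mode + Gaussian approximation, default)
        or ``"mcmc"`` (emcee ensemble sampler over the marginal posterior).
    draws : int
        Number of posterior draws kept for summaries and derived quantities.
    mcmc_steps, mcmc_walkers : int
        Ensemble-sampler schedule (``engine="mcmc"``); half the steps are
        discarded as burn-in.
    seed : int
        Seed for every stochastic stage (posterior draws, sampler).
    age_center : float, optional
        Origin for age centring; defaults to the sample mean over persons.
    compute_uncertainty : bool
        Skip the curvature/draws stage when False (point estimates only).
    maxiter : int
        Outer optimiser iteration cap.

    Fitted attributes use the sklearn trailing-underscore convention:
    ``location_coefs_`` / ``scale_coefs_`` (coefficient tables, the scale one
    exponentiated with a raw-log column), ``random_sd_``, ``random_cor_``,
    ``loglik_``, ``draws_``, ``converged_``, ``warnings_``.
    """

    _RHAT_THRESHOLD = 1.01
    _ESS_THRESHOLD = 400.0

    def __init__(
        self,
        model: str = "M4",
        engine: str = "map",
        family: str = "normal",
        draws: int = 1000,
        mcmc_steps: int = 500,
        mcmc_walkers: int | None = None,
        seed: int = 0,
        age_center: float | None = None,
        compute_uncertainty: bool = True,
        maxiter: int = 2000,
    ):
        self.model = model
        self.engine = engine
        self.family = family
        self.draws = draws
        self.mcmc_steps = mcmc_steps
        self.mcmc_walkers = mcmc_walkers
        self.seed = seed
        self.age_center = age_center
        self.compute_uncertainty = compute_uncertainty
        self.maxiter = maxiter

    # -- fitting --------------------------------------------------------

    def fit(self, X, y=None):
        if self.engine not in ("map", "mcmc"):
            raise ValueError("engine must be 'map' or 'mcmc'")
        data = fi_frame(X) if isinstance(X, DeficitPanel) else X
        self.spec_ = MelsmSpec.from_model_id(self.model, family=self.family)
        self.design_ = build_design(data, self.spec_, age_center=self.age_center)
        self.idx_ = ParamIndex.from_spec(self.spec_)
        g = _Grouped(self.design_)
        self._grouped = g
        obj = _NegLogPost(g, self.idx_)
        x0 = self._initial_theta(g)
        if self.spec_.family == "truncated_normal":
            # the truncated likelihood is violently non-linear where the mean
            # sits far outside [0, 1]; stage one fits the plain-normal model,
            # whose optimum is a benign starting point
            import dataclasses as _dc

            design_n = _dc.replace(
                self.design_, spec=_dc.replace(self.spec_, family="normal")
            )
            obj_n = _NegLogPost(_Grouped(design_n), self.idx_)
            res_n = self._optimize(obj_n, x0)
            x0 = res_n.x
        res = self._optimize(obj, x0)
        self.theta_map_ = res.x
        self.params_map_ = self.idx_.unpack(res.x)
        ll, r_hat = marginal_loglik(self.design_, self.params_map_, grouped=g, r0=obj.r_cache)
        self.loglik_ = ll
        self.random_effect_modes_ = r_hat
        self.n_obs_ = self.design_.n_obs
        self.warnings_ = []
        self.converged_ = bool(res.success) or res.status == 0
        if not self.converged_:
            self.warnings_.append(f"optimizer: {res.message}")
            warnings.warn(f"MELSM fit did not converge cleanly: {res.message}", stacklevel=2)

        rng = np.random.default_rng(self.seed)
        if self.engine == "mcmc":
            self._run_mcmc(obj, rng)
        elif self.compute_uncertainty:
            self._laplace_draws(obj, rng)
        else:
            self.draws_ = self.theta_map_[None, :].repeat(2, axis=0)
        self._summarize()
        return self

    def _optimize(self, obj: _NegLogPost, x0: np.ndarray):
        # box bounds keep log-SDs away from the unidentified -inf tail when a
        # variance component is effectively zero
        s = self.idx_.slices
        lo = np.full(self.idx_.n, -30.0)
        hi = np.full(self.idx_.n, 30.0)
        lo[s["logsd"]], hi[s["logsd"]] = -8.0, 2.0
        lo[s["zcor"]], hi[s["zcor"]] = -6.0, 6.0
        x0 = np.clip(x0, lo, hi)

        # diagonal preconditioning: curvature varies over ~6 orders of
        # magnitude between FI-unit fixed effects and log-SDs, which cripples
        # L-BFGS; estimate per-coordinate curvature from the analytic gradient
        eps = 1e-5
        f0, g0 = obj.value_and_grad(x0)
        curv = np.ones(self.idx_.n)
        for k in range(self.idx_.n):
            xk = x0.copy()
            xk[k] += eps
            fk, gk = obj.value_and_grad(xk)
            if fk < 1e11 and f0 < 1e11 and np.isfinite(gk[k]):
                curv[k] = (gk[k] - g0[k]) / eps
        # cap the curvature range: a quasi-degenerate boundary block can fake
        # astronomic curvature at the probe point, and the resulting minuscule
        # steps would sink later finite differences into gradient noise
        scale = 1.0 / np.sqrt(np.clip(np.abs(curv), 1.0, 1e9))

        self._precond_scale_ = scale

        def scaled(z):
            f, g = obj.value_and_grad(x0 + scale * z)
            return f, g * scale

        bounds = list(zip((lo - x0) / scale, (hi - x0) / scale))
        z0 = np.zeros(self.idx_.n)
        res = None
        for _ in range(3):  # restart on premature line-search aborts
            res = minimize(
                scaled,
                z0,
                jac=True,
                method="L-BFGS-B",
                bounds=bounds,
                options={"maxiter": self.maxiter, "ftol": 1e-10, "gtol": 1e-5, "maxls": 50},
            )
            if res.status != 2:
                break
            z0 = res.x
        res.x = x0 + scale * res.x
        return res

    def _initial_theta(self, g: _Grouped) -> np.ndarray:
        d = self.design_
        beta, *_ = np.linalg.lstsq(d.X, d.y, rcond=None)
        resid = d.y - d.X @ beta
        sd_resid = max(float(np.std(resid)), 1e-3)
        gamma = np.zeros(len(self.idx_.sc_names))
        gamma[0] = np.log(0.7 * sd_resid)
        pm = pd.Series(resid).groupby(d.person_codes).mean()
        sd_person = max(float(pm.std()), 1e-3)
        sds = {
            "sd_person_loc": sd_person,
            "sd_person_sc": 0.3,
            "sd_burst_loc": 0.5 * sd_person,
            "sd_burst_wave": 0.01,
            "sd_burst_sc": 0.3,
        }
        params = {
            "beta": beta,
            "gamma": gamma,
            "sds": {n: sds[n] for n in self.idx_.sd_names},
            "cors": {n: 0.0 for n in self.idx_.cor_names},
        }
        return self.idx_.pack(params)

    def _laplace_draws(self, obj: _NegLogPost, rng) -> None:
        steps = 0.05 * getattr(self, "_precond_scale_", np.ones(self.idx_.n))
        H = _numerical_hessian(obj.value_and_grad, self.theta_map_, steps)
        evals, evecs = np.linalg.eigh(H)
        if np.any(evals <= 0):
            self.warnings_.append("posterior curvature not positive definite; clipped")
        # flat directions (a variance component pinned at its bound) get a
        # curvature floor on the prior's own scale, so draw SDs stay bounded
        evals = np.clip(evals, 0.1, None)
        L = evecs * (1.0 / np.sqrt(evals))
        zs = rng.standard_normal((self.draws, len(self.theta_map_)))
        draws = self.theta_map_[None, :] + zs @ L.T
        s = self.idx_.slices
        draws[:, s["logsd"]] = np.clip(draws[:, s["logsd"]], -8.0, 2.0)
        draws[:, s["zcor"]] = np.clip(draws[:, s["zcor"]], -6.0, 6.0)
        self.draws_ = draws

    def _run_mcmc(self, obj: _NegLogPost, rng) -> None:
        import emcee

        ndim = len(self.theta_map_)
        nwalkers = self.mcmc_walkers or max(2 * ndim + 2, 16)
        p0 = self.theta_map_[None, :] + 1e-3 * rng.standard_normal((nwalkers, ndim))
        sampler = emcee.EnsembleSampler(nwalkers, ndim, obj.logpost)
        sampler.random_state = np.random.RandomState(self.seed).get_state()
        sampler.run_mcmc(p0, self.mcmc_steps, progress=False)
        burn = self.mcmc_steps // 2
        chain = sampler.get_chain(discard=burn)  # (steps, walkers, dim)
        import arviz as az

        posterior = {n: chain[:, :, i].T for i, n in enumerate(self.idx_.names)}
        idata = az.from_dict(posterior=posterior)
        rhat = az.rhat(idata).to_array().values
        ess = az.ess(idata).to_array().values
        self.rhat_max_ = float(np.nanmax(rhat))
        self.ess_min_ = float(np.nanmin(ess))
        if self.rhat_max_ > self._RHAT_THRESHOLD:
            self.warnings_.append(f"rhat {self.rhat_max_:.3f} exceeds {self._RHAT_THRESHOLD}")
        if self.ess_min_ < self._ESS_THRESHOLD:
            self.warnings_.append(f"bulk ESS {self.ess_min_:.0f} below {self._ESS_THRESHOLD:.0f}")
        if self.warnings_:
            self.converged_ = False
        flat = chain.reshape(-1, ndim)
        take = min(self.draws, flat.shape[0])
        sel = rng.choice(flat.shape[0], size=take, replace=False)
        self.draws_ = flat[sel]

    # -- summaries ------------------------------------------------------

    def _summarize(self) -> None:
        idx = self.idx_
        s = idx.slices
        th = self.theta_map_
        dr = self.draws_

        def ci(mat):
            return np.quantile(mat, [0.025, 0.975], axis=0)

        b_lo, b_hi = ci(dr[:, s["beta"]])
        self.location_coefs_ = pd.DataFrame(
            {
                "estimate": th[s["beta"]],
                "ci_low": b_lo,
                "ci_high": b_hi,
            },
            index=list(idx.loc_names),
        )
        g_raw = th[s["gamma"]]
        g_lo, g_hi = ci(dr[:, s["gamma"]])
        self.scale_coefs_ = pd.DataFrame(
            {
                "estimate": np.exp(g_raw),
                "ci_low": np.exp(g_lo),
                "ci_high": np.exp(g_hi),
                "log_estimate": g_raw,
            },
            index=list(idx.sc_names),
        )
        sd_lo, sd_hi = ci(np.exp(dr[:, s["logsd"]]))
        self.random_sd_ = pd.DataFrame(
            {
                "estimate": np.exp(th[s["logsd"]]),
                "ci_low": sd_lo,
                "ci_high": sd_hi,
            },
            index=list(idx.sd_names),
        )
        if len(idx.cor_names):
            c_lo, c_hi = ci(np.tanh(dr[:, s["zcor"]]))
            self.random_cor_ = pd.DataFrame(
                {
                    "estimate": np.tanh(th[s["zcor"]]),
                    "ci_low": np.atleast_1d(c_lo),
                    "ci_high": np.atleast_1d(c_hi),
                },
                index=list(idx.cor_names),
            )
        else:
            self.random_cor_ = pd.DataFrame(columns=["estimate", "ci_low", "ci_high"])

    # -- derived quantities ---------------------------------------------

    def decompose_variance(self) -> dict:
        """Three-level variance decomposition from the unconditional model (M0)."""
        if self.model != "M0":
            raise ValueError("variance decomposition is defined for the M0 fit only")
        sds = self.params_map_["sds"]
        within = float(np.exp(2.0 * self.params_map_["gamma"][0]))
        return variance_decomposition(
            between_person=sds["sd_person_loc"] ** 2,
            between_burst=sds["sd_burst_loc"] ** 2,
            within_burst=within,
        )

    def pointwise_loglik(
        self, n_draws: int = 200, seed: int | None = None, level: str = "observation"
    ) -> np.ndarray:
        """Per-draw pointwise log-likelihood matrix.

        ``level="observation"`` returns per-row log densities conditional on
        the random-effect modes recomputed at each posterior draw;
        ``level="person"`` returns the per-person marginal (Laplace)
        log-likelihood contributions, the exchangeable unit for
        leave-one-cluster-out comparison of grouped data.
        """
        if level not in ("observation", "person"):
            raise ValueError("level must be 'observation' or 'person'")
        rng = np.random.default_rng(self.seed if seed is None else seed)
        take = min(n_draws, self.draws_.shape[0])
        sel = rng.choice(self.draws_.shape[0], size=take, replace=False)
        g = self._grouped
        out = np.empty((take, self.n_obs_ if level == "observation" else g.P))
        r0 = self.random_effect_modes_
        for k, i in enumerate(sel):
            params = self.idx_.unpack(self.draws_[i])
            try:
                Sinv, logdetS = _cov_from_params(self.spec_, params)
                r, f, H = g.solve_modes(
                    params["beta"], params["gamma"], Sinv, logdetS, r0=r0
                )
            except np.linalg.LinAlgError:
                params = self.params_map_
                Sinv, logdetS = _cov_from_params(self.spec_, params)
                r, f, H = g.solve_modes(
                    params["beta"], params["gamma"], Sinv, logdetS, r0=r0
                )
            if level == "observation":
                out[k] = g.pointwise(
                    np.asarray(params["beta"]), np.asarray(params["gamma"]), r
                )
            else:
                evals = np.linalg.eigvalsh(-H)
                logdet_negH = np.sum(np.log(np.clip(evals, 1e-12, None)), axis=1)
                out[k] = f + 0.5 * g.d * _LOG2PI - 0.5 * logdet_negH
        return out

    def bayes_r2(self, n_draws: int = 400) -> float:
        """Bayesian R-squared based on the fixed effects.

        Per draw: var(X beta) / (var(X beta) + random-effect variance +
        expected residual variance), averaged over the posterior draws.  The
        expected residual variance integrates the log-normal scale random
        effects: E[sigma^2] = exp(2 z'gamma) * exp(2 (tau_a^2 + tau_c^2)).
        """
        d = self.design_
        s = self.idx_.slices
        take = min(n_draws, self.draws_.shape[0])
        vals = np.empty(take)
        mean_w2 = float(np.mean(d.wave_c**2))
        for k in range(take):
            params = self.idx_.unpack(self.draws_[k])
            fv = d.X @ params["beta"]
            var_f = float(np.var(fv))
            sds = params["sds"]
            rand = sds["sd_person_loc"] ** 2 + sds["sd_burst_loc"] ** 2
            if "sd_burst_wave" in sds:
                rand += sds["sd_burst_wave"] ** 2 * mean_w2
            tau_sc2 = sds.get("sd_person_sc", 0.0) ** 2 + sds.get("sd_burst_sc", 0.0) ** 2
            resid = float(np.mean(np.exp(2.0 * (d.Z @ params["gamma"])) * np.exp(2.0 * tau_sc2)))
            vals[k] = var_f / (var_f + rand + resid)
        return float(np.mean(vals))

    def predict(self, data: pd.DataFrame, what: str = "location") -> np.ndarray:
        """Fixed-effects prediction of the FI mean or residual SD."""
        des = build_design(
            data.assign(fi=0.0) if "fi" not in data.columns else data,
            self.spec_,
            age_center=self.design_.age_center,
        )
        if what == "location":
            return des.X @ self.params_map_["beta"]
        if what == "scale":
            return np.exp(des.Z @ self.params_map_["gamma"])
        raise ValueError("what must be 'location' or 'scale'")

    def report_table(self, fmt: str = "frame", digits: int = 2):
        """Coefficient table: mu and (exponentiated) sigma columns plus random effects.

        ``fmt`` is ``"frame"`` (DataFrame), ``"csv"`` or ``"markdown"``.  For
        location-only models the sigma column is suppressed.
        """
        return report_table(self, fmt=fmt, digits=digits)


def variance_decomposition(
    between_person: float, between_burst: float, within_burst: float
) -> dict:
    """Percentages of total variance by level; always sums to 100."""
    comps = np.array([between_person, between_burst, within_burst], dtype=float)
    if np.any(comps < 0):
        raise ValueError("variance components must be non-negative")
    total = comps.sum()
    if total <= 0:
        raise ValueError("total variance must be positive")
    pct = 100.0 * comps / total
    return {
        "between_person_pct": float(pct[0]),
        "between_burst_pct": float(pct[1]),
        "within_burst_pct": float(pct[2]),
        "variances": {
            "between_person": float(comps[0]),
            "between_burst": float(comps[1]),
            "within_burst": float(comps[2]),
        },
    }


# ---------------------------------------------------------------------------
# module-level operation wrappers


def fit(
    data,
    model: str = "M4",
    engine: str = "map",
    seed: int = 0,
    **kwargs,
) -> LocationScaleMixedRegression:
    """Fit a ladder model; thin wrapper over :class:`LocationScaleMixedRegression`."""
    return LocationScaleMixedRegression(model=model, engine=engine, seed=seed, **kwargs).fit(data)


def decompose_variance(fitted: LocationScaleMixedRegression) -> dict:
    return fitted.decompose_variance()


def bayes_r2(fitted: LocationScaleMixedRegression, n_draws: int = 400) -> float:
    return fitted.bayes_r2(n_draws=n_draws)


def compare_models(
    fit_a: LocationScaleMixedRegression,
    fit_b: LocationScaleMixedRegression,
    n_draws: int = 200,
    method: str = "loo",
    level: str = "person",
) -> dict:
    """Pointwise information-criterion comparison (PSIS-LOO by default).

    The pointwise unit defaults to the person (leave-one-cluster-out on the
    marginal likelihood) — the exchangeable unit of a grouped panel, and the
    comparison that properly penalises extra random effects; observation-level
    conditional likelihoods are available via ``level``.  Returns the elpd
    difference (b minus a) with its standard error and a ``preferred`` label
    when the difference exceeds twice its SE.
    """
    import arviz as az

    if fit_a.n_obs_ != fit_b.n_obs_ or not np.allclose(fit_a.design_.y, fit_b.design_.y):
        raise ValueError("fits must be on identical data rows")
    res = {}
    loo_i = {}
    for name, f in (("a", fit_a), ("b", fit_b)):
        mat = f.pointwise_loglik(n_draws=n_draws, level=level)
        idata = az.from_dict(log_likelihood={"y": mat[None, :, :]})
        # draws are near-independent (Gaussian approximation or thinned chain)
        loo = (
            az.loo(idata, pointwise=True, reff=1.0)
            if method == "loo"
            else az.waic(idata, pointwise=True)
        )
        res[name] = float(loo.elpd_loo if method == "loo" else loo.elpd_waic)
        loo_i[name] = np.asarray(loo.loo_i if method == "loo" else loo.waic_i)
    diff_i = loo_i["b"] - loo_i["a"]
    n = diff_i.size
    se = float(np.sqrt(n * np.var(diff_i, ddof=1)))
    diff = float(res["b"] - res["a"])
    preferred = None
    if abs(diff) > 2.0 * se:
        preferred = "b" if diff > 0 else "a"
    return {
        "elpd_a": res["a"],
        "elpd_b": res["b"],
        "elpd_diff": diff,
        "se_diff": se,
        "preferred": preferred,
    }


def report_table(fitted: LocationScaleMixedRegression, fmt: str = "frame", digits: int = 2):
    has_scale = fitted.spec_.has_scale_submodel
    rows = []

    def _fmt(v):
        return "" if v is None or (isinstance(v, float) and np.isnan(v)) else f"{v:.{digits}f}"

    for term in fitted.location_coefs_.index:
        mu = fitted.location_coefs_.loc[term]
        row = {
            "block": "fixed",
            "term": term,
            "mu": round(float(mu["estimate"]), digits),
            "mu_ci_low": round(float(mu["ci_low"]), digits),
            "mu_ci_high": round(float(mu["ci_high"]), digits),
        }
        if has_scale and term in fitted.scale_coefs_.index:
            sg = fitted.scale_coefs_.loc[term]
            row.update(
                sigma=round(float(sg["estimate"]), digits),
                sigma_ci_low=round(float(sg["ci_low"]), digits),
                sigma_ci_high=round(float(sg["ci_high"]), digits),
            )
        rows.append(row)
    for name in fitted.random_sd_.index:
        r = fitted.random_sd_.loc[name]
        rows.append(
            {
                "block": "random_sd",
                "term": name,
                "mu": round(float(r["estimate"]), digits),
                "mu_ci_low": round(float(r["ci_low"]), digits),
                "mu_ci_high": round(float(r["ci_high"]), digits),
            }
        )
    for name in fitted.random_cor_.index:
        r = fitted.random_cor_.loc[name]
        rows.append(
            {
                "block": "random_cor",
                "term": name,
                "mu": round(float(r["estimate"]), digits),
                "mu_ci_low": round(float(r["ci_low"]), digits),
                "mu_ci_high": round(float(r["ci_high"]), digits),
            }
        )
    rows.append({"block": "fit", "term": "marginal_loglik", "mu": round(fitted.loglik_, digits)})
    table = pd.DataFrame(rows)
    if fmt == "frame":
        return table
    if fmt == "csv":
        return table.to_csv(index=False, lineterminator="\n")
    if fmt == "markdown":
        cols = list(table.columns)
        lines = ["| " + " | ".join(cols) + " |", "| " + " | ".join("---" for _ in cols) + " |"]
        for _, r in table.iterrows():
            cells = []
            for c in cols:
                v = r[c]
                if isinstance(v, float):
                    cells.append("" if np.isnan(v) else f"{v:.{digits}f}")
                else:
                    cells.append("" if v is None else str(v))
            lines.append("| " + " | ".join(cells) + " |")
        return "\n".join(lines) + "\n"
    raise ValueError("fmt must be 'frame', 'csv' or 'markdown'")


def posterior_predictive_mean_isd(
    fitted: LocationScaleMixedRegression, n_rep: int = 200, seed: int = 0
) -> dict:
    """Replicate the design from the fitted parameters and recompute the mean iSD.

    Simulates fresh random effects and observations on the observed design
    rows, computes the mean within-burst iSD per replicate, and returns its
    predictive distribution alongside the observed value (self-consistency
    check of the scale submodel).
    """
    g = fitted._grouped
    d = fitted.design_
    params = fitted.params_map_
    S = sigma_block(fitted.spec_, params["sds"], params["cors"])
    L = np.linalg.cholesky(S + 1e-12 * np.eye(S.shape[0]))
    rng = np.random.default_rng(seed)

    def mean_isd(yvec):
        df = pd.DataFrame(
            {"pid": d.person_codes, "burst": d.burst, "y": yvec}
        )
        sds = df.groupby(["pid", "burst"])["y"].agg(["std", "count"])
        return float(sds.loc[sds["count"] > 1, "std"].mean())

    obs = mean_isd(d.y)
    reps = np.empty(n_rep)
    for k in range(n_rep):
        r = rng.standard_normal((g.P, g.d)) @ L.T
        mu, lam = g._linpred(np.asarray(params["beta"]), np.asarray(params["gamma"]), r)
        if fitted.spec_.family == "truncated_normal":
            from scipy.stats import truncnorm as _tn

            sg = np.exp(lam)
            yrep = _tn.rvs((0 - mu) / sg, (1 - mu) / sg, loc=mu, scale=sg, random_state=rng)
        else:
            yrep = mu + np.exp(lam) * rng.standard_normal(mu.shape)
        reps[k] = mean_isd(yrep[g.p_idx, g.j_idx])
    lo, hi = np.quantile(reps, [0.025, 0.975])
    return {
        "observed": obs,
        "predictive_mean": float(reps.mean()),
        "ci_low": float(lo),
        "ci_high": float(hi),
        "replicates": reps,
    }
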