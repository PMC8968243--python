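"""Panel logit with a normally distributed random opt-out constant.

The opt-out constant delta_io ~ N(delta_o, sigma_o^2) is drawn once per
respondent and shared across that respondent's tasks, which induces the
panel correlation a plain conditional logit ignores.  Estimation is by
maximum simulated likelihood: the per-respondent likelihood is the
product of task probabilities averaged over R draws of the constant,

    ll_i = log (1/R) sum_r prod_t P(chosen_it | delta_ir),
    delta_ir = delta_o + sigma_o * z_ir.

Halton deviates (base 3, burn-in discarded) are the default draw scheme.
The same code path evaluates the likelihood on Gauss-Hermite nodes,
which serves as a deterministic quadrature cross-check of the simulated
integral.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats

from ..data import ChoiceDataset
from ..spec import ModelSpec, Parameters
from .base import (
    Design,
    DiscreteChoiceResults,
    build_design,
    covariance_from_hessian,
    numerical_hessian,
)
from .clogit import SEPARATION_BOUND, ConditionalLogit


def van_der_corput(n: int, base: int = 3, skip: int = 10) -> np.ndarray:
    """First ``n`` radical-inverse points in the given base after burn-in."""
    k = np.arange(1 + skip, n + 1 + skip, dtype=np.int64)
    out = np.zeros(n)
    f = 1.0
    while k.any():
        f /= base
        out += f * (k % base)
        k //= base
    return out


@dataclass
class DrawSet:
    """Standard-normal deviates, one block of R per respondent."""

    R: int
    scheme: str
    seed: int
    values: np.ndarray  # (n_resp, R)

    @classmethod
    def generate(
        cls, n_resp: int, R: int = 500, scheme: str = "halton", seed: int = 0
    ) -> "DrawSet":
        if R < 1:
            raise ValueError("R must be >= 1")
        if scheme == "halton":
            u = van_der_corput(n_resp * R, base=3, skip=10)
            # seeded random shift decorrelates replications while keeping
            # the low-discrepancy structure
            rng = np.random.default_rng(seed)
            u = (u + rng.random()) % 1.0
            z = stats.norm.ppf(np.clip(u, 1e-12, 1 - 1e-12))
            values = z.reshape(n_resp, R)
        elif scheme == "pseudo_random":
            rng = np.random.default_rng(seed)
            values = rng.standard_normal((n_resp, R))
        else:
            raise ValueError(f"unknown draw scheme {scheme!r}")
        return cls(R=R, scheme=scheme, seed=seed, values=values)


class PanelMixedLogitResults(DiscreteChoiceResults):
    model_kind = "RPL"

    @property
    def parameters(self) -> Parameters:
        return self.model.split_theta(self.theta)

    @property
    def spec(self) -> ModelSpec:
        return self.model.spec


class PanelMixedLogit:
    """Mixed logit with a single random (normal) opt-out constant.

    The packed parameter vector is [attribute coefficients, delta_o,
    gamma, s] with sigma_o = |s|; the absolute value keeps the
    optimization unconstrained while the reported deviation is
    nonnegative.
    """

    def __init__(
        self,
        dataset: ChoiceDataset | None,
        spec: ModelSpec,
        draws: DrawSet | None = None,
        design: Design | None = None,
    ):
        if not spec.optout_random:
            raise ValueError("spec.optout_random must be True for PanelMixedLogit")
        self.spec = spec
        self.dataset = dataset
        if design is None:
            design = build_design(dataset, spec)
        self.design = design
        if draws is None:
            draws = DrawSet.generate(design.n_resp, R=500, scheme="halton", seed=0)
        if draws.values.shape[0] != design.n_resp:
            raise ValueError(
                f"draw set has {draws.values.shape[0]} respondent blocks, "
                f"dataset has {design.n_resp}"
            )
        self.draws = draws
        K = design.n_attr
        Kg = design.w_opt.shape[1]
        self.n_params = K + 1 + Kg + 1
        self.names = (
            list(design.attr_names)
            + ["delta_o"]
            + list(design.gamma_names)
            + ["sigma_o"]
        )
        # respondent block boundaries (tasks are grouped by respondent)
        ri = design.resp_index
        if np.any(np.diff(ri) < 0):
            raise ValueError("tasks must be grouped by respondent")
        self._starts = np.searchsorted(ri, np.arange(design.n_resp))

    # -- likelihood ----------------------------------------------------------

    def _split(self, theta):
        K = self.design.n_attr
        Kg = self.design.w_opt.shape[1]
        beta = theta[:K]
        delta_o = theta[K]
        gamma = theta[K + 1 : K + 1 + Kg]
        s = theta[-1]
        return beta, delta_o, gamma, s

    def _panel_logkernel(self, theta, nodes):
        """Per-respondent, per-node joint log-probability S (n_resp, R).

        ``nodes`` (n_resp, R) are standard-normal abscissae; the
        realized constant is delta_o + |s| * node.
        """
        beta, delta_o, gamma, s = self._split(theta)
        d = self.design
        Uv = d.Xv @ beta  # (n_tasks, 2)
        base_o = delta_o + d.w_opt @ gamma  # (n_tasks,)
        delta_tr = base_o[:, None] + abs(s) * nodes[d.resp_index]  # (n_tasks, R)

        m = np.maximum(Uv.max(axis=1)[:, None], delta_tr)
        lse = m + np.log(
            np.exp(Uv[:, 0][:, None] - m)
            + np.exp(Uv[:, 1][:, None] - m)
            + np.exp(delta_tr - m)
        )
        chosen = d.chosen
        u_chosen = np.where(
            (chosen == 2)[:, None],
            delta_tr,
            np.where((chosen == 0)[:, None], Uv[:, 0][:, None], Uv[:, 1][:, None]),
        )
        logP = u_chosen - lse  # (n_tasks, R)
        S = np.add.reduceat(logP, self._starts, axis=0)  # (n_resp, R)
        return S, logP, lse, Uv, delta_tr

    def loglike(self, theta: np.ndarray) -> float:
        S, *_ = self._panel_logkernel(theta, self.draws.values)
        m = S.max(axis=1)
        ll_i = m + np.log(np.exp(S - m[:, None]).mean(axis=1))
        return float(ll_i.sum())

    def loglike_quadrature(self, theta: np.ndarray, n_nodes: int = 20) -> float:
        """Gauss-Hermite evaluation of the same panel integral."""
        x, w = np.polynomial.hermite.hermgauss(n_nodes)
        keep = w > 0  # extreme-node weights underflow for very large n_nodes
        x, w = x[keep], w[keep]
        nodes = np.tile(np.sqrt(2.0) * x, (self.design.n_resp, 1))
        S, *_ = self._panel_logkernel(theta, nodes)
        logw = np.log(w / np.sqrt(np.pi))
        m = (S + logw).max(axis=1)
        ll_i = m + np.log(np.exp(S + logw - m[:, None]).sum(axis=1))
        return float(ll_i.sum())

    def loglike_and_score(self, theta: np.ndarray):
        d = self.design
        nodes = self.draws.values
        S, logP, lse, Uv, delta_tr = self._panel_logkernel(theta, nodes)
        m = S.max(axis=1)
        ll_i = m + np.log(np.exp(S - m[:, None]).mean(axis=1))
        ll = float(ll_i.sum())

        # draw weights w_ir = L_ir / sum_r L_ir, rows sum to 1
        W = np.exp(S - (m + np.log(np.exp(S - m[:, None]).sum(axis=1)))[:, None])
        Wt = W[d.resp_index]  # (n_tasks, R)

        # per-draw choice probabilities
        P_A = np.exp(Uv[:, 0][:, None] - lse)
        P_B = np.exp(Uv[:, 1][:, None] - lse)
        P_o = np.exp(delta_tr - lse)

        # draw-averaged probabilities per task
        Q_A = (Wt * P_A).sum(axis=1)
        Q_B = (Wt * P_B).sum(axis=1)
        Q_o = (Wt * P_o).sum(axis=1)

        chosen = d.chosen
        ind_A = (chosen == 0).astype(float)
        ind_B = (chosen == 1).astype(float)
        ind_o = (chosen == 2).astype(float)

        g_attr = (
            (ind_A - Q_A) @ d.Xv[:, 0, :] + (ind_B - Q_B) @ d.Xv[:, 1, :]
        )
        resid_o = ind_o - Q_o
        g_delta = resid_o.sum()
        g_gamma = resid_o @ d.w_opt

        beta, delta_o, gamma, s = self._split(theta)
        z_tr = nodes[d.resp_index]
        g_s = np.sign(s) * (Wt * z_tr * (ind_o[:, None] - P_o)).sum()
        grad = np.concatenate([g_attr, [g_delta], g_gamma, [g_s]])
        return ll, grad

    def score(self, theta: np.ndarray) -> np.ndarray:
        return self.loglike_and_score(theta)[1]

    # -- estimation ----------------------------------------------------------

    def fit(
        self,
        start: np.ndarray | None = None,
        sigma_start: float = 0.1,
        gtol: float = 1e-5,
        maxiter: int = 500,
        compute_se: bool = True,
    ) -> PanelMixedLogitResults:
        """Maximize the simulated likelihood (BFGS, analytic gradient).

        By default the search is warm-started from the conditional-logit
        estimates with sigma_o = ``sigma_start``.
        """
        if start is None:
            cl_spec = ModelSpec(**{**self.spec.to_dict(), "optout_random": False})
            cl = ConditionalLogit(None, cl_spec, design=self.design)
            cl_res = cl.fit(compute_se=False)
            start = np.concatenate([cl_res.theta, [sigma_start]])
        start = np.asarray(start, float)

        def negobj(theta):
            ll, g = self.loglike_and_score(theta)
            return -ll, -g

        opt = optimize.minimize(
            negobj,
            start,
            jac=True,
            method="BFGS",
            options={"gtol": gtol, "maxiter": maxiter},
        )
        theta = opt.x.copy()
        theta[-1] = abs(theta[-1])  # report sigma_o >= 0
        # BFGS can stop on a line-search precision warning with the
        # gradient already negligible; treat that as converged
        converged = bool(opt.success) or np.abs(opt.jac).max() < 10 * gtol
        cov = None
        if compute_se:
            H = numerical_hessian(self.score, theta)
            cov = covariance_from_hessian(H)
        for name, val in zip(self.names, theta):
            if abs(val) > SEPARATION_BOUND:
                warnings.warn(
                    f"possible separation: coefficient '{name}' diverging",
                    RuntimeWarning,
                    stacklevel=2,
                )
        return PanelMixedLogitResults(
            model=self,
            theta=theta,
            names=self.names,
            cov=cov,
            loglik=-opt.fun,
            n_choices=self.design.n_tasks,
            n_respondents=self.design.n_resp,
            converged=converged,
            iterations=int(opt.nit),
            draws_used=self.draws.R,
            seed=self.draws.seed,
        )

    def split_theta(self, theta: np.ndarray) -> Parameters:
        beta_all, delta_o, gamma, s = self._split(theta)
        nb = self.spec.n_beta
        return Parameters(
            beta=beta_all[:nb],
            pi=beta_all[nb:],
            delta_o=float(delta_o),
            gamma=gamma,
            sigma_o=abs(float(s)),
        )

    def pack_parameters(self, params: Parameters) -> np.ndarray:
        params.validate(self.spec)
        return np.concatenate(
            [params.utility, [params.delta_o], params.gamma, [params.sigma_o]]
        )


def fit_rpl(
    dataset: ChoiceDataset,
    spec: ModelSpec,
    draws: DrawSet | None = None,
    **options,
) -> PanelMixedLogitResults:
    """Convenience wrapper around :class:`PanelMixedLogit`."""
    return PanelMixedLogit(dataset, spec, draws=draws).fit(**options)
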