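"""Latent-class conditional logit, estimated by EM.

Preferences take one of Q class-specific values theta_q = (beta_q,
Pi_q, delta_o_q); the opt-out alternative carries only the class
constant.  Class membership follows a multinomial logit in respondent
covariates with class 1 as the reference (its coefficients fixed at 0),

    pi_iq = exp(g_q + w_i' g_q) / sum_q exp(...).

The EM iteration alternates posterior responsibilities (E-step) with
weighted conditional-logit fits per class and a weighted multinomial
logit for membership (M-step); the observed-data log-likelihood is
nondecreasing along the iteration and any material decrease aborts the
run as a defect.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

from ..data import ChoiceDataset
from ..spec import ModelSpec, Parameters
from .base import (
    Design,
    build_design,
    covariance_from_hessian,
    log_softmax_rows,
    numerical_hessian,
    significance_stars,
)
from .clogit import ConditionalLogit

EM_ASCENT_SLACK = 1e-8  # tolerated relative decrease before declaring a defect


class EMDescentError(RuntimeError):
    """Observed-data log-likelihood decreased materially during EM."""


def _membership_logprior(Wm: np.ndarray, Gamma: np.ndarray) -> np.ndarray:
    """log pi_iq for all respondents; class 1 is the reference."""
    n = Wm.shape[0]
    logits = np.zeros((n, Gamma.shape[0] + 1))
    logits[:, 1:] = Wm @ Gamma.T
    return log_softmax_rows(logits)


def _fit_membership(
    Wm: np.ndarray, R: np.ndarray, Gamma0: np.ndarray, maxiter: int = 50
) -> np.ndarray:
    """Weighted multinomial logit M-step (fractional responses R).

    Maximizes sum_i sum_q r_iq log pi_iq by Newton's method; the problem
    is concave.
    """
    n, p = Wm.shape
    Q = R.shape[1]
    Gamma = Gamma0.copy()  # (Q-1, p)
    if Q == 1:
        return Gamma

    def unpack(v):
        return v.reshape(Q - 1, p)

    v = Gamma.ravel().copy()
    for _ in range(maxiter):
        logpi = _membership_logprior(Wm, unpack(v))
        Pi = np.exp(logpi)
        resid = R[:, 1:] - Pi[:, 1:]  # (n, Q-1)
        g = (resid.T @ Wm).ravel()
        if np.abs(g).max() < 1e-9:
            break
        # Hessian blocks: -sum_i [diag(pi)-pi pi'] (x) w w'
        H = np.zeros(((Q - 1) * p, (Q - 1) * p))
        for a in range(1, Q):
            for b in range(1, Q):
                wgt = Pi[:, a] * ((a == b) - Pi[:, b])
                block = -(Wm * wgt[:, None]).T @ Wm
                H[(a - 1) * p : a * p, (b - 1) * p : b * p] = block
        try:
            step = -np.linalg.solve(H - 1e-10 * np.eye(H.shape[0]), g)
        except np.linalg.LinAlgError:
            step = g
        # step halving on the weighted objective
        obj = (R * logpi).sum()
        t = 1.0
        for _ in range(30):
            cand = v + t * step
            obj_new = (R * _membership_logprior(Wm, unpack(cand))).sum()
            if obj_new >= obj - 1e-12:
                break
            t /= 2.0
        v = v + t * step
    return unpack(v)


class LatentClassResults:
    """Estimates of the latent-class conditional logit.

    ``class_thetas`` has one row per class: attribute coefficients then
    the class opt-out constant.  ``membership`` holds the
    class-membership coefficients for classes 2..Q (class 1 reference),
    columns [const, class covariates].
    """

    model_kind = "LCL"

    def __init__(
        self,
        model,
        class_thetas: np.ndarray,
        membership: np.ndarray,
        loglik: float,
        loglik_path: list[float],
        responsibilities: np.ndarray,
        converged: bool,
        iterations: int,
        n_starts: int,
        seed: int | None,
        cov: np.ndarray | None = None,
    ):
        self.model = model
        self.class_thetas = class_thetas
        self.membership = membership
        self.loglik = float(loglik)
        self.loglik_path = list(loglik_path)
        self.responsibilities = responsibilities
        self.converged = bool(converged)
        self.iterations = int(iterations)
        self.n_starts = n_starts
        self.seed = seed
        self.cov = cov

    # -- shapes ---------------------------------------------------------------

    @property
    def Q(self) -> int:
        return self.class_thetas.shape[0]

    @property
    def spec(self) -> ModelSpec:
        return self.model.spec

    @property
    def n_choices(self) -> int:
        return self.model.design.n_tasks

    @property
    def k(self) -> int:
        return self.class_thetas.size + self.membership.size

    @property
    def bic(self) -> float:
        return -2.0 * self.loglik + self.k * np.log(self.n_choices)

    @property
    def theta(self) -> np.ndarray:
        """Packed parameter vector: class blocks then membership rows."""
        return np.concatenate([self.class_thetas.ravel(), self.membership.ravel()])

    @property
    def names(self) -> list[str]:
        out = []
        per_class = list(self.model.class_param_names)
        for q in range(self.Q):
            out += [f"class{q + 1}:{n}" for n in per_class]
        for q in range(2, self.Q + 1):
            out += [f"member{q}:{n}" for n in self.model.design.class_names]
        return out

    @property
    def bse(self) -> np.ndarray:
        if self.cov is None:
            return np.full(self.k, np.nan)
        return np.sqrt(np.clip(np.diag(self.cov), 0, None))

    @property
    def pvalues(self) -> np.ndarray:
        with np.errstate(divide="ignore", invalid="ignore"):
            z = self.theta / self.bse
        return 2 * stats.norm.sf(np.abs(z))

    # -- posterior machinery ----------------------------------------------------

    def class_parameters(self, q: int) -> Parameters:
        """Parameters object of class q (1-based)."""
        theta_q = self.class_thetas[q - 1]
        nb = self.model.spec.n_beta
        K = self.model.design.n_attr
        return Parameters(
            beta=theta_q[:nb],
            pi=theta_q[nb:K],
            delta_o=float(theta_q[K]),
            gamma=np.zeros(0),
            sigma_o=0.0,
        )

    def class_results(self, q: int):
        """Per-class parameter view (1-based q) usable by post-estimation."""
        from ..published import FixedParameters

        P = self.model.design.n_attr + 1
        sl = slice((q - 1) * P, q * P)
        cov = None if self.cov is None else self.cov[sl, sl]
        return FixedParameters(
            spec=self.model._class_spec,
            params=self.class_parameters(q),
            cov=cov,
        )

    def prior_probabilities(self) -> np.ndarray:
        """Multinomial-logit class priors pi_iq, (n_resp, Q)."""
        Wm = self.model.Wm
        return np.exp(_membership_logprior(Wm, self.membership))

    def expected_shares(self) -> np.ndarray:
        """Mean posterior probability per class."""
        return self.responsibilities.mean(axis=0)

    def summary(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {"estimate": self.theta, "se": self.bse, "p": self.pvalues},
            index=self.names,
        )
        df["sig"] = [
            significance_stars(p) if np.isfinite(p) else "" for p in df["p"]
        ]
        return df

    def __str__(self) -> str:
        head = (
            f"LCL results | Q {self.Q} | loglik {self.loglik:.2f} | "
            f"BIC {self.bic:.2f} | k {self.k} | converged {self.converged} | "
            f"shares {np.round(self.expected_shares(), 4)}"
        )
        return head + "\n" + self.summary().to_string(float_format="%.4f")


class LatentClassLogit:
    """Latent-class conditional logit model (EM estimation)."""

    def __init__(self, dataset: ChoiceDataset | None, spec: ModelSpec,
                 design: Design | None = None):
        if spec.n_classes < 1:
            raise ValueError("n_classes must be >= 1")
        self.spec = spec
        # within-class models carry only the opt-out constant
        self._class_spec = ModelSpec(
            **{
                **spec.to_dict(),
                "optout_covariates": [],
                "optout_random": False,
                "n_classes": 1,
            }
        )
        if design is None:
            design = build_design(dataset, spec)
        self.design = design
        # class-model design shares Xv/chosen but drops the opt-out covariates
        self._class_design = Design(
            Xv=design.Xv,
            w_opt=np.zeros((design.n_tasks, 0)),
            chosen=design.chosen,
            resp_index=design.resp_index,
            resp_ids=design.resp_ids,
            w_class=design.w_class,
            attr_names=design.attr_names,
            gamma_names=(),
            class_names=design.class_names,
        )
        self.Wm = np.column_stack([np.ones(design.n_resp), design.w_class])
        self.class_param_names = list(design.attr_names) + ["delta_o"]
        ri = design.resp_index
        self._starts = np.searchsorted(ri, np.arange(design.n_resp))
        self._cl = ConditionalLogit(None, self._class_spec, design=self._class_design)

    @property
    def Q(self) -> int:
        return self.spec.n_classes

    # -- E-step quantities ------------------------------------------------------

    def _class_logliks(self, class_thetas: np.ndarray) -> np.ndarray:
        """log L_iq: per-respondent sequence log-likelihood per class."""
        out = np.empty((self.design.n_resp, self.Q))
        for q in range(self.Q):
            per_task = self._cl.loglike_per_task(class_thetas[q])
            out[:, q] = np.add.reduceat(per_task, self._starts)
        return out

    def observed_loglik(
        self, class_thetas: np.ndarray, membership: np.ndarray
    ) -> float:
        logL = self._class_logliks(class_thetas) + _membership_logprior(
            self.Wm, membership
        )
        m = logL.max(axis=1)
        return float((m + np.log(np.exp(logL - m[:, None]).sum(axis=1))).sum())

    def _estep(self, class_thetas, membership):
        logL = self._class_logliks(class_thetas) + _membership_logprior(
            self.Wm, membership
        )
        m = logL.max(axis=1)
        ll_i = m + np.log(np.exp(logL - m[:, None]).sum(axis=1))
        R = np.exp(logL - ll_i[:, None])
        return R, float(ll_i.sum())

    # -- EM ----------------------------------------------------------------------

    def _single_run(self, R0: np.ndarray, tol: float, maxiter: int):
        d = self.design
        Q = self.Q
        P = d.n_attr + 1
        class_thetas = np.zeros((Q, P))
        membership = np.zeros((Q - 1, self.Wm.shape[1]))
        R = R0
        ll_prev = -np.inf
        path: list[float] = []
        converged = False
        it = 0
        for it in range(1, maxiter + 1):
            # M-step
            for q in range(Q):
                self._cl.task_weights = R[d.resp_index, q]
                res = self._cl.fit(
                    start=class_thetas[q], compute_se=False, gtol=1e-7,
                    maxiter=50, warn_separation=False,
                )
                class_thetas[q] = res.theta
            membership = _fit_membership(self.Wm, R, membership)
            # E-step
            R, ll = self._estep(class_thetas, membership)
            path.append(ll)
            if ll < ll_prev - EM_ASCENT_SLACK * max(1.0, abs(ll_prev)):
                raise EMDescentError(
                    f"EM log-likelihood decreased: {ll_prev} -> {ll}"
                )
            if np.isfinite(ll_prev) and abs(ll - ll_prev) <= tol * abs(ll_prev):
                converged = True
                ll_prev = ll
                break
            ll_prev = ll
        # empty-class diagnostics
        shares = R.mean(axis=0)
        for q, s in enumerate(shares, start=1):
            if s < 0.005:
                warnings.warn(
                    f"expected share of class {q} below 0.5% ({s:.4f}); "
                    "Q may exceed what the data support",
                    RuntimeWarning,
                    stacklevel=3,
                )
        return class_thetas, membership, R, ll_prev, path, converged, it

    def fit(
        self,
        n_starts: int = 10,
        seed: int = 0,
        tol: float = 1e-8,
        maxiter: int = 2000,
        compute_se: bool = True,
    ) -> LatentClassResults:
        """Run EM from ``n_starts`` seeded random initializations.

        Initial responsibilities are Dirichlet(1) draws per respondent;
        the run with the highest observed-data log-likelihood is kept
        (ties broken by the earlier start).
        """
        if n_starts < 1:
            raise ValueError("n_starts must be >= 1")
        rng = np.random.default_rng(seed)
        best = None
        d = self.design
        for start_idx in range(n_starts):
            if self.Q == 1:
                R0 = np.ones((d.n_resp, 1))
            else:
                R0 = rng.dirichlet(np.ones(self.Q), size=d.n_resp)
            try:
                run = self._single_run(R0, tol=tol, maxiter=maxiter)
            except EMDescentError:
                warnings.warn(
                    f"EM start {start_idx} aborted on a likelihood decrease",
                    RuntimeWarning,
                    stacklevel=2,
                )
                continue
            if best is None or run[3] > best[3] + 1e-10:
                best = run
            if self.Q == 1:
                break
        if best is None:
            raise RuntimeError("all EM starts failed")
        class_thetas, membership, R, ll, path, converged, it = best
        cov = None
        if compute_se:
            cov = self._covariance(class_thetas, membership)
        return LatentClassResults(
            model=self,
            class_thetas=class_thetas,
            membership=membership,
            loglik=ll,
            loglik_path=path,
            responsibilities=R,
            converged=converged,
            iterations=it,
            n_starts=n_starts,
            seed=seed,
            cov=cov,
        )

    # -- standard errors -----------------------------------------------------------

    def _pack(self, class_thetas, membership):
        return np.concatenate([class_thetas.ravel(), membership.ravel()])

    def _unpack(self, v):
        Q, P = self.Q, self.design.n_attr + 1
        nc = Q * P
        class_thetas = v[:nc].reshape(Q, P)
        membership = v[nc:].reshape(Q - 1, self.Wm.shape[1])
        return class_thetas, membership

    def _observed_score(self, v: np.ndarray) -> np.ndarray:
        """Gradient of the observed-data loglik (Fisher's identity)."""
        class_thetas, membership = self._unpack(v)
        R, _ = self._estep(class_thetas, membership)
        d = self.design
        grads = []
        for q in range(self.Q):
            self._cl.task_weights = R[d.resp_index, q]
            grads.append(self._cl.score(class_thetas[q]))
        Pi = np.exp(_membership_logprior(self.Wm, membership))
        resid = R[:, 1:] - Pi[:, 1:]
        grads.append((resid.T @ self.Wm).ravel())
        return np.concatenate(grads)

    def _covariance(self, class_thetas, membership):
        v = self._pack(class_thetas, membership)
        H = numerical_hessian(self._observed_score, v, eps=1e-5)
        return covariance_from_hessian(H)


def em_fit_lcl(
    dataset: ChoiceDataset, spec: ModelSpec, Q: int | None = None, **options
) -> LatentClassResults:
    """Convenience wrapper; ``Q`` overrides ``spec.n_classes`` if given."""
    if Q is not None and Q != spec.n_classes:
        spec = ModelSpec(**{**spec.to_dict(), "n_classes": Q})
    return LatentClassLogit(dataset, spec).fit(**options)
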