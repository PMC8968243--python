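"""Conditional logit with an opt-out index function.

Each choice task is treated as an independent pseudo-individual; the
log-likelihood is globally concave in the stacked parameter vector
[attribute coefficients, opt-out constant, opt-out covariates], so the
maximizer is found by Newton's method with step halving.
"""

from __future__ import annotations

import warnings

import numpy as np

from ..data import ChoiceDataset
from ..spec import ModelSpec, Parameters
from .base import (
    Design,
    DiscreteChoiceResults,
    build_design,
    build_z_tensor,
    covariance_from_hessian,
    log_softmax_rows,
)

#: |estimate| beyond which a coefficient is flagged as likely separated
SEPARATION_BOUND = 12.0


class ConditionalLogitResults(DiscreteChoiceResults):
    model_kind = "CL"

    @property
    def parameters(self) -> Parameters:
        return self.model.split_theta(self.theta)

    @property
    def spec(self) -> ModelSpec:
        return self.model.spec


class ConditionalLogit:
    """Conditional logit model of choices among {A, B, opt-out}.

    Parameters
    ----------
    dataset
        Validated long-format panel.
    spec
        Model specification; ``optout_random`` must be False.
    task_weights
        Optional nonnegative per-task weights (used by the latent-class
        EM M-step).
    """

    def __init__(
        self,
        dataset: ChoiceDataset | None,
        spec: ModelSpec,
        task_weights: np.ndarray | None = None,
        design: Design | None = None,
    ):
        if spec.optout_random:
            raise ValueError(
                "spec requests a random opt-out constant; use PanelMixedLogit"
            )
        self.spec = spec
        self.dataset = dataset
        if design is None:
            if dataset is None:
                raise ValueError("either dataset or design must be given")
            design = build_design(dataset, spec)
        self.design = design
        if design.n_tasks == 0:
            raise ValueError("empty dataset")
        self.Z = build_z_tensor(design)
        self.names = (
            list(design.attr_names) + ["delta_o"] + list(design.gamma_names)
        )
        self.n_params = self.Z.shape[2]
        if task_weights is None:
            task_weights = np.ones(design.n_tasks)
        self.task_weights = np.asarray(task_weights, float)
        self._rows = np.arange(design.n_tasks)

    # -- likelihood ----------------------------------------------------------

    def _logprobs(self, theta: np.ndarray) -> np.ndarray:
        U = self.Z @ theta  # (n_tasks, 3)
        return log_softmax_rows(U)

    def loglike(self, theta: np.ndarray) -> float:
        logP = self._logprobs(theta)
        return float(
            (self.task_weights * logP[self._rows, self.design.chosen]).sum()
        )

    def loglike_per_task(self, theta: np.ndarray) -> np.ndarray:
        """Unweighted log-probability of the chosen alternative per task."""
        logP = self._logprobs(theta)
        return logP[self._rows, self.design.chosen]

    def score(self, theta: np.ndarray) -> np.ndarray:
        logP = self._logprobs(theta)
        P = np.exp(logP)
        resid = -P
        resid[self._rows, self.design.chosen] += 1.0
        return np.einsum("t,tj,tjp->p", self.task_weights, resid, self.Z)

    def hessian(self, theta: np.ndarray) -> np.ndarray:
        P = np.exp(self._logprobs(theta))
        M = np.einsum("tj,tjp->tp", P, self.Z)
        H = np.einsum("t,tp,tq->pq", self.task_weights, M, M)
        H -= np.einsum("t,tj,tjp,tjq->pq", self.task_weights, P, self.Z, self.Z)
        return H

    # -- estimation ----------------------------------------------------------

    def fit(
        self,
        start: np.ndarray | None = None,
        gtol: float = 1e-6,
        maxiter: int = 500,
        compute_se: bool = True,
        ridge: float = 1e-10,
        warn_separation: bool = True,
    ) -> ConditionalLogitResults:
        """Newton maximization from a zero start (unless given)."""
        theta = np.zeros(self.n_params) if start is None else np.array(start, float)
        ll = self.loglike(theta)
        converged = False
        it = 0
        for it in range(1, maxiter + 1):
            g = self.score(theta)
            if np.max(np.abs(g)) < gtol:
                converged = True
                break
            H = self.hessian(theta)
            try:
                d = np.linalg.solve(H - ridge * np.eye(self.n_params), g)
                step = -d
            except np.linalg.LinAlgError:
                step = g / max(1.0, np.abs(g).max())
            t = 1.0
            for _ in range(40):
                cand = theta + t * step
                ll_new = self.loglike(cand)
                if ll_new >= ll - 1e-12:
                    break
                t /= 2.0
            theta, ll = theta + t * step, ll_new
        cov = None
        if compute_se:
            cov = covariance_from_hessian(self.hessian(theta))
        if warn_separation:
            self._warn_separation(theta)
        return ConditionalLogitResults(
            model=self,
            theta=theta,
            names=self.names,
            cov=cov,
            loglik=ll,
            n_choices=self.design.n_tasks,
            n_respondents=self.design.n_resp,
            converged=converged,
            iterations=it,
        )

    def _warn_separation(self, theta: np.ndarray) -> None:
        big = np.abs(theta) > SEPARATION_BOUND
        for name, flag in zip(self.names, big):
            if flag:
                warnings.warn(
                    f"possible separation: coefficient '{name}' diverging "
                    f"(|estimate| > {SEPARATION_BOUND})",
                    RuntimeWarning,
                    stacklevel=3,
                )

    # -- parameter bookkeeping ------------------------------------------------

    def split_theta(self, theta: np.ndarray) -> Parameters:
        K = len(self.design.attr_names)
        nb = self.spec.n_beta
        return Parameters(
            beta=theta[:nb],
            pi=theta[nb:K],
            delta_o=float(theta[K]),
            gamma=theta[K + 1 :],
            sigma_o=0.0,
        )

    def pack_parameters(self, params: Parameters) -> np.ndarray:
        params.validate(self.spec)
        return np.concatenate([params.utility, [params.delta_o], params.gamma])


def fit_conditional_logit(
    dataset: ChoiceDataset, spec: ModelSpec, **options
) -> ConditionalLogitResults:
    """Convenience wrapper: build the model and fit from a zero start."""
    return ConditionalLogit(dataset, spec).fit(**options)
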