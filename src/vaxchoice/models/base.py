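"""Shared machinery for the choice models: vectorized design arrays,
overflow-safe logit kernels, and the common Results surface.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from ..data import ChoiceDataset
from ..spec import ModelSpec, Parameters
from ..types import HIGH_INCOME_THRESHOLD, ORIGIN_LEVELS, RECOMMENDER_LEVELS


@dataclass
class Design:
    """Dense design arrays for one dataset under one model spec.

    ``Xv``: (n_tasks, 2, K) encoded attribute rows for alternatives A and
    B.  ``w_opt``: (n_tasks, Kg) opt-out covariates (without constant).
    ``chosen``: 0=A, 1=B, 2=opt-out.  ``resp_index`` maps tasks to the
    respondent block (0..n_resp-1).  ``w_class``: (n_resp, Kc)
    class-membership covariates (without constant).
    """

    Xv: np.ndarray
    w_opt: np.ndarray
    chosen: np.ndarray
    resp_index: np.ndarray
    resp_ids: np.ndarray
    w_class: np.ndarray
    attr_names: tuple[str, ...]
    gamma_names: tuple[str, ...]
    class_names: tuple[str, ...]

    @property
    def n_tasks(self) -> int:
        return self.Xv.shape[0]

    @property
    def n_resp(self) -> int:
        return len(self.resp_ids)

    @property
    def n_attr(self) -> int:
        return self.Xv.shape[2]


def _covariate_series(df: pd.DataFrame, name: str) -> np.ndarray:
    if name == "household_income_10k":
        return df["household_income"].to_numpy(float) / 10_000.0
    if name == "high_income":
        return (df["household_income"].to_numpy(float) >= HIGH_INCOME_THRESHOLD).astype(
            float
        )
    if name not in df.columns:
        raise KeyError(f"covariate {name!r} not present in the data")
    return df[name].to_numpy(float)


def build_design(dataset: ChoiceDataset, spec: ModelSpec) -> Design:
    """Encode the whole panel at once (mirrors the scalar encoders)."""
    df = dataset.df
    vac = df[df["alt"] != "optout"]
    n_tasks = dataset.n_tasks
    if len(vac) != 2 * n_tasks:
        raise ValueError("malformed dataset: expected 2 vaccine rows per task")

    base_cols = {
        "cost": vac["cost"].to_numpy(float),
        "effectiveness": vac["effectiveness"].to_numpy(float),
        "protection": vac["protection"].to_numpy(float),
        "incubation": vac["incubation"].to_numpy(float),
        "severe": vac["severe"].to_numpy(float),
        "mild": vac["mild"].to_numpy(float),
        "introduced": vac["introduced"].to_numpy(float),
    }
    origin = vac["origin"].astype(str).to_numpy()
    rec = vac["recommender"].astype(str).to_numpy()
    for level in ORIGIN_LEVELS[1:]:
        base_cols[f"origin_{level.lower()}"] = (origin == level).astype(float)
    for level in RECOMMENDER_LEVELS[1:]:
        base_cols[f"rec_{level.lower()}"] = (rec == level).astype(float)
    if spec.cost_mode == "linear_plus_free":
        base_cols["free"] = (base_cols["cost"] == 0).astype(float)

    columns = [base_cols[c] for c in spec.base_columns()]
    for attr, cov in spec.interactions:
        columns.append(base_cols[attr] * _covariate_series(vac, cov))
    X = np.column_stack(columns)  # (2*n_tasks, K)
    Xv = X.reshape(n_tasks, 2, -1)

    # per-task opt-out covariates: taken from the A rows (covariates are
    # constant within a respondent, hence within a task)
    a_rows = vac.iloc[0::2]
    w_opt = (
        np.column_stack([_covariate_series(a_rows, c) for c in spec.optout_covariates])
        if spec.optout_covariates
        else np.zeros((n_tasks, 0))
    )

    chosen_alt = df.loc[df["chosen"] == 1, "alt"].to_numpy()
    chosen = np.array([{"A": 0, "B": 1, "optout": 2}[a] for a in chosen_alt])

    task_resp = a_rows["resp_id"].to_numpy()
    # respondent blocks in first-appearance order
    order = pd.unique(task_resp)
    remap = {rid: i for i, rid in enumerate(order)}
    resp_index = np.array([remap[r] for r in task_resp])
    resp_ids = np.asarray(order)

    first_rows = a_rows.drop_duplicates("resp_id", keep="first")
    w_class = (
        np.column_stack([_covariate_series(first_rows, c) for c in spec.class_covariates])
        if spec.class_covariates
        else np.zeros((len(first_rows), 0))
    )

    return Design(
        Xv=Xv,
        w_opt=w_opt,
        chosen=chosen,
        resp_index=resp_index,
        resp_ids=resp_ids,
        w_class=w_class,
        attr_names=spec.attribute_columns(),
        gamma_names=tuple(f"optout:{c}" for c in spec.optout_covariates),
        class_names=("const",) + spec.class_covariates,
    )


def build_z_tensor(design: Design) -> np.ndarray:
    """Stack the full per-alternative regressor rows z_jt.

    Layout of the parameter vector: [attribute coefficients (K),
    delta_o, gamma (Kg)].  Vaccine rows carry x in the first K slots;
    the opt-out row carries 1 in the delta slot and w in the gamma slots.
    """
    n_tasks, _, K = design.Xv.shape
    Kg = design.w_opt.shape[1]
    P = K + 1 + Kg
    Z = np.zeros((n_tasks, 3, P))
    Z[:, :2, :K] = design.Xv
    Z[:, 2, K] = 1.0
    Z[:, 2, K + 1 :] = design.w_opt
    return Z


def log_softmax_rows(U: np.ndarray) -> np.ndarray:
    """Row-wise log softmax over the last axis, overflow-safe."""
    m = U.max(axis=-1, keepdims=True)
    s = np.log(np.exp(U - m).sum(axis=-1, keepdims=True))
    return U - m - s


STAR_CODES = ((0.001, "***"), (0.01, "**"), (0.05, "*"), (0.1, "."))


def significance_stars(p: float) -> str:
    for cut, code in STAR_CODES:
        if p < cut:
            return code
    return ""


class DiscreteChoiceResults:
    """Common estimation-results surface.

    Carries the packed parameter vector, names, covariance at the
    optimum, fit statistics, and formatting/serialization helpers.
    """

    model_kind = "CL"

    def __init__(
        self,
        model,
        theta: np.ndarray,
        names: Sequence[str],
        cov: np.ndarray | None,
        loglik: float,
        n_choices: int,
        n_respondents: int,
        converged: bool,
        iterations: int,
        draws_used: int = 0,
        seed: int | None = None,
    ):
        self.model = model
        self.theta = np.asarray(theta, float)
        self.names = list(names)
        self.cov = cov
        self.loglik = float(loglik)
        self.n_choices = int(n_choices)
        self.n_respondents = int(n_respondents)
        self.converged = bool(converged)
        self.iterations = int(iterations)
        self.draws_used = int(draws_used)
        self.seed = seed

    @property
    def k(self) -> int:
        return self.theta.size

    @property
    def bic(self) -> float:
        return -2.0 * self.loglik + self.k * np.log(self.n_choices)

    @property
    def bse(self) -> np.ndarray:
        if self.cov is None:
            return np.full(self.k, np.nan)
        return np.sqrt(np.clip(np.diag(self.cov), 0, None))

    @property
    def zvalues(self) -> np.ndarray:
        with np.errstate(divide="ignore", invalid="ignore"):
            return self.theta / self.bse

    @property
    def pvalues(self) -> np.ndarray:
        return 2 * stats.norm.sf(np.abs(self.zvalues))

    def summary(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "estimate": self.theta,
                "se": self.bse,
                "z": self.zvalues,
                "p": self.pvalues,
            },
            index=self.names,
        )
        df["sig"] = [significance_stars(p) if np.isfinite(p) else "" for p in df["p"]]
        return df

    def __str__(self) -> str:
        head = (
            f"{self.model_kind} results | loglik {self.loglik:.2f} | "
            f"BIC {self.bic:.2f} | k {self.k} | n_choices {self.n_choices} | "
            f"converged {self.converged}"
        )
        return head + "\n" + self.summary().to_string(float_format="%.4f")

    def to_json(self, path=None) -> str:
        payload = {
            "model_kind": self.model_kind,
            "loglik": self.loglik,
            "bic": self.bic,
            "k": self.k,
            "n_choices": self.n_choices,
            "n_respondents": self.n_respondents,
            "converged": self.converged,
            "iterations": self.iterations,
            "draws_used": self.draws_used,
            "seed": self.seed,
            "parameters": [
                {
                    "name": n,
                    "estimate": float(e),
                    "se": None if not np.isfinite(s) else float(s),
                    "z": None if not np.isfinite(z) else float(z),
                    "p": None if not np.isfinite(p) else float(p),
                    "sig": significance_stars(p) if np.isfinite(p) else "",
                }
                for n, e, s, z, p in zip(
                    self.names, self.theta, self.bse, self.zvalues, self.pvalues
                )
            ],
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text


def numerical_hessian(grad_fn, theta: np.ndarray, eps: float = 1e-5) -> np.ndarray:
    """Symmetrized finite-difference Jacobian of an analytic gradient."""
    P = theta.size
    H = np.zeros((P, P))
    for j in range(P):
        h = eps * max(1.0, abs(theta[j]))
        tp = theta.copy()
        tp[j] += h
        tm = theta.copy()
        tm[j] -= h
        H[:, j] = (grad_fn(tp) - grad_fn(tm)) / (2 * h)
    return 0.5 * (H + H.T)


def covariance_from_hessian(H: np.ndarray) -> np.ndarray | None:
    """Covariance = inverse of the negative Hessian of the loglik."""
    try:
        cov = np.linalg.inv(-H)
    except np.linalg.LinAlgError:
        return None
    return 0.5 * (cov + cov.T)
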