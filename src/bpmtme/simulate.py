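"""Model-based simulator for multi-trait multi-environment count phenotypes.

Counts are generated from the Poisson-lognormal hierarchy: per trait l,
replicate k, environment i and genotype j,

    Y_ijk(l) ~ Poisson(exp(beta_i(l) + b_j(l) + b_ij(l) + c_ijk(l)))

with b1 ~ N(0, G (x) Sigma_t), b2 ~ N(0, Sigma_E (x) G (x) Sigma_t) and
the replicate-level overdispersion effects c_ijk ~ iid N(0, Sigma_c).
The two benchmark scenarios S1 (high trait/environment correlation, ~0.8)
and S2 (low, ~0.3) are available by name: 3 environments, 2 traits, 200
genotypes, 5 replications, identity relationship among genotypes.

The simulator draws c per replicate even though fitting collapses
replicates to sums: data are generated at replicate level and summed for
analysis, exactly the pipeline the model is meant for.  The intercepts
``beta`` are on the per-replicate Poisson log scale.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data import CountDataset

__all__ = ["SimulationParams", "scenario_params", "simulate_dataset", "cov_to_corr"]


def cov_to_corr(matrix) -> np.ndarray:
    """Convert a positive-definite covariance matrix to a correlation matrix."""
    S = np.asarray(matrix, dtype=float)
    d = np.sqrt(np.diag(S))
    if np.any(d <= 0):
        raise ValueError("covariance matrix must have positive diagonal")
    R = S / np.outer(d, d)
    np.fill_diagonal(R, 1.0)
    return R


@dataclass
class SimulationParams:
    """Dimensions, intercepts and generating covariances for the simulator."""

    n_env: int
    n_lines: int
    n_reps: int
    n_traits: int
    beta: np.ndarray        # length I*L, (environment outer, trait inner)
    Sigma_t: np.ndarray     # L x L
    Sigma_E: np.ndarray     # I x I
    Sigma_c: np.ndarray     # L x L
    G: np.ndarray | None = None  # J x J, identity when None
    seed: int | None = None

    def __post_init__(self) -> None:
        self.beta = np.asarray(self.beta, dtype=float).ravel()
        if self.beta.size != self.n_env * self.n_traits:
            raise ValueError("beta must have length n_env * n_traits")
        if not np.all(np.isfinite(self.beta)):
            raise ValueError("beta must be finite")
        for name, M, dim in (
            ("Sigma_t", self.Sigma_t, self.n_traits),
            ("Sigma_E", self.Sigma_E, self.n_env),
            ("Sigma_c", self.Sigma_c, self.n_traits),
        ):
            M = np.asarray(M, dtype=float)
            if M.shape != (dim, dim) or np.max(np.abs(M - M.T)) > 1e-12:
                raise ValueError(f"{name} must be a symmetric {dim}x{dim} matrix")
            try:
                np.linalg.cholesky(M)
            except np.linalg.LinAlgError as exc:
                raise ValueError(f"{name} must be positive definite") from exc
            setattr(self, name, M)
        if self.G is None:
            self.G = np.eye(self.n_lines)
        else:
            self.G = np.asarray(self.G, dtype=float)
            if self.G.shape != (self.n_lines, self.n_lines):
                raise ValueError("G must be n_lines x n_lines")


_S1 = dict(
    Sigma_t=[[0.005, 0.0031], [0.0031, 0.003]],
    Sigma_E=[
        [0.003, 0.0022, 0.0024],
        [0.0022, 0.0022, 0.0012],
        [0.0024, 0.0012, 0.0030],
    ],
    Sigma_c=[[0.0003, 0.0003], [0.0003, 0.0004]],
)
_S2 = dict(
    Sigma_t=[[0.005, 0.0012], [0.0012, 0.003]],
    Sigma_E=[
        [0.003, 0.0007, 0.0009],
        [0.0007, 0.0022, 0.0007],
        [0.0009, 0.0007, 0.0030],
    ],
    Sigma_c=[[0.0003, 0.0001], [0.0001, 0.0004]],
)
_SCENARIO_BETA = [0.20, 0.25, 0.15, 0.20, 0.30, 0.32]


def scenario_params(name: str, seed: int | None = None) -> SimulationParams:
    """Benchmark scenario constants: "S1" (corr ~0.8) or "S2" (corr ~0.3)."""
    try:
        mats = {"S1": _S1, "S2": _S2}[name]
    except KeyError:
        raise ValueError(f"unknown scenario {name!r}; expected 'S1' or 'S2'") from None
    return SimulationParams(
        n_env=3,
        n_lines=200,
        n_reps=5,
        n_traits=2,
        beta=np.array(_SCENARIO_BETA),
        G=np.eye(200),
        seed=seed,
        **{k: np.array(v) for k, v in mats.items()},
    )


def _matrix_normal(rng, row_chol: np.ndarray, col_chol: np.ndarray) -> np.ndarray:
    """Draw M (rows x cols) with cov(vec_row-major(M)) = (R R') (x) (C C')."""
    Z = rng.standard_normal((row_chol.shape[0], col_chol.shape[0]))
    return row_chol @ Z @ col_chol.T


def simulate_dataset(params: SimulationParams, rng=None, return_truth: bool = False):
    """Simulate a long-format CountDataset from the generative model.

    With ``return_truth=True`` also returns a dict with the drawn random
    effects and per-cell Poisson means (replicate effects averaged out),
    useful for parameter- and prediction-recovery checks.
    """
    if rng is None:
        rng = np.random.default_rng(params.seed)
    elif isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(int(rng))
    I, J, K, L = params.n_env, params.n_lines, params.n_reps, params.n_traits

    chol_t = np.linalg.cholesky(params.Sigma_t)
    chol_E = np.linalg.cholesky(params.Sigma_E)
    chol_G = np.linalg.cholesky(params.G)
    chol_c = np.linalg.cholesky(params.Sigma_c)

    b1 = _matrix_normal(rng, chol_G, chol_t)                      # J x L
    # b2: cov (Sigma_E (x) G) over rows (env outer, line inner), Sigma_t cols
    Z = rng.standard_normal((I * J, L))
    row_chol = np.kron(chol_E, chol_G)
    b2 = (row_chol @ Z @ chol_t.T).reshape(I, J, L)
    c = rng.standard_normal((I, J, K, L)) @ chol_c.T              # iid N(0, Sigma_c)

    beta = params.beta.reshape(I, L)
    eta = beta[:, None, None, :] + b1[None, :, None, :] + b2[:, :, None, :] + c
    y = rng.poisson(np.exp(eta))

    env_ids = [f"Env{i + 1}" for i in range(I)]
    line_ids = [f"L{j + 1:03d}" for j in range(J)]
    trait_ids = [f"Trait{l + 1}" for l in range(L)]
    ii, jj, kk, ll = np.meshgrid(
        np.arange(I), np.arange(J), np.arange(K), np.arange(L), indexing="ij"
    )
    records = pd.DataFrame(
        {
            "env": np.array(env_ids)[ii.ravel()],
            "line": np.array(line_ids)[jj.ravel()],
            "rep": kk.ravel() + 1,
            "trait": np.array(trait_ids)[ll.ravel()],
            "count": y.ravel(),
        }
    )
    data = CountDataset(env_ids, line_ids, trait_ids, records)
    if not return_truth:
        return data
    truth = {
        "beta": params.beta.copy(),
        "b1": b1,
        "b2": b2,
        "c": c,
        # cell-level mean with replicate effect integrated out (lognormal mean)
        "cell_mu": np.exp(
            beta[:, None, :] + b1[None, :, :] + b2
            + 0.5 * np.diag(params.Sigma_c)[None, None, :]
        ),
    }
    return data, truth
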