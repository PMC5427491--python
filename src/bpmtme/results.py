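"""Posterior chain container, summaries and prediction from retained samples."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data import DesignBundle
from .gibbs import ChainSettings, Hyperparameters

__all__ = ["PosteriorChain", "FitResults"]


@dataclass
class PosteriorChain:
    """Thinned post-burn-in Gibbs samples plus posterior summaries.

    ``samples`` maps block names (beta_star, b1, b2, c, Sigma_t, Sigma_E,
    Sigma_c, a_t, a_E, a_c) to arrays whose leading axis indexes retained
    iterations.
    """

    samples: dict
    design: DesignBundle
    hyper: Hyperparameters
    settings: ChainSettings

    @property
    def n_retained(self) -> int:
        return self.samples["beta_star"].shape[0]

    def posterior_mean(self, name: str) -> np.ndarray:
        return self.samples[name].mean(axis=0)

    def posterior_sd(self, name: str) -> np.ndarray:
        return self.samples[name].std(axis=0, ddof=1)

    @property
    def beta(self) -> np.ndarray:
        """Intercept samples back-transformed to the count scale of the
        fitted (replicate-summed) response: beta = beta* + log r."""
        return self.samples["beta_star"] + np.log(self.design.r)

    # -- traces -----------------------------------------------------------
    def trace(self, name: str, index=None) -> np.ndarray:
        """Retained-sample trace of a block (or one scalar component).

        ``index`` may be a flat integer or a tuple into the block's shape.
        """
        arr = self.samples[name]
        flat = arr.reshape(arr.shape[0], -1)
        if index is None:
            return flat
        if isinstance(index, tuple):
            index = int(np.ravel_multi_index(index, arr.shape[1:]))
        return flat[:, int(index)]

    def autocorrelation(self, name: str, index: int = 0, n_lags: int = 50) -> np.ndarray:
        """Empirical autocorrelation function of one scalar trace."""
        x = self.trace(name, index)
        x = x - x.mean()
        n = x.size
        n_lags = min(n_lags, n - 1)
        denom = float(x @ x)
        if denom == 0:
            return np.zeros(n_lags + 1)
        return np.array([x[: n - k] @ x[k:] / denom for k in range(n_lags + 1)])

    # -- prediction -------------------------------------------------------
    def predict_cells(self, env_labels, line_labels, trait_labels) -> np.ndarray:
        """Posterior-mean predicted counts for arbitrary (env, line, trait)
        cells: average over samples of exp(beta + b1 + b2), the
        observation-level effect c set to its prior mean 0."""
        d = self.design
        env_pos = {e: i for i, e in enumerate(d.env_ids)}
        line_pos = {l: j for j, l in enumerate(d.line_ids)}
        trait_pos = {t: l for l, t in enumerate(d.trait_ids)}
        missing = [l for l in line_labels if l not in line_pos]
        if missing:
            raise KeyError(f"line(s) not present in the fitted design: {sorted(set(map(str, missing)))}")
        ei = np.array([env_pos[e] for e in env_labels])
        ji = np.array([line_pos[l] for l in line_labels])
        li = np.array([trait_pos[t] for t in trait_labels])
        L, J = d.n_traits, d.n_lines
        xcol = ei * L + li
        z1col = ji * L + li
        z2col = (ei * J + ji) * L + li
        eta = (
            self.samples["beta_star"][:, xcol]
            + np.log(d.r)
            + self.samples["b1"][:, z1col]
            + self.samples["b2"][:, z2col]
        )
        return np.exp(eta).mean(axis=0)

    # -- tabular output ---------------------------------------------------
    def _param_rows(self):
        d = self.design
        L, I = d.n_traits, d.n_env
        rows = []
        for i in range(I):
            for l in range(L):
                rows.append((f"beta*[{d.env_ids[i]},{d.trait_ids[l]}]",
                             self.samples["beta_star"][:, i * L + l]))
        for name, labels in (("Sigma_t", d.trait_ids), ("Sigma_c", d.trait_ids),
                             ("Sigma_E", d.env_ids)):
            arr = self.samples[name]
            p = arr.shape[1]
            for a in range(p):
                for b in range(a, p):
                    rows.append((f"{name}[{labels[a]},{labels[b]}]", arr[:, a, b]))
        return rows

    def summary(self) -> pd.DataFrame:
        """Posterior means and SDs of the intercepts and covariance
        components, one parameter per row."""
        rows = [
            {"parameter": name, "mean": float(tr.mean()), "sd": float(tr.std(ddof=1))}
            for name, tr in self._param_rows()
        ]
        return pd.DataFrame(rows)

    def to_csv(self, directory) -> None:
        """Serialize the chain (one CSV per block, iteration-indexed) and
        the summary table."""
        import pathlib

        directory = pathlib.Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        for name, arr in self.samples.items():
            flat = arr.reshape(arr.shape[0], -1)
            df = pd.DataFrame(flat)
            df.insert(0, "iteration", self._retained_iterations())
            df.to_csv(directory / f"chain_{name}.csv", index=False)
        self.summary().to_csv(directory / "summary.csv", index=False)

    def _retained_iterations(self) -> np.ndarray:
        s = self.settings
        return np.arange(
            s.burn_in + s.thin, s.burn_in + s.thin * (self.n_retained + 1), s.thin
        )[: self.n_retained]


class FitResults:
    """Model-fit results: a thin, statsmodels-flavored facade over the chain."""

    def __init__(self, model, chain: PosteriorChain):
        self.model = model
        self.chain = chain

    @property
    def design(self) -> DesignBundle:
        return self.chain.design

    def summary(self) -> pd.DataFrame:
        return self.chain.summary()

    def predict(self, env_labels, line_labels, trait_labels) -> np.ndarray:
        return self.chain.predict_cells(env_labels, line_labels, trait_labels)

    @property
    def posterior_means(self) -> dict:
        return {k: self.chain.posterior_mean(k) for k in self.chain.samples}

    def trait_correlation(self, which: str = "Sigma_t") -> np.ndarray:
        from .simulate import cov_to_corr

        return cov_to_corr(self.chain.posterior_mean(which))

    def plot_trace(self, name: str = "Sigma_t", index: int = 0, ax=None):
        """Trace plot of one scalar parameter (requires matplotlib)."""
        import matplotlib

        matplotlib.use("Agg", force=False)
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.plot(self.chain._retained_iterations(), self.chain.trace(name, index))
        ax.set_xlabel("iteration")
        ax.set_ylabel(f"{name}[{index}]")
        return ax
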