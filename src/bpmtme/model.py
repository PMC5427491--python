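"""Model classes: multivariate BPMTME and its univariate BPME special case.

The API follows the fit-from-data idiom: construct a model from a
long-format phenotype table (and optionally a genomic relationship
matrix), call :meth:`fit` to run the Gibbs sampler, and work with the
returned :class:`~bpmtme.results.FitResults`.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .data import (
    CollapsedDataset,
    CountDataset,
    RelationshipMatrix,
    build_design,
    collapse_replicates,
)
from .gibbs import ChainSettings, Hyperparameters, run_chain
from .results import FitResults

__all__ = ["BPMTME", "BPME", "fit_bpme"]


def _as_collapsed(data) -> CollapsedDataset:
    if isinstance(data, CollapsedDataset):
        return data
    if isinstance(data, CountDataset):
        return collapse_replicates(data)
    raise TypeError("data must be a CountDataset or CollapsedDataset")


def restrict_to_trait(collapsed: CollapsedDataset, trait) -> CollapsedDataset:
    """Single-trait view of a collapsed dataset (for univariate fits)."""
    if trait not in collapsed.trait_ids:
        raise KeyError(f"unknown trait {trait!r}")
    cells = collapsed.cells[collapsed.cells["trait"] == trait].reset_index(drop=True)
    return CollapsedDataset(
        env_ids=list(collapsed.env_ids),
        line_ids=list(collapsed.line_ids),
        trait_ids=[trait],
        cells=cells,
    )


class BPMTME:
    """Bayesian Poisson-lognormal multiple-trait multiple-environment model.

    Parameters
    ----------
    data : CountDataset or CollapsedDataset
        Count phenotypes; replicate-level data are summed per (environment,
        line, trait) cell before fitting.
    grm : RelationshipMatrix, optional
        Genomic relationships among lines; identity (independent
        genotypes) when omitted.  Reordered to the dataset's line order.
    hyper : Hyperparameters, optional
        NB size r and prior constants; weakly-informative defaults.

    Examples
    --------
    >>> model = BPMTME.from_dataframe(df)          # doctest: +SKIP
    >>> res = model.fit(n_iter=4000, burn_in=2000, thin=5, seed=7)
    >>> res.summary()
    """

    def __init__(self, data, grm: RelationshipMatrix | None = None,
                 hyper: Hyperparameters | None = None):
        self.collapsed = _as_collapsed(data)
        self.hyper = hyper or Hyperparameters()
        if grm is None:
            grm = RelationshipMatrix.identity(self.collapsed.line_ids)
        self.grm = grm.reorder(self.collapsed.line_ids)
        self.design = build_design(self.collapsed, r=self.hyper.r)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, schema: dict | None = None,
                       grm: RelationshipMatrix | None = None,
                       hyper: Hyperparameters | None = None) -> "BPMTME":
        return cls(CountDataset.from_dataframe(df, schema), grm=grm, hyper=hyper)

    def fit(self, n_iter: int = 40000, burn_in: int = 20000, thin: int = 5,
            seed: int | None = None, rng=None, progress: bool = False) -> FitResults:
        settings = ChainSettings(n_iter=n_iter, burn_in=burn_in, thin=thin, seed=seed)
        chain = run_chain(self.design, self.grm, self.hyper, settings,
                          rng=rng, progress=progress)
        return FitResults(self, chain)


class BPME(BPMTME):
    """Univariate (single-trait) multi-environment special case.

    Identical machinery with L = 1; the trait covariances degenerate to
    scalars.  ``trait`` selects which trait of the dataset to model.
    """

    def __init__(self, data, trait, grm: RelationshipMatrix | None = None,
                 hyper: Hyperparameters | None = None):
        collapsed = restrict_to_trait(_as_collapsed(data), trait)
        super().__init__(collapsed, grm=grm, hyper=hyper)
        self.trait = trait


def fit_bpme(data, trait, grm: RelationshipMatrix | None = None,
             hyper: Hyperparameters | None = None,
             n_iter: int = 40000, burn_in: int = 20000, thin: int = 5,
             seed: int | None = None, rng=None) -> FitResults:
    """Fit the univariate multi-environment model to one trait."""
    return BPME(data, trait, grm=grm, hyper=hyper).fit(
        n_iter=n_iter, burn_in=burn_in, thin=thin, seed=seed, rng=rng
    )
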