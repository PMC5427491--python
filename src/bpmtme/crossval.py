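"""CV1 cross-validation: masking plans, posterior prediction, Spearman accuracy.

CV1 mimics the breeding situation where a line has been phenotyped (for
all traits) in some environments but is missing in others: whole
(environment, line) cells are masked jointly across traits.  Accuracy is
the Spearman rank correlation between predicted and observed counts of
the masked cells, computed per (trait, environment) combination within
each random partition and averaged over partitions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .data import CollapsedDataset, RelationshipMatrix
from .gibbs import Hyperparameters
from .model import BPME, BPMTME
from .results import PosteriorChain

__all__ = [
    "CV1Plan",
    "AccuracyTable",
    "make_cv1_partitions",
    "predict_masked",
    "spearman",
    "evaluate_models",
]

TEST_FRACTIONS = (0.1, 0.2, 0.3, 0.4, 0.5)


@dataclass
class CV1Plan:
    """Masked (env, line) cells for each of n_partitions random splits."""

    n_partitions: int
    test_fraction: float
    masked: list          # per partition: list of (env_label, line_label)
    seed: int | None = None
    by_line: bool = False

    def __post_init__(self) -> None:
        if len(self.masked) != self.n_partitions:
            raise ValueError("masked must hold one cell list per partition")


def _partition_seed(seed, *tags) -> np.random.Generator:
    entropy = [int(t) for t in tags]
    if seed is not None:
        entropy = [int(seed)] + entropy
    return np.random.default_rng(np.random.SeedSequence(entropy))


def make_cv1_partitions(
    collapsed: CollapsedDataset,
    fraction: float,
    n_partitions: int = 10,
    seed: int | None = None,
    by_line: bool = False,
) -> CV1Plan:
    """Draw CV1 masking partitions.

    Cell-level masking (default) removes ``floor(fraction * n_cells)``
    (env, line) cells uniformly at random, never leaving a line
    unobserved in every environment.  With ``by_line=True`` a fraction of
    *lines* is selected instead and each selected line is masked in a
    random nonempty, proper subset of its environments.
    """
    if not 0 < fraction < 1:
        raise ValueError("fraction must lie in (0, 1)")
    cells = (
        collapsed.cells[["env", "line"]]
        .drop_duplicates()
        .reset_index(drop=True)
    )
    line_cells = cells.groupby("line", sort=False).size()

    masked_sets = []
    for p in range(n_partitions):
        rng = _partition_seed(seed, 11, p)
        if by_line:
            lines = list(collapsed.line_ids)
            n_sel = int(np.floor(fraction * len(lines)))
            if n_sel < 1:
                raise ValueError("fraction selects no lines")
            multi = [l for l in lines if line_cells.get(l, 0) >= 2]
            if len(multi) < n_sel:
                raise ValueError(
                    "cannot mask lines observed in a single environment only"
                )
            chosen = rng.choice(len(multi), size=n_sel, replace=False)
            mask = []
            for idx in chosen:
                line = multi[idx]
                envs = cells.loc[cells["line"] == line, "env"].tolist()
                n_drop = int(rng.integers(1, len(envs)))  # proper, nonempty
                for e in rng.choice(len(envs), size=n_drop, replace=False):
                    mask.append((envs[int(e)], line))
        else:
            n_mask = int(np.floor(fraction * len(cells)))
            if n_mask < 1:
                raise ValueError("fraction masks no cells")
            order = rng.permutation(len(cells))
            remaining = line_cells.to_dict()
            mask = []
            for idx in order:
                if len(mask) == n_mask:
                    break
                env, line = cells.iloc[int(idx)]
                if remaining[line] >= 2:
                    mask.append((env, line))
                    remaining[line] -= 1
            if len(mask) < n_mask:
                raise ValueError(
                    f"cannot mask {n_mask} cells without leaving a line "
                    f"unobserved in every environment"
                )
        masked_sets.append(mask)
    return CV1Plan(
        n_partitions=n_partitions,
        test_fraction=fraction,
        masked=masked_sets,
        seed=seed,
        by_line=by_line,
    )


def mask_cells(collapsed: CollapsedDataset, masked) -> CollapsedDataset:
    """Training view of a collapsed dataset with the given cells removed."""
    key = set(masked)
    keep = ~collapsed.cells.apply(
        lambda row: (row["env"], row["line"]) in key, axis=1
    )
    return CollapsedDataset(
        env_ids=list(collapsed.env_ids),
        line_ids=list(collapsed.line_ids),
        trait_ids=list(collapsed.trait_ids),
        cells=collapsed.cells[keep].reset_index(drop=True),
    )


def predict_masked(chain: PosteriorChain, masked) -> pd.DataFrame:
    """Posterior-mean predicted counts for masked cells, all traits.

    Per retained sample s the prediction for cell (i, j) and trait l is
    exp(beta_i(l) + b_j(l) + b_ij(l)); the unobserved cell's
    observation-level effect is set to its prior mean 0.  The average
    over samples is returned on the fitted (replicate-summed) count
    scale.
    """
    d = chain.design
    rows = [
        {"env": env, "line": line, "trait": t}
        for env, line in masked
        for t in d.trait_ids
    ]
    out = pd.DataFrame(rows)
    out["prediction"] = chain.predict_cells(
        out["env"].tolist(), out["line"].tolist(), out["trait"].tolist()
    )
    return out


def spearman(x, y) -> float:
    """Spearman rank correlation with average-rank tie handling."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D vectors of equal length")
    if x.size < 2:
        raise ValueError("need at least 2 values")
    import warnings

    with warnings.catch_warnings():
        # a constant vector has no defined rank correlation; propagate NaN
        warnings.simplefilter("ignore", stats.ConstantInputWarning)
        rho = stats.spearmanr(x, y).statistic
    return float(rho)


@dataclass
class AccuracyTable:
    """Per-(trait, env, model, test_fraction) Spearman accuracy summaries."""

    table: pd.DataFrame  # trait, env, model, test_fraction, mean_spearman, sd_spearman

    def __post_init__(self) -> None:
        t = self.table
        bad = t["mean_spearman"].abs() > 1 + 1e-12
        if bad.any() or (t["sd_spearman"] < 0).any():
            raise ValueError("invalid accuracy summaries")

    def grand_average(self, model: str, test_fraction: float) -> float:
        """Average of the per-(trait, env) mean correlations — the
        'Average' row of the accuracy tables."""
        sel = self.table[
            (self.table["model"] == model)
            & (np.isclose(self.table["test_fraction"], test_fraction))
        ]
        if sel.empty:
            raise KeyError(f"no rows for {model} at {test_fraction}")
        return float(sel["mean_spearman"].mean())

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)

    def to_markdown(self) -> str:
        t = self.table
        cols = list(t.columns)
        lines = ["| " + " | ".join(cols) + " |",
                 "|" + "|".join("---" for _ in cols) + "|"]
        for _, row in t.iterrows():
            cells = [
                f"{v:.4f}" if isinstance(v, float) else str(v) for v in row
            ]
            lines.append("| " + " | ".join(cells) + " |")
        return "\n".join(lines)


def _fit_and_predict(model_name, train, grm, hyper, masked, chain_kw, seed_tags):
    """Fit one model on the training cells and predict the masked cells."""
    rng = _partition_seed(chain_kw.get("seed"), *seed_tags)
    kw = {k: v for k, v in chain_kw.items() if k != "seed"}
    if callable(model_name):
        return model_name(train, masked, rng)
    if model_name == "BPMTME":
        res = BPMTME(train, grm=grm, hyper=hyper).fit(rng=rng, **kw)
        return predict_masked(res.chain, masked)
    if model_name == "BPME":
        parts = []
        for ti, trait in enumerate(train.trait_ids):
            res = BPME(train, trait, grm=grm, hyper=hyper).fit(
                rng=_partition_seed(chain_kw.get("seed"), *seed_tags, ti), **kw
            )
            parts.append(predict_masked(res.chain, masked))
        return pd.concat(parts, ignore_index=True)
    raise ValueError(f"unknown model {model_name!r}")


def evaluate_models(
    data,
    grm: RelationshipMatrix | None = None,
    fractions=(0.1,),
    n_partitions: int = 10,
    models=("BPMTME", "BPME"),
    hyper: Hyperparameters | None = None,
    n_iter: int = 4000,
    burn_in: int = 2000,
    thin: int = 5,
    seed: int | None = None,
) -> AccuracyTable:
    """CV1 accuracy table for the requested models and testing fractions.

    For every model x fraction x partition the model is refit on the
    unmasked cells only, masked cells are predicted from the retained
    samples, and Spearman correlations between predictions and observed
    counts are computed per (trait, environment) combination, then
    averaged (mean and SD) over partitions.
    """
    from .model import _as_collapsed

    collapsed = _as_collapsed(data)
    hyper = hyper or Hyperparameters()
    chain_kw = dict(n_iter=n_iter, burn_in=burn_in, thin=thin, seed=seed)
    obs = collapsed.cells.set_index(["env", "line", "trait"])["count"]

    rows = []
    for fi, fraction in enumerate(fractions):
        plan = make_cv1_partitions(
            collapsed, fraction, n_partitions=n_partitions, seed=seed
        )
        per_combo: dict = {}
        for p, masked in enumerate(plan.masked):
            train = mask_cells(collapsed, masked)
            for mi, model_name in enumerate(models):
                name = model_name if isinstance(model_name, str) else getattr(
                    model_name, "__name__", "custom"
                )
                pred = _fit_and_predict(
                    model_name, train, grm, hyper, masked, chain_kw,
                    seed_tags=(23, fi, p, mi),
                )
                pred = pred.assign(
                    observed=[
                        obs.loc[(e, l, t)]
                        for e, l, t in zip(pred["env"], pred["line"], pred["trait"])
                    ]
                )
                for (trait, env), grp in pred.groupby(["trait", "env"], sort=False):
                    # a combination with a single masked cell carries no
                    # rank information in this partition
                    rho = (
                        spearman(grp["prediction"], grp["observed"])
                        if len(grp) >= 2 else np.nan
                    )
                    per_combo.setdefault((trait, env, name), []).append(rho)
        for (trait, env, name), rhos in per_combo.items():
            rhos = np.asarray(rhos, dtype=float)
            valid = rhos[np.isfinite(rhos)]
            rows.append(
                {
                    "trait": trait,
                    "env": env,
                    "model": name,
                    "test_fraction": fraction,
                    "mean_spearman": float(valid.mean()) if valid.size else np.nan,
                    "sd_spearman": float(valid.std(ddof=1)) if valid.size > 1 else 0.0,
                }
            )
    return AccuracyTable(pd.DataFrame(rows))
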