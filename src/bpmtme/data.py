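"""Phenotype/marker ingestion, replicate collapsing, GRM and design structures.

The observation stacking convention used throughout the package is fixed
here and is law for every downstream module:

* rows are ordered environment-major, then line, then observational unit,
  with trait innermost;
* the environment-by-trait intercept design ``X`` has I*L columns ordered
  (environment outer, trait inner);
* the line-by-trait design ``Z1`` has J*L columns ordered (line outer,
  trait inner), matching the Kronecker prior covariance G (x) Sigma_t;
* the interaction design ``Z2`` has I*J*L columns ordered (environment
  outer, line middle, trait inner), matching Sigma_E (x) G (x) Sigma_t.

Internal indexing is 0-based; user-facing labels are preserved.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp

__all__ = [
    "CountDataset",
    "CollapsedDataset",
    "RelationshipMatrix",
    "DesignBundle",
    "DEFAULT_SCHEMA",
    "load_phenotypes",
    "load_markers",
    "collapse_replicates",
    "compute_grm",
    "build_design",
]

DEFAULT_SCHEMA = {
    "env": "env",
    "line": "line",
    "rep": "rep",
    "trait": "trait",
    "count": "count",
}


class SchemaError(ValueError):
    """A required column is missing from an input table."""


class ValidationError(ValueError):
    """An input value violates the data contract."""


def _unique_in_order(values) -> list:
    seen: dict = {}
    for v in values:
        seen.setdefault(v, None)
    return list(seen)


@dataclass
class CountDataset:
    """Long-format count phenotypes indexed by environment/line/replicate/trait.

    ``records`` holds one row per observed count with columns
    ``env, line, rep, trait, count``; counts are non-negative integers and
    each (env, line, rep, trait) combination occurs at most once.
    """

    env_ids: list
    line_ids: list
    trait_ids: list
    records: pd.DataFrame

    def __post_init__(self) -> None:
        req = ["env", "line", "rep", "trait", "count"]
        missing = [c for c in req if c not in self.records.columns]
        if missing:
            raise SchemaError(f"records missing columns: {missing}")
        rec = self.records.reset_index(drop=True)
        counts = rec["count"]
        as_float = pd.to_numeric(counts, errors="coerce")
        bad = as_float.isna() | (as_float < 0) | (as_float != np.floor(as_float))
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise ValidationError(
                f"count must be a non-negative integer; offending row {row} "
                f"(value {counts.iloc[row]!r})"
            )
        rec["count"] = as_float.astype(np.int64)
        dup = rec.duplicated(subset=["env", "line", "rep", "trait"])
        if dup.any():
            row = int(np.flatnonzero(dup.to_numpy())[0])
            raise ValidationError(f"duplicate (env,line,rep,trait) at row {row}")
        for col, ids in (("env", self.env_ids), ("line", self.line_ids),
                         ("trait", self.trait_ids)):
            unknown = set(rec[col]) - set(ids)
            if unknown:
                raise ValidationError(f"unknown {col} label(s): {sorted(map(str, unknown))}")
        observed_lines = set(rec["line"])
        orphan = [l for l in self.line_ids if l not in observed_lines]
        if orphan:
            raise ValidationError(f"line(s) with no records: {orphan}")
        self.records = rec

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, schema: dict | None = None) -> "CountDataset":
        schema = {**DEFAULT_SCHEMA, **(schema or {})}
        missing = [v for v in schema.values() if v not in df.columns]
        if missing:
            raise SchemaError(f"input table missing column(s): {missing}")
        rec = df[[schema[k] for k in ("env", "line", "rep", "trait", "count")]].copy()
        rec.columns = ["env", "line", "rep", "trait", "count"]
        return cls(
            env_ids=_unique_in_order(rec["env"]),
            line_ids=_unique_in_order(rec["line"]),
            trait_ids=_unique_in_order(rec["trait"]),
            records=rec,
        )

    @property
    def n_env(self) -> int:
        return len(self.env_ids)

    @property
    def n_lines(self) -> int:
        return len(self.line_ids)

    @property
    def n_traits(self) -> int:
        return len(self.trait_ids)

    def to_csv(self, path) -> None:
        self.records.to_csv(path, index=False)


def load_phenotypes(path, schema: dict | None = None) -> CountDataset:
    """Read a long-format phenotype table (CSV or TSV) into a CountDataset.

    ``schema`` maps the canonical roles env/line/rep/trait/count to the
    file's column names; defaults to those names themselves.
    """
    df = pd.read_csv(path, sep=None, engine="python")
    return CountDataset.from_dataframe(df, schema)


@dataclass
class CollapsedDataset:
    """Replicate-summed counts: one row per (env, line, trait) cell.

    ``cells`` has columns ``env, line, trait, count, k`` where ``count`` is
    the sum over the cell's replicates and ``k`` their number.  Replicates
    are summed rather than averaged so the response stays a count; the
    environment intercepts absorb the resulting scale.
    """

    env_ids: list
    line_ids: list
    trait_ids: list
    cells: pd.DataFrame

    def __post_init__(self) -> None:
        if (self.cells["k"] < 1).any():
            raise ValidationError("replicate count k must be >= 1")

    def is_complete(self) -> bool:
        """True when every retained (env, line) cell carries all traits."""
        per_cell = self.cells.groupby(["env", "line"], sort=False)["trait"].nunique()
        return bool((per_cell == len(self.trait_ids)).all())


def collapse_replicates(data: CountDataset) -> CollapsedDataset:
    """Sum counts over replicates within each (env, line, trait) cell."""
    g = data.records.groupby(["env", "line", "trait"], sort=False)["count"]
    summed = g.sum().rename("count")
    k = (
        data.records.groupby(["env", "line"], sort=False)["rep"]
        .nunique()
        .rename("k")
    )
    cells = summed.reset_index().merge(k.reset_index(), on=["env", "line"])
    return CollapsedDataset(
        env_ids=list(data.env_ids),
        line_ids=list(data.line_ids),
        trait_ids=list(data.trait_ids),
        cells=cells,
    )


@dataclass
class RelationshipMatrix:
    """Symmetric positive-definite genomic relationship matrix among lines."""

    G: np.ndarray
    line_ids: list

    def __post_init__(self) -> None:
        G = np.asarray(self.G, dtype=float)
        if G.ndim != 2 or G.shape[0] != G.shape[1]:
            raise ValidationError("G must be square")
        if G.shape[0] != len(self.line_ids):
            raise ValidationError("G dimension does not match line_ids")
        if np.max(np.abs(G - G.T)) > 1e-10:
            raise ValidationError("G must be symmetric (tolerance 1e-10)")
        if np.any(np.diag(G) <= 0):
            raise ValidationError("G must have positive diagonal")
        try:
            np.linalg.cholesky(G)
        except np.linalg.LinAlgError as exc:
            raise ValidationError("G is not positive definite") from exc
        self.G = G

    @classmethod
    def identity(cls, line_ids) -> "RelationshipMatrix":
        return cls(np.eye(len(line_ids)), list(line_ids))

    @classmethod
    def from_file(cls, path) -> "RelationshipMatrix":
        df = pd.read_csv(path, sep=None, engine="python", index_col=0)
        return cls(df.to_numpy(dtype=float), list(df.index))

    @property
    def is_diagonal(self) -> bool:
        cached = self.__dict__.get("_is_diag")
        if cached is None:
            cached = bool(np.count_nonzero(self.G - np.diag(np.diag(self.G))) == 0)
            self.__dict__["_is_diag"] = cached
        return cached

    @property
    def G_inv(self) -> np.ndarray:
        """Cached inverse (diagonal shortcut when G is diagonal)."""
        cached = self.__dict__.get("_G_inv")
        if cached is None:
            if self.is_diagonal:
                cached = np.diag(1.0 / np.diag(self.G))
            else:
                from scipy.linalg import cho_factor, cho_solve

                inv = cho_solve(cho_factor(self.G), np.eye(self.G.shape[0]))
                cached = 0.5 * (inv + inv.T)
            self.__dict__["_G_inv"] = cached
        return cached

    @property
    def logdet(self) -> float:
        cached = self.__dict__.get("_logdet")
        if cached is None:
            cached = float(np.linalg.slogdet(self.G)[1])
            self.__dict__["_logdet"] = cached
        return cached

    def reorder(self, line_ids) -> "RelationshipMatrix":
        """Align rows/columns with the given line ordering."""
        pos = {l: i for i, l in enumerate(self.line_ids)}
        missing = [l for l in line_ids if l not in pos]
        if missing:
            raise ValidationError(f"lines absent from relationship matrix: {missing}")
        idx = np.array([pos[l] for l in line_ids])
        return RelationshipMatrix(self.G[np.ix_(idx, idx)], list(line_ids))


def load_markers(path) -> pd.DataFrame:
    """Read a line-by-marker dosage table; first column is the line ID."""
    df = pd.read_csv(path, sep=None, engine="python", index_col=0,
                     na_values=["NA", ""])
    return df


def compute_grm(
    markers,
    line_ids=None,
    maf_min: float = 0.05,
    max_missing: float = 0.10,
    jitter: float = 1e-8,
) -> RelationshipMatrix:
    """Centered cross-product genomic relationship matrix G = W W' / m_eff.

    Markers are filtered for minor allele frequency (>= ``maf_min``) and
    per-marker missing-call rate (<= ``max_missing``), then missing dosages
    are mean-imputed and columns centered.  For 0/1/2 dosage coding the
    VanRaden denominator m_eff = 2 sum p_q (1 - p_q) is used; for
    presence/absence 0/1 coding m_eff is the number of retained markers.
    A relative jitter (starting at ``jitter`` times the mean diagonal and
    growing tenfold up to 1e-4) is added until the matrix factorizes.
    """
    if isinstance(markers, pd.DataFrame):
        line_ids = list(markers.index)
        M = markers.to_numpy(dtype=float)
    else:
        M = np.asarray(markers, dtype=float)
        line_ids = list(line_ids) if line_ids is not None else list(range(M.shape[0]))
    if M.shape[0] < 2:
        raise ValidationError("need at least 2 lines to build a relationship matrix")
    finite = M[np.isfinite(M)]
    if finite.size and not np.all(np.isin(finite, (0.0, 1.0, 2.0))):
        raise ValidationError("marker dosages must be 0/1/2 or missing")

    ploidy_coded = bool(finite.size) and finite.max() > 1.0
    denom = 2.0 if ploidy_coded else 1.0

    miss_rate = np.mean(~np.isfinite(M), axis=0)
    keep = miss_rate <= max_missing
    with np.errstate(invalid="ignore"):
        p = np.nanmean(M, axis=0) / denom
    maf = np.minimum(p, 1.0 - p)
    keep &= np.isfinite(p) & (maf >= maf_min)
    if not keep.any():
        raise ValidationError("all markers removed by MAF/missingness filters")
    M = M[:, keep]
    p = p[keep]

    col_mean = np.nanmean(M, axis=0)
    idx = np.where(np.isfinite(M), M, col_mean[None, :])
    W = idx - col_mean[None, :]
    if ploidy_coded:
        m_eff = 2.0 * np.sum(p * (1.0 - p))
    else:
        m_eff = float(M.shape[1])
    G = W @ W.T / m_eff

    G = 0.5 * (G + G.T)
    base = np.mean(np.diag(G))
    if base <= 0:
        base = 1.0
    eps = jitter
    while True:
        try:
            np.linalg.cholesky(G + eps * base * np.eye(G.shape[0]))
            break
        except np.linalg.LinAlgError:
            eps *= 10.0
            if eps > 1e-4:
                raise ValidationError("relationship matrix could not be stabilized")
    return RelationshipMatrix(G + eps * base * np.eye(G.shape[0]), line_ids)


@dataclass
class DesignBundle:
    """Stacked response and index-map realizations of X, Z1, Z2.

    One row per (observed cell, trait) in the fixed stacking order.  The
    integer index arrays give, per row, the 0-based environment, line,
    observational unit and trait; ``*_col`` properties give each row's
    single nonzero column in the corresponding incidence matrix.
    """

    y: np.ndarray
    r: float
    env_idx: np.ndarray
    line_idx: np.ndarray
    unit_idx: np.ndarray
    trait_idx: np.ndarray
    n_env: int
    n_lines: int
    n_traits: int
    n_units: int
    env_ids: list
    line_ids: list
    trait_ids: list
    unit_cells: pd.DataFrame  # per unit (in order): env, line, k
    ystar: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.y = np.asarray(self.y, dtype=float)
        self.ystar = (self.y - self.r) / 2.0

    # -- column index maps (the Kronecker-consistent flattenings) ---------
    @property
    def x_col(self) -> np.ndarray:
        return self.env_idx * self.n_traits + self.trait_idx

    @property
    def z1_col(self) -> np.ndarray:
        return self.line_idx * self.n_traits + self.trait_idx

    @property
    def z2_col(self) -> np.ndarray:
        return (self.env_idx * self.n_lines + self.line_idx) * self.n_traits + self.trait_idx

    @property
    def n_obs(self) -> int:
        return self.y.size

    def _incidence(self, cols: np.ndarray, width: int) -> sp.csr_matrix:
        data = np.ones(self.n_obs)
        return sp.csr_matrix(
            (data, (np.arange(self.n_obs), cols)), shape=(self.n_obs, width)
        )

    @property
    def X(self) -> sp.csr_matrix:
        return self._incidence(self.x_col, self.n_env * self.n_traits)

    @property
    def Z1(self) -> sp.csr_matrix:
        return self._incidence(self.z1_col, self.n_lines * self.n_traits)

    @property
    def Z2(self) -> sp.csr_matrix:
        return self._incidence(
            self.z2_col, self.n_env * self.n_lines * self.n_traits
        )

    def eta_star(self, beta_star, b1, b2, c) -> np.ndarray:
        """Linear predictor X beta* + Z1 b1 + Z2 b2 + c through index maps."""
        beta_star = np.asarray(beta_star, float).ravel()
        b1 = np.asarray(b1, float).ravel()
        b2 = np.asarray(b2, float).ravel()
        c = np.asarray(c, float).reshape(self.n_units, self.n_traits)
        return (
            beta_star[self.x_col]
            + b1[self.z1_col]
            + b2[self.z2_col]
            + c[self.unit_idx, self.trait_idx]
        )


def build_design(collapsed: CollapsedDataset, r: float = 1000.0) -> DesignBundle:
    """Stack a collapsed dataset into the fixed design/index structures.

    Every retained (env, line) cell must carry all declared traits; the
    negative-binomial size ``r`` fixes the working response
    ystar = (y - r) / 2.
    """
    env_pos = {e: i for i, e in enumerate(collapsed.env_ids)}
    line_pos = {l: j for j, l in enumerate(collapsed.line_ids)}
    trait_pos = {t: l for l, t in enumerate(collapsed.trait_ids)}
    L = len(collapsed.trait_ids)

    cells = collapsed.cells.copy()
    cells["_e"] = cells["env"].map(env_pos)
    cells["_j"] = cells["line"].map(line_pos)
    cells["_l"] = cells["trait"].map(trait_pos)
    cells = cells.sort_values(["_e", "_j", "_l"], kind="stable")

    per_cell = cells.groupby(["_e", "_j"], sort=True)
    counts = per_cell["_l"].nunique()
    if (counts != L).any():
        e, j = counts.index[counts != L][0]
        raise ValidationError(
            f"cell (env={collapsed.env_ids[e]!r}, line={collapsed.line_ids[j]!r}) "
            f"has partial trait coverage"
        )

    unit_of = {cell: u for u, cell in enumerate(counts.index)}
    env_idx = cells["_e"].to_numpy()
    line_idx = cells["_j"].to_numpy()
    trait_idx = cells["_l"].to_numpy()
    unit_idx = np.array([unit_of[(e, j)] for e, j in zip(env_idx, line_idx)])

    k_per_unit = per_cell["k"].first()
    unit_cells = pd.DataFrame(
        {
            "env": [collapsed.env_ids[e] for e, _ in counts.index],
            "line": [collapsed.line_ids[j] for _, j in counts.index],
            "k": k_per_unit.to_numpy(),
        }
    )

    return DesignBundle(
        y=cells["count"].to_numpy(),
        r=float(r),
        env_idx=env_idx,
        line_idx=line_idx,
        unit_idx=unit_idx,
        trait_idx=trait_idx,
        n_env=len(collapsed.env_ids),
        n_lines=len(collapsed.line_ids),
        n_traits=L,
        n_units=len(unit_of),
        env_ids=list(collapsed.env_ids),
        line_ids=list(collapsed.line_ids),
        trait_ids=list(collapsed.trait_ids),
        unit_cells=unit_cells,
    )
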