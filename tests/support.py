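"""Shared test utilities: tiny model builders, dense conditional oracles,
and the Geweke successive-conditional sampler check."""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

import bpmtme as bp
from bpmtme import gibbs as G
from bpmtme.polya_gamma import draw_pg


def make_count_dataset(I=2, J=3, L=2, K=1, counts=None, rng=None):
    """Deterministic (or seeded) complete dataset with simple labels."""
    env_ids = [f"E{i + 1}" for i in range(I)]
    line_ids = [f"L{j + 1}" for j in range(J)]
    trait_ids = [f"T{l + 1}" for l in range(L)]
    if rng is None:
        rng = np.random.default_rng(0)
    recs = []
    pos = 0
    for e in env_ids:
        for l in line_ids:
            for k in range(1, K + 1):
                for t in trait_ids:
                    if counts is not None:
                        y = counts[pos]
                        pos += 1
                    else:
                        y = int(rng.poisson(3))
                    recs.append(
                        {"env": e, "line": l, "rep": k, "trait": t, "count": y}
                    )
    return bp.CountDataset(env_ids, line_ids, trait_ids, pd.DataFrame(recs))


def make_tiny_model(I=2, J=3, L=2, r=5.0, seed=5, diag_g=True, n_sweeps=10,
                    hyper_kw=None):
    """Small fitted-state bundle for conditional-distribution checks."""
    rng = np.random.default_rng(seed)
    data = make_count_dataset(I, J, L, rng=rng)
    col = bp.collapse_replicates(data)
    design = bp.build_design(col, r=r)
    if diag_g:
        grm = bp.RelationshipMatrix.identity(col.line_ids)
    else:
        A = rng.standard_normal((J, J))
        grm = bp.RelationshipMatrix(A @ A.T + J * np.eye(J), col.line_ids)
    kw = dict(r=r, beta_prior_scale=4.0, A_t=2.0, A_E=2.0, A_c=2.0)
    kw.update(hyper_kw or {})
    hyper = bp.Hyperparameters(**kw)
    state = G.initialize_state(design, grm, hyper, rng)
    for _ in range(n_sweeps):
        state = G.gibbs_step(state, design, grm, hyper, rng)
    return state, design, grm, hyper, rng


def dense_conditional(block, state, design, grm, hyper):
    """Brute-force (dense-matrix) Gaussian full-conditional (Q, mean) oracle."""
    X = design.X.toarray()
    Z1 = design.Z1.toarray()
    Z2 = design.Z2.toarray()
    D = np.diag(state.omega)
    G_inv = np.linalg.inv(grm.G)
    St_inv = np.linalg.inv(state.Sigma_t)
    SE_inv = np.linalg.inv(state.Sigma_E)
    Sc_inv = np.linalg.inv(state.Sigma_c)
    p_beta = design.n_env * design.n_traits
    cvec = state.c.ravel()
    Zc = np.eye(design.n_obs)
    blocks = {
        "beta_star": (X, hyper.beta_prior_precision * np.eye(p_beta), state.beta_star),
        "b1": (Z1, np.kron(G_inv, St_inv), state.b1),
        "b2": (Z2, np.kron(SE_inv, np.kron(G_inv, St_inv)), state.b2),
        "c": (Zc, np.kron(np.eye(design.n_units), Sc_inv), cvec),
    }
    Z, P, _ = blocks[block]
    parts = {
        "beta_star": X @ state.beta_star,
        "b1": Z1 @ state.b1,
        "b2": Z2 @ state.b2,
        "c": cvec,
    }
    eta_rest = sum(v for k, v in parts.items() if k != block)
    Q = Z.T @ D @ Z + P
    rhs = Z.T @ (design.ystar - D @ eta_rest)
    if block == "beta_star":
        m0 = np.broadcast_to(np.asarray(hyper.beta_prior_mean, float), (p_beta,))
        rhs = rhs + hyper.beta_prior_precision * m0
    return Q, np.linalg.solve(Q, rhs)


def batch_means_se(x, n_batches=50):
    m = len(x) // n_batches
    bm = x[: m * n_batches].reshape(n_batches, m).mean(axis=1)
    return bm.std(ddof=1) / np.sqrt(n_batches)


def geweke_zscores(n_marginal=4000, n_successive=9000, burn=500, seed=1234):
    """Successive-conditional ("getting it right") check on an I=2, J=3,
    L=2 model with r=5 and tight priors.

    Returns z-scores comparing, per monitored functional, the probability
    mass below the marginal-conditional median between the two simulators.
    Under a correct sampler every |z| should behave like a standard
    normal.
    """
    I, J, L = 2, 3, 2
    r = 5.0
    hyper = bp.Hyperparameters(r=r, beta_prior_scale=0.25, A_t=0.5, A_E=0.5, A_c=0.5)
    data = make_count_dataset(I, J, L, counts=[1] * (I * J * L))
    col = bp.collapse_replicates(data)
    design = bp.build_design(col, r=r)
    grm = bp.RelationshipMatrix.identity(col.line_ids)
    Gm = grm.G
    rng = np.random.default_rng(seed)

    def draw_prior():
        a_t = (1 / hyper.A_t**2) / rng.gamma(0.5, size=L)
        a_E = (1 / hyper.A_E**2) / rng.gamma(0.5, size=I)
        a_c = (1 / hyper.A_c**2) / rng.gamma(0.5, size=L)
        St = np.atleast_2d(stats.invwishart.rvs(
            df=hyper.nu_t + L - 1, scale=2 * hyper.nu_t * np.diag(1 / a_t),
            random_state=rng))
        SE = np.atleast_2d(stats.invwishart.rvs(
            df=hyper.nu_E + I - 1, scale=2 * hyper.nu_E * np.diag(1 / a_E),
            random_state=rng))
        Sc = np.atleast_2d(stats.invwishart.rvs(
            df=hyper.nu_c + L - 1, scale=2 * hyper.nu_c * np.diag(1 / a_c),
            random_state=rng))
        beta = rng.standard_normal(I * L) * np.sqrt(hyper.beta_prior_scale)
        ct = np.linalg.cholesky(St)
        b1 = (np.linalg.cholesky(Gm) @ rng.standard_normal((J, L)) @ ct.T).ravel()
        rowc = np.kron(np.linalg.cholesky(SE), np.linalg.cholesky(Gm))
        b2 = (rowc @ rng.standard_normal((I * J, L)) @ ct.T).ravel()
        c = rng.standard_normal((design.n_units, L)) @ np.linalg.cholesky(Sc).T
        return G.ModelState(
            beta_star=beta, b1=b1, b2=b2, c=c, omega=np.ones(design.n_obs),
            Sigma_t=St, Sigma_E=SE, Sigma_c=Sc, a_t=a_t, a_E=a_E, a_c=a_c,
        )

    def refresh_data(state):
        # NB data model implied by the augmented likelihood; eta clipped as
        # a numerical guard against astronomically rare overflow draws
        eta = np.clip(state.eta_star(design), -30, 30)
        p = 1.0 / (1.0 + np.exp(eta))
        y = rng.negative_binomial(r, p).astype(float)
        design.y = y
        design.ystar = (y - r) / 2.0
        state.omega = draw_pg(y + r, eta, rng, trunc=hyper.pg_trunc)

    def functionals(state):
        St, SE, Sc = state.Sigma_t, state.Sigma_E, state.Sigma_c
        y = design.y
        return np.array([
            state.beta_star[0], state.beta_star[3],
            np.mean(state.b1**2), np.mean(state.b2**2), np.mean(state.c**2),
            np.log(St[0, 0]), np.log(St[1, 1]),
            St[0, 1] / np.sqrt(St[0, 0] * St[1, 1]),
            np.log(SE[0, 0]), SE[0, 1] / np.sqrt(SE[0, 0] * SE[1, 1]),
            np.log(Sc[0, 0]), Sc[0, 1] / np.sqrt(Sc[0, 0] * Sc[1, 1]),
            np.log1p(y.mean()), np.log1p(y.max()),
            np.log(state.a_t[0]), np.log(state.a_c[0]),
        ])

    F1 = []
    for _ in range(n_marginal):
        st = draw_prior()
        refresh_data(st)
        F1.append(functionals(st))
    F1 = np.array(F1)

    st = draw_prior()
    refresh_data(st)
    F2 = []
    for it in range(n_successive + burn):
        refresh_data(st)
        st = G.gibbs_step(st, design, grm, hyper, rng)
        if it >= burn:
            F2.append(functionals(st))
    F2 = np.array(F2)

    zs = []
    for k in range(F1.shape[1]):
        q = np.median(F1[:, k])
        p1 = (F1[:, k] <= q).mean()
        p2 = (F2[:, k] <= q).mean()
        se1 = np.sqrt(p1 * (1 - p1) / n_marginal)
        se2 = batch_means_se((F2[:, k] <= q).astype(float))
        zs.append((p2 - p1) / np.hypot(se1, se2))
    return np.array(zs)
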