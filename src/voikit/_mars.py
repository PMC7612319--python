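"""Multivariate adaptive regression splines, used as an EVPPI/EVSI emulator.

Forward stagewise selection of hinge-function pairs max(0, +/-(x_v - t)),
optionally multiplied into existing terms up to interaction degree 2,
followed by backward pruning against generalized cross-validation:

    GCV(M) = RSS/R / (1 - C(M)/R)^2,   C(M) = m + penalty * (m - 1) / 2

with m the number of basis terms in model M. Candidate knots are taken at
marginal quantiles of each predictor. Candidate scoring uses incremental
Gram-matrix updates so the forward pass costs one small linear solve per
candidate rather than a full least-squares fit.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["MarsModel", "fit_mars"]

_RIDGE = 1e-9


@dataclass(frozen=True)
class _Hinge:
    var: int
    sign: int  # +1: max(0, x - knot); -1: max(0, knot - x)
    knot: float


def _term_values(x: np.ndarray, term: tuple[_Hinge, ...]) -> np.ndarray:
    v = np.ones(x.shape[0])
    for h in term:
        v = v * np.maximum(0.0, h.sign * (x[:, h.var] - h.knot))
    return v


@dataclass
class MarsModel:
    terms: list[tuple[_Hinge, ...]]  # () is the intercept
    coef: np.ndarray
    gcv: float

    def basis(self, x: np.ndarray) -> np.ndarray:
        return np.column_stack([_term_values(x, t) for t in self.terms])

    def predict(self, x: np.ndarray) -> np.ndarray:
        x = np.atleast_2d(np.asarray(x, dtype=float))
        return self.basis(x) @ self.coef


def _gcv(rss: float, r: int, m: int, penalty: float) -> float:
    c = m + penalty * (m - 1) / 2.0
    denom = max(1.0 - c / r, 1e-8)
    return (rss / r) / denom**2


def fit_mars(
    x: np.ndarray,
    y: np.ndarray,
    max_terms: int = 21,
    max_degree: int = 2,
    n_knots: int = 15,
    penalty: float | None = None,
) -> MarsModel:
    """Fit by forward selection then backward GCV pruning."""
    x = np.atleast_2d(np.asarray(x, dtype=float))
    y = np.asarray(y, dtype=float)
    r, p = x.shape
    if penalty is None:
        penalty = 3.0 if max_degree > 1 else 2.0

    # marginal quantile knots, interior only, deduplicated
    knots: list[np.ndarray] = []
    for v in range(p):
        qs = np.quantile(x[:, v], np.linspace(0.05, 0.95, n_knots))
        knots.append(np.unique(qs))

    terms: list[tuple[_Hinge, ...]] = [()]
    B = np.ones((r, 1))
    G = B.T @ B
    c = B.T @ y
    yty = float(y @ y)
    beta = np.linalg.solve(G + _RIDGE * np.eye(1), c)
    rss = yty - float(beta @ c)
    rss0 = max(rss, 1e-300)

    while len(terms) + 2 <= max_terms:
        best = None  # (rss_new, parent_idx, var, knot)
        for pi, parent in enumerate(terms):
            if len(parent) >= max_degree:
                continue
            parent_vars = {h.var for h in parent}
            pv = B[:, pi]
            for v in range(p):
                if v in parent_vars:
                    continue
                kn = knots[v]
                # hinge pairs for all knots at once: R x K each
                diff = x[:, v][:, None] - kn[None, :]
                hp = np.maximum(0.0, diff) * pv[:, None]
                hm = np.maximum(0.0, -diff) * pv[:, None]
                BtHp = B.T @ hp
                BtHm = B.T @ hm
                hp_y = hp.T @ y
                hm_y = hm.T @ y
                hp_sq = np.einsum("ij,ij->j", hp, hp)
                hm_sq = np.einsum("ij,ij->j", hm, hm)
                hphm = np.einsum("ij,ij->j", hp, hm)
                m = B.shape[1]
                for ki in range(kn.size):
                    U_gram = np.array(
                        [[hp_sq[ki], hphm[ki]], [hphm[ki], hm_sq[ki]]]
                    )
                    A = np.empty((m + 2, m + 2))
                    A[:m, :m] = G
                    A[:m, m:] = np.column_stack([BtHp[:, ki], BtHm[:, ki]])
                    A[m:, :m] = A[:m, m:].T
                    A[m:, m:] = U_gram
                    rhs = np.concatenate([c, [hp_y[ki], hm_y[ki]]])
                    A[np.diag_indices_from(A)] += _RIDGE * (1.0 + np.diag(A))
                    try:
                        b = np.linalg.solve(A, rhs)
                    except np.linalg.LinAlgError:
                        continue
                    rss_new = yty - float(b @ rhs)
                    if rss_new < -1e-6 * rss0:
                        continue  # numerically broken solve
                    if best is None or rss_new < best[0]:
                        best = (rss_new, pi, v, kn[ki])
        if best is None:
            break
        rss_new, pi, v, knot = best
        if rss - rss_new < 1e-8 * rss0:
            break
        parent = terms[pi]
        for sign in (+1, -1):
            term = parent + (_Hinge(v, sign, float(knot)),)
            col = _term_values(x, term)
            bc = B.T @ col
            G = np.block([[G, bc[:, None]],
                          [bc[None, :], np.array([[col @ col]])]])
            c = np.append(c, col @ y)
            B = np.column_stack([B, col])
            terms.append(term)
        rss = rss_new

    # backward pruning by GCV over nested deletions
    def _fit_subset(idx: list[int]) -> tuple[np.ndarray, float]:
        Gs = G[np.ix_(idx, idx)].copy()
        Gs[np.diag_indices_from(Gs)] += _RIDGE * (1.0 + np.diag(Gs))
        cs = c[idx]
        b = np.linalg.solve(Gs, cs)
        return b, max(yty - float(b @ cs), 0.0)

    active = list(range(len(terms)))
    b, rss_a = _fit_subset(active)
    best_state = (list(active), b, _gcv(rss_a, r, len(active), penalty))
    while len(active) > 1:
        best_del = None
        for j in active[1:]:  # never drop the intercept
            idx = [i for i in active if i != j]
            b_j, rss_j = _fit_subset(idx)
            g = _gcv(rss_j, r, len(idx), penalty)
            if best_del is None or g < best_del[2]:
                best_del = (idx, b_j, g)
        active = best_del[0]
        if best_del[2] < best_state[2]:
            best_state = best_del

    idx, b, g = best_state
    return MarsModel([terms[i] for i in idx], b, g)
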