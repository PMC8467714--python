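"""Genetic relatedness matrices for the combined F2 + advanced intercross analysis.

The centered GRM is G = W W' / p over column-centered genotypes.  Because
all F2 individuals of a cross are (effectively) full siblings, their block
of the GRM is overridden with the pedigree expectation (0.5 off-diagonal,
1 on the diagonal); the combined matrix is then adjusted to the nearest
positive definite matrix so the mixed model stays numerically stable, and
the adjustment is verified with a Mantel-style similarity between the pre-
and post-adjustment matrices.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .simulate import MISSING

__all__ = [
    "Grm",
    "centered_grm",
    "override_f2_block",
    "near_pd",
    "mantel_similarity",
]


@dataclass(frozen=True)
class Grm:
    """Square symmetric relatedness matrix with provenance flags."""

    values: np.ndarray
    ids: tuple[str, ...]
    provenance: tuple[str, ...] = ("raw",)

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("GRM must be square")
        if v.shape[0] != len(self.ids):
            raise ValueError("GRM size does not match ids")
        if not np.allclose(v, v.T, atol=1e-9):
            raise ValueError("GRM must be symmetric")
        object.__setattr__(self, "values", v)
        object.__setattr__(self, "ids", tuple(self.ids))

    @property
    def n(self) -> int:
        return self.values.shape[0]

    def min_eigenvalue(self) -> float:
        return float(np.linalg.eigvalsh(self.values)[0])


def centered_grm(genotypes: np.ndarray, ids) -> Grm:
    """Centered GRM, G = W W' / p, from a genotype matrix.

    Missing genotypes are mean-imputed per marker (for GRM construction
    only).  Markers with zero variance after imputation contribute nothing;
    if every marker is constant the matrix is undefined and rejected.
    """
    X = np.asarray(genotypes, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2 or X.shape[1] < 1:
        raise ValueError("need >= 2 individuals and >= 1 marker")
    W = X.copy()
    miss = X == MISSING
    if miss.any():
        obs_counts = (~miss).sum(axis=0)
        if (obs_counts == 0).any():
            raise ValueError("marker with no observed genotypes")
        col_means = np.where(miss, 0.0, X).sum(axis=0) / obs_counts
        W[miss] = np.broadcast_to(col_means, X.shape)[miss]
    W = W - W.mean(axis=0, keepdims=True)
    if not (W.std(axis=0) > 0).any():
        raise ValueError("all markers have zero variance; GRM undefined")
    G = (W @ W.T) / X.shape[1]
    return Grm(values=G, ids=tuple(ids), provenance=("raw",))


def override_f2_block(grm: Grm, f2_ids) -> Grm:
    """Replace the F2-F2 block with pedigree expectations.

    Off-diagonal F2-F2 entries become 0.5 and F2 diagonal entries 1;
    entries involving a non-F2 individual are untouched.
    """
    idx_map = {ind: i for i, ind in enumerate(grm.ids)}
    try:
        idx = np.array([idx_map[i] for i in f2_ids], dtype=int)
    except KeyError as exc:
        raise ValueError(f"unknown individual id {exc.args[0]!r}") from None
    V = grm.values.copy()
    V[np.ix_(idx, idx)] = 0.5
    V[idx, idx] = 1.0
    return Grm(values=V, ids=grm.ids,
               provenance=grm.provenance + ("f2-overridden",))


def near_pd(grm: Grm | np.ndarray, eig_floor: float = 1e-8) -> Grm:
    """Nearest positive definite matrix (Frobenius norm, no diagonal constraint).

    Without a diagonal constraint the alternating-projection scheme
    converges in one step to the eigenvalue-clipped matrix, so the result
    is the symmetric eigendecomposition with negative eigenvalues raised to
    ``eig_floor`` (a strictly positive floor keeps downstream Cholesky
    factorizations stable).  Already-PD input is returned unchanged.
    """
    if isinstance(grm, Grm):
        V, ids, prov = grm.values, grm.ids, grm.provenance
    else:
        V = np.asarray(grm, dtype=float)
        ids = tuple(str(i) for i in range(V.shape[0]))
        prov = ("raw",)
    if not np.allclose(V, V.T, atol=1e-8):
        raise ValueError("input must be symmetric")
    V = 0.5 * (V + V.T)
    w, U = np.linalg.eigh(V)
    if w[0] >= eig_floor:
        return Grm(values=V, ids=ids, provenance=prov + ("pd-adjusted",))
    w_clipped = np.maximum(w, eig_floor)
    out = (U * w_clipped) @ U.T
    out = 0.5 * (out + out.T)
    return Grm(values=out, ids=ids, provenance=prov + ("pd-adjusted",))


def mantel_similarity(m1: Grm | np.ndarray, m2: Grm | np.ndarray,
                      n_perm: int = 0, seed: int | None = None
                      ) -> tuple[float, float | None]:
    """Similarity between two relatedness matrices.

    Pearson correlation of the lower-triangle off-diagonal entries; with
    ``n_perm > 0`` a one-sided permutation p-value from simultaneous
    row/column shuffles of the second matrix.  Returns ``(r, p)`` with
    ``p = None`` when no permutations are requested.
    """
    A = m1.values if isinstance(m1, Grm) else np.asarray(m1, dtype=float)
    B = m2.values if isinstance(m2, Grm) else np.asarray(m2, dtype=float)
    if A.shape != B.shape or A.ndim != 2 or A.shape[0] != A.shape[1]:
        raise ValueError("matrices must be square and of equal shape")
    n = A.shape[0]
    if n < 3:
        raise ValueError("need at least 3 individuals")
    il = np.tril_indices(n, k=-1)
    a, b = A[il], B[il]
    if a.std() == 0 or b.std() == 0:
        raise ValueError("constant matrix: correlation undefined")
    r = float(np.corrcoef(a, b)[0, 1])
    if n_perm <= 0:
        return r, None
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        bp = B[np.ix_(perm, perm)][il]
        if np.corrcoef(a, bp)[0, 1] >= r:
            count += 1
    return r, (count + 1) / (n_perm + 1)
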