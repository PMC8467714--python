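"""Independent brute-force oracles shared by the test modules."""

import itertools

import numpy as np

from crossepi.impute import F2_PRIOR, HmmParams, transition_matrix
from crossepi.simulate import haldane_recomb


def brute_force_effects(P: np.ndarray) -> np.ndarray:
    """Unweighted least-squares main-effects residual of a 3x3 table."""
    rows = []
    for i in range(3):
        for j in range(3):
            r = [1.0, 0, 0, 0, 0]
            if i < 2:
                r[1 + i] = 1.0
            else:
                r[1] = r[2] = -1.0
            if j < 2:
                r[3 + j] = 1.0
            else:
                r[3] = r[4] = -1.0
            rows.append(r)
    A = np.array(rows)
    coef = np.linalg.lstsq(A, P.ravel(), rcond=None)[0]
    return (P.ravel() - A @ coef).reshape(3, 3)


def brute_force_posteriors(obs, cm, expansion, eps):
    """Posterior genotype marginals by full hidden-path enumeration."""
    m = len(cm)
    trans = [transition_matrix(haldane_recomb(d * expansion))
             for d in np.diff(cm)]
    emis = HmmParams(eps).emission_matrix()
    post = np.zeros((m, 3))
    total = 0.0
    for path in itertools.product(range(3), repeat=m):
        p = F2_PRIOR[path[0]]
        for k in range(1, m):
            p *= trans[k - 1][path[k - 1], path[k]]
        for k in range(m):
            if obs[k] >= 0:
                p *= emis[path[k], obs[k]]
        total += p
        for k in range(m):
            post[k, path[k]] += p
    return post / total
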