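"""Three-state HMM genotype imputation along a chromosome.

Hidden states are the genotype codes {0, 1, 2} counting non-reference
strain alleles.  In an F2 the stationary distribution is (1/4, 1/2, 1/4)
and the two gametes recombine independently between adjacent positions, so
the genotype transition matrix over an interval with recombination
fraction r (Haldane, from the cM distance) is

        [ q^2   2qr      r^2 ]
    T = [ qr    q^2+r^2  qr  ]   with q = 1 - r.
        [ r^2   2qr      q^2 ]

Advanced-intercross generations accumulate recombination; generation t is
modeled by scaling cM distances by the expected map expansion t/2 before
applying the Haldane function, and each generation is imputed with its own
expansion factor.  Observations are correct with probability 1 - e and
each wrong state with probability e/2.  Posteriors at typed-but-missing or
entirely untyped positions come from exact forward-backward smoothing.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .simulate import MISSING, MarkerMap, haldane_recomb

__all__ = [
    "HmmParams",
    "ImputationResult",
    "map_expansion",
    "transition_matrix",
    "forward_backward",
    "impute_individual",
    "impute_cohort_chromosome",
    "confidence_summary",
]

F2_PRIOR = np.array([0.25, 0.5, 0.25])


def map_expansion(generation: str) -> float:
    """Expected genetic-map expansion of an intercross generation.

    F2 -> 1; generation t of random mating -> t/2 (the standard expected
    expansion for advanced intercross lines).
    """
    if not generation.startswith("F"):
        raise ValueError(f"unknown generation label {generation!r}")
    t = int(generation[1:])
    if t < 2:
        raise ValueError("generation must be F2 or later")
    return max(1.0, t / 2.0)


@dataclass(frozen=True)
class HmmParams:
    """Genotyping error rate and per-generation map expansion."""

    error_rate: float = 0.005

    def __post_init__(self):
        if not 0.0 <= self.error_rate <= 0.1:
            raise ValueError("error rate must be in [0, 0.1]")

    def emission_matrix(self) -> np.ndarray:
        e = self.error_rate
        return np.full((3, 3), e / 2.0) + np.eye(3) * (1.0 - 1.5 * e)


def transition_matrix(r: float) -> np.ndarray:
    """Genotype transition matrix from the two-gamete recombination model."""
    q = 1.0 - r
    return np.array([
        [q * q, 2 * q * r, r * r],
        [q * r, q * q + r * r, q * r],
        [r * r, 2 * q * r, q * q],
    ])


def _emissions(obs: np.ndarray, error_rate: float) -> np.ndarray:
    """Per-individual emission likelihoods, (n, m, 3); missing rows are 1."""
    n, m = obs.shape
    e = np.ones((n, m, 3))
    emis = HmmParams(error_rate).emission_matrix()
    observed = obs != MISSING
    e[observed] = emis[obs[observed]]
    return e


def forward_backward(obs: np.ndarray, cm: np.ndarray, expansion: float = 1.0,
                     error_rate: float = 0.005,
                     allow_unobserved: bool = False) -> np.ndarray:
    """Exact smoothed posteriors over hidden genotypes for one chromosome.

    ``obs`` is (n_individuals, m) with -1 for missing; ``cm`` the marker
    positions in F2 cM, strictly increasing.  Returns (n, m, 3) posterior
    probabilities.  Every individual must have at least one observed
    marker unless ``allow_unobserved`` is set, in which case fully
    unobserved individuals get the stationary prior everywhere.
    """
    obs = np.atleast_2d(np.asarray(obs))
    cm = np.asarray(cm, dtype=float)
    if obs.shape[1] != len(cm):
        raise ValueError("observation width does not match positions")
    if len(cm) == 0:
        raise ValueError("empty chromosome")
    if np.any(np.diff(cm) <= 0):
        raise ValueError("positions must be strictly increasing")
    if not (obs != MISSING).any(axis=1).all():
        if not allow_unobserved:
            raise ValueError("each individual needs at least one observed marker")
        # posteriors of unobserved rows reduce to the prior anyway; the
        # explicit check only guards accidental all-missing input

    n, m = obs.shape
    e = _emissions(obs, error_rate)
    trans = [transition_matrix(haldane_recomb(d * expansion))
             for d in np.diff(cm)]

    alpha = np.empty((n, m, 3))
    a = F2_PRIOR * e[:, 0]
    a /= a.sum(axis=1, keepdims=True)
    alpha[:, 0] = a
    for k in range(1, m):
        a = (a @ trans[k - 1]) * e[:, k]
        a /= a.sum(axis=1, keepdims=True)
        alpha[:, k] = a

    beta = np.empty((n, m, 3))
    b = np.ones((n, 3))
    beta[:, -1] = b
    for k in range(m - 2, -1, -1):
        b = (b * e[:, k + 1]) @ trans[k].T
        b /= b.sum(axis=1, keepdims=True)
        beta[:, k] = b

    post = alpha * beta
    post /= post.sum(axis=2, keepdims=True)
    return post


@dataclass
class ImputationResult:
    """Posterior genotypes at target positions for a set of individuals."""

    cm: np.ndarray          # (k,) target positions (F2 cM)
    posteriors: np.ndarray  # (n, k, 3)
    calls: np.ndarray = field(init=False)
    confidence: np.ndarray = field(init=False)

    def __post_init__(self):
        sums = self.posteriors.sum(axis=2)
        if not np.allclose(sums, 1.0, atol=1e-9):
            raise ValueError("posteriors must sum to 1")
        self.calls = self.posteriors.argmax(axis=2).astype(np.int8)
        self.confidence = self.posteriors.max(axis=2)


def impute_cohort_chromosome(obs: np.ndarray, cm: np.ndarray, generation: str,
                             params: HmmParams = HmmParams(),
                             target_cm: np.ndarray | None = None,
                             allow_unobserved: bool = False
                             ) -> ImputationResult:
    """Impute one chromosome for many individuals of one generation.

    ``target_cm`` adds untyped positions (must lie within the typed map's
    span); by default the targets are the typed positions themselves.
    Positions are merged into one chain and smoothed jointly, so the
    posteriors at targets are exact.
    """
    obs = np.atleast_2d(np.asarray(obs))
    cm = np.asarray(cm, dtype=float)
    expansion = map_expansion(generation)
    if target_cm is None:
        post = forward_backward(obs, cm, expansion, params.error_rate,
                                allow_unobserved=allow_unobserved)
        return ImputationResult(cm=cm, posteriors=post)

    target_cm = np.asarray(target_cm, dtype=float)
    if target_cm.size and (target_cm.min() < cm.min() or target_cm.max() > cm.max()):
        raise ValueError("target positions fall outside the typed map span")
    extra = np.setdiff1d(target_cm, cm)
    full = np.concatenate([cm, extra])
    order = np.argsort(full)
    full = full[order]
    obs_full = np.concatenate(
        [obs, np.full((obs.shape[0], len(extra)), MISSING, dtype=obs.dtype)], axis=1)
    obs_full = obs_full[:, order]
    post = forward_backward(obs_full, full, expansion, params.error_rate,
                            allow_unobserved=allow_unobserved)
    sel = np.searchsorted(full, target_cm)
    return ImputationResult(cm=target_cm, posteriors=post[:, sel])


def impute_individual(observed: np.ndarray, marker_map: MarkerMap, chrom: int,
                      generation: str, params: HmmParams = HmmParams(),
                      target_cm: np.ndarray | None = None) -> ImputationResult:
    """Impute a single individual's genotypes on one chromosome.

    ``observed`` is the genotype vector over that chromosome's markers in
    map order (missing = -1).
    """
    sl = marker_map.chromosome_slices().get(chrom)
    if sl is None:
        raise ValueError(f"chromosome {chrom} not on the map")
    cm = marker_map.cm[sl]
    observed = np.asarray(observed)
    if observed.ndim != 1 or len(observed) != len(cm):
        raise ValueError("observed vector does not match the chromosome's markers")
    return impute_cohort_chromosome(observed[None, :], cm, generation, params,
                                    target_cm=target_cm)


def confidence_summary(confidence: np.ndarray, thresholds=(0.70, 0.50),
                       calls: np.ndarray | None = None,
                       truth: np.ndarray | None = None) -> dict:
    """Fractions of imputed calls above/below confidence thresholds.

    Optionally scores call accuracy against known truth (e.g. from a mask
    index).  Fractions use strict inequalities, matching "above 0.70" /
    "below 0.50" style statements.
    """
    conf = np.asarray(confidence, dtype=float).ravel()
    if conf.size == 0:
        raise ValueError("no posteriors to summarize")
    out: dict = {"n": int(conf.size)}
    for thr in thresholds:
        out[f"fraction_above_{thr:g}"] = float((conf > thr).mean())
        out[f"fraction_below_{thr:g}"] = float((conf < thr).mean())
    if calls is not None and truth is not None:
        calls = np.asarray(calls).ravel()
        truth = np.asarray(truth).ravel()
        if calls.shape != conf.shape or truth.shape != conf.shape:
            raise ValueError("calls/truth must match confidence shape")
        out["accuracy"] = float((calls == truth).mean())
    return out
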