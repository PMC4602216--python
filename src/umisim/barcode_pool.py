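"""Barcode pools, molecule labelling and barcode-clash statistics.

A barcode (unique molecular identifier, UMI) is a short random nucleotide
sequence attached to a template molecule before amplification.  This module
generates pools of available barcodes (uniform or non-uniform), labels
molecules by sampling from the pool *with replacement* — so two molecules may
receive the same barcode ("barcode clash") — and provides both exact
birthday-problem analytics and simulation-based summaries of clash.

The inverse problem is also covered: given the histogram of
barcode-labelling events (how many times each barcode was seen to label a
molecule, over one or more experiments), a zero-truncated mixed-Poisson
maximum-likelihood fit recovers the structure of the pool — what fraction of
barcodes is drawn at which relative propensity.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.optimize import minimize
from scipy.special import gammaln, logsumexp

__all__ = [
    "BarcodePool",
    "Labelling",
    "ClashSummary",
    "MixedPoissonFit",
    "PoolStructure",
    "pool_size",
    "make_pool",
    "label_molecules",
    "prob_no_clash",
    "prob_no_clash_approx",
    "expected_unique_fraction",
    "clash_summary",
    "zt_mixed_poisson_pmf",
    "fit_zt_mixed_poisson",
    "infer_pool_structure",
]

_BASES = np.array(list("ACGT"))


def pool_size(length: int) -> int:
    """Number of distinct nucleotide barcodes of the given length (4**L)."""
    if length < 1:
        raise ValueError(f"barcode length must be >= 1, got {length}")
    return 4**length


@dataclass(frozen=True)
class BarcodePool:
    """A distribution over nucleotide barcodes of fixed length.

    Parameters
    ----------
    length
        Barcode length L in nucleotides.
    size
        Number N of distinct barcodes available (N <= 4**L).
    weights
        Probability of drawing each barcode.  ``None`` means uniform
        (1/N each) and avoids materialising a length-N vector, which
        matters when N is 4**12 ~ 1.7e7.
    spec
        The distribution descriptor the pool was built from.
    """

    length: int
    size: int
    weights: np.ndarray | None = None
    spec: dict = field(default_factory=lambda: {"kind": "uniform"})

    def __post_init__(self) -> None:
        if self.length < 1:
            raise ValueError("barcode length must be >= 1")
        if not 1 <= self.size <= pool_size(self.length):
            raise ValueError(
                f"pool size {self.size} outside [1, 4^{self.length}]"
            )
        if self.weights is not None:
            w = np.asarray(self.weights, dtype=float)
            if w.shape != (self.size,):
                raise ValueError("weights length must equal pool size")
            if np.any(w < 0):
                raise ValueError("weights must be non-negative")
            if abs(w.sum() - 1.0) > 1e-9:
                raise ValueError("weights must sum to 1 within 1e-9")
            object.__setattr__(self, "weights", w)

    def barcode_string(self, barcode_id: int) -> str:
        """Nucleotide sequence of a barcode id (base-4 expansion to ACGT).

        Strings are materialised lazily: ids are the canonical
        representation, so 4**12 strings never need to exist at once.
        """
        if not 0 <= barcode_id < pool_size(self.length):
            raise ValueError(f"barcode id {barcode_id} out of range")
        digits = np.empty(self.length, dtype=np.int64)
        x = barcode_id
        for pos in range(self.length - 1, -1, -1):
            digits[pos] = x & 3
            x >>= 2
        return "".join(_BASES[digits])


def make_pool(
    spec: Mapping | str,
    length: int,
    size: int | None = None,
    seed: int | None = None,
) -> BarcodePool:
    """Build a barcode pool from a distribution descriptor.

    ``spec`` is either the string ``"uniform"`` or a mapping with a
    ``kind`` key:

    - ``{"kind": "uniform"}``
    - ``{"kind": "normal", "mean": m, "sd": s}`` — one Normal(m, s) variate
      per barcode, rejection-sampled to be strictly positive, then
      normalised.  Rejection (not clipping) avoids an atom at zero.
    - ``{"kind": "lognormal", "mean": m, "sigma": s}`` — log-normal weight
      per barcode, normalised.
    - ``{"kind": "empirical-mixture", "fractions": [...],
      "propensities": [...]}`` — the pool splits into classes; a class
      holding fraction f_j of barcodes draws each of them with weight
      proportional to propensity p_j.  This is the descriptor produced by
      :func:`infer_pool_structure`, closing the loop from observed
      labelling events back to a simulable pool.

    Same seed and spec give a bit-identical pool.
    """
    if isinstance(spec, str):
        spec = {"kind": spec}
    kind = spec.get("kind")
    if size is None:
        size = pool_size(length)
    rng = np.random.default_rng(seed)

    if kind == "uniform":
        return BarcodePool(length, size, None, {"kind": "uniform"})

    if kind == "normal":
        try:
            mean, sd = float(spec["mean"]), float(spec["sd"])
        except KeyError as exc:
            raise ValueError(f"normal pool spec missing {exc}") from exc
        if not (math.isfinite(mean) and math.isfinite(sd) and sd >= 0):
            raise ValueError("normal pool parameters must be finite, sd >= 0")
        w = _positive_normal(rng, mean, sd, size)
    elif kind == "lognormal":
        mean = float(spec.get("mean", 0.0))
        sigma = float(spec.get("sigma", 1.0))
        if not (math.isfinite(mean) and math.isfinite(sigma) and sigma >= 0):
            raise ValueError("lognormal pool parameters must be finite")
        w = rng.lognormal(mean, sigma, size)
    elif kind == "empirical-mixture":
        fractions = np.asarray(spec["fractions"], dtype=float)
        propens = np.asarray(spec["propensities"], dtype=float)
        if fractions.shape != propens.shape or fractions.ndim != 1:
            raise ValueError("fractions and propensities must align")
        if np.any(fractions < 0) or abs(fractions.sum() - 1.0) > 1e-9:
            raise ValueError("mixture fractions must be a probability vector")
        if np.any(propens <= 0):
            raise ValueError("mixture propensities must be positive")
        # deterministic class sizes: largest-remainder apportionment of N
        counts = _apportion(fractions, size)
        w = np.repeat(propens, counts).astype(float)
    else:
        raise ValueError(f"unknown pool spec kind: {kind!r}")

    w = w / w.sum()
    return BarcodePool(length, size, w, dict(spec))


def _positive_normal(
    rng: np.random.Generator, mean: float, sd: float, size: int
) -> np.ndarray:
    """Normal(mean, sd) variates rejection-sampled to be > 0."""
    if sd == 0:
        if mean <= 0:
            raise ValueError("degenerate normal spec with mean <= 0")
        return np.full(size, mean)
    out = np.empty(size)
    filled = 0
    while filled < size:
        draw = rng.normal(mean, sd, size - filled)
        draw = draw[draw > 0]
        out[filled : filled + draw.size] = draw
        filled += draw.size
    return out


def _apportion(fractions: np.ndarray, total: int) -> np.ndarray:
    """Integer class sizes summing to ``total``, proportional to fractions."""
    raw = fractions * total
    counts = np.floor(raw).astype(np.int64)
    short = total - counts.sum()
    if short:
        order = np.argsort(-(raw - counts))
        counts[order[:short]] += 1
    return counts


@dataclass(frozen=True)
class Labelling:
    """Outcome of attaching barcodes to ``n`` molecules.

    ``assignments[i]`` is the barcode id drawn by molecule i.
    ``barcode_ids``/``multiplicities`` tabulate, for every barcode that was
    used at least once, how many molecules carry it (the barcode-labelling
    events).  Barcodes never drawn do not appear.
    """

    n: int
    assignments: np.ndarray
    barcode_ids: np.ndarray
    multiplicities: np.ndarray

    def __post_init__(self) -> None:
        if self.n != len(self.assignments):
            raise ValueError("n must equal len(assignments)")
        if int(self.multiplicities.sum()) != self.n:
            raise ValueError("multiplicities must sum to n")

    def multiplicity_of(self) -> np.ndarray:
        """Per-molecule multiplicity of the barcode each molecule carries."""
        order = np.argsort(self.barcode_ids)
        idx = np.searchsorted(self.barcode_ids[order], self.assignments)
        return self.multiplicities[order][idx]


def label_molecules(
    pool: BarcodePool, n: int, seed: int | None = None
) -> Labelling:
    """Label ``n`` molecules by drawing barcodes from the pool with replacement.

    Clash is an outcome, never prevented: two molecules drawing the same
    barcode end up indistinguishable downstream.
    """
    if n < 1:
        raise ValueError("need at least one molecule to label")
    rng = np.random.default_rng(seed)
    if pool.weights is None:
        assignments = rng.integers(0, pool.size, size=n)
    else:
        assignments = rng.choice(pool.size, size=n, p=pool.weights)
    ids, mult = np.unique(assignments, return_counts=True)
    return Labelling(n, assignments, ids, mult)


def prob_no_clash(n: int, pool_n: int) -> float:
    """Exact probability that no two of ``n`` molecules share a barcode.

    Assumes a uniform pool of ``pool_n`` barcodes: the birthday problem,
    prod_{i=0}^{n-1} (1 - i/N), computed in log space.  Zero whenever
    n > N (pigeonhole).
    """
    if n < 1 or pool_n < 1:
        raise ValueError("n and pool size must be >= 1")
    if n > pool_n:
        return 0.0
    if n == 1:
        return 1.0
    i = np.arange(1, n, dtype=float)
    return float(np.exp(np.log1p(-i / pool_n).sum()))


def prob_no_clash_approx(n: int, pool_n: int) -> float:
    """Birthday-problem approximation exp(-n(n-1)/(2N)).

    Flagged as an approximation: prefer :func:`prob_no_clash` (exact)
    unless n is astronomically large.
    """
    if n < 1 or pool_n < 1:
        raise ValueError("n and pool size must be >= 1")
    return float(np.exp(-n * (n - 1) / (2.0 * pool_n)))


def expected_unique_fraction(n: int, pool_n: int) -> float:
    """Probability a given molecule's barcode is drawn by no other molecule.

    Uniform pool: ((N-1)/N)**(n-1).  By linearity this is also the expected
    fraction of the n molecules that are uniquely barcoded.
    """
    if n < 1 or pool_n < 1:
        raise ValueError("n and pool size must be >= 1")
    return float(np.exp((n - 1) * np.log1p(-1.0 / pool_n)))


@dataclass(frozen=True)
class ClashSummary:
    """Clash outcome of one labelling: unique fraction, worst clash, histogram."""

    unique_fraction: float
    max_clash: int
    multiplicity_histogram: dict[int, int]


def clash_summary(labelling: Labelling) -> ClashSummary:
    """Summarise barcode clash in a labelling.

    ``unique_fraction`` is the share of *molecules* whose barcode has
    multiplicity 1; ``max_clash`` the largest number of molecules sharing
    one barcode; the histogram maps multiplicity -> number of barcodes.
    """
    if labelling.n < 1:
        raise ValueError("empty labelling")
    mult = labelling.multiplicities
    unique = int(mult[mult == 1].sum())  # == number of multiplicity-1 barcodes
    sizes, counts = np.unique(mult, return_counts=True)
    return ClashSummary(
        unique_fraction=unique / labelling.n,
        max_clash=int(mult.max()),
        multiplicity_histogram=dict(
            zip((int(s) for s in sizes), (int(c) for c in counts))
        ),
    )


# ---------------------------------------------------------------------------
# Zero-truncated mixed-Poisson fitting of labelling-event histograms
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class MixedPoissonFit:
    """Maximum-likelihood zero-truncated K-component Poisson mixture.

    The model for the number of labelling events k >= 1 per observed barcode:

        P(k) = [ sum_j w_j Pois(k; lambda_j) ] / [ 1 - sum_j w_j e^{-lambda_j} ]

    where w_j are the fractions of the *whole* pool (including never-drawn
    barcodes) in each component and lambda_j the per-barcode event rates.
    """

    K: int
    weights: np.ndarray
    rates: np.ndarray
    loglik: float
    aic: float
    converged: bool
    n_events: int
    n_barcodes: int

    def pmf(self, k) -> np.ndarray:
        return zt_mixed_poisson_pmf(k, self.weights, self.rates)


def zt_mixed_poisson_pmf(k, weights, rates) -> np.ndarray:
    """Zero-truncated mixed-Poisson pmf at integer k (0 for k < 1)."""
    k = np.atleast_1d(np.asarray(k, dtype=float))
    w = np.asarray(weights, dtype=float)
    lam = np.asarray(rates, dtype=float)
    if np.any(lam <= 0):
        raise ValueError("rates must be positive")
    # components along axis 1
    logpois = (
        k[:, None] * np.log(lam)[None, :]
        - lam[None, :]
        - gammaln(k[:, None] + 1.0)
    )
    num = np.exp(logsumexp(logpois, axis=1, b=w[None, :]))
    denom = 1.0 - float(np.dot(w, np.exp(-lam)))
    out = num / denom
    out[k < 1] = 0.0
    return out


def _zt_mixture_negloglik(theta: np.ndarray, K: int, ks, counts) -> float:
    lam = np.exp(theta[:K])
    logits = np.concatenate([theta[K:], [0.0]])
    logw = logits - logsumexp(logits)
    w = np.exp(logw)
    logpois = (
        ks[:, None] * np.log(lam)[None, :]
        - lam[None, :]
        - gammaln(ks[:, None] + 1.0)
    )
    lognum = logsumexp(logpois + logw[None, :], axis=1)
    denom = 1.0 - float(np.dot(w, np.exp(-lam)))
    if denom <= 0:
        return np.inf
    return -(float(np.dot(counts, lognum)) - counts.sum() * math.log(denom))


def fit_zt_mixed_poisson(
    event_counts: Mapping[int, int],
    K: int = 1,
    *,
    select_k: bool = False,
    n_restarts: int = 10,
    seed: int | None = 0,
    tol: float = 1e-8,
) -> MixedPoissonFit:
    """Fit a zero-truncated K-component Poisson mixture to an event histogram.

    Parameters
    ----------
    event_counts
        Histogram mapping number of labelling events k (>= 1) to the number
        of barcodes observed with exactly k events.
    K
        Number of mixture components (or K_max when ``select_k``).
    select_k
        When true, fit K = 1..K and return the fit with the lowest AIC.
    n_restarts
        Random restarts of the optimiser; the likelihood surface is
        multimodal for K >= 2.
    seed
        Seed for restart initialisation (deterministic fitting).

    The optimisation runs over an unconstrained reparameterisation
    (log rates, softmax weights).  A fit where no restart converged is
    returned with ``converged=False`` rather than raising.
    """
    ks = np.asarray(sorted(event_counts), dtype=float)
    counts = np.asarray([event_counts[int(k)] for k in ks], dtype=float)
    if ks.size == 0 or np.any(ks < 1):
        raise ValueError("event histogram must be non-empty with all k >= 1")
    if K < 1:
        raise ValueError("K must be >= 1")

    if select_k:
        fits = [
            fit_zt_mixed_poisson(
                event_counts, kk, n_restarts=n_restarts, seed=seed, tol=tol
            )
            for kk in range(1, K + 1)
        ]
        return min(fits, key=lambda f: f.aic)

    rng = np.random.default_rng(seed)
    n_barcodes = counts.sum()
    mean_k = float(np.dot(ks, counts) / n_barcodes)

    best = None
    best_nll = np.inf
    any_converged = False
    for r in range(n_restarts):
        if r == 0:
            # deterministic start: rates spread geometrically around the mean
            lam0 = mean_k * np.geomspace(0.5, 2.0, K)
            w0 = np.zeros(max(K - 1, 0))
        else:
            lam0 = mean_k * rng.lognormal(0.0, 1.0, K)
            w0 = rng.normal(0.0, 1.0, max(K - 1, 0))
        theta0 = np.concatenate([np.log(np.maximum(lam0, 1e-6)), w0])
        res = minimize(
            _zt_mixture_negloglik,
            theta0,
            args=(K, ks, counts),
            method="Nelder-Mead",
            options={"xatol": tol, "fatol": tol, "maxiter": 20000},
        )
        if res.fun < best_nll:
            best_nll = res.fun
            best = res
        any_converged = any_converged or bool(res.success)

    theta = best.x
    lam = np.exp(theta[:K])
    logits = np.concatenate([theta[K:], [0.0]])
    w = np.exp(logits - logsumexp(logits))
    order = np.argsort(lam)
    lam, w = lam[order], w[order]
    loglik = -best_nll
    n_params = 2 * K - 1
    return MixedPoissonFit(
        K=K,
        weights=w,
        rates=lam,
        loglik=loglik,
        aic=2 * n_params - 2 * loglik,
        converged=any_converged and np.isfinite(loglik),
        n_events=int(np.dot(ks, counts)),
        n_barcodes=int(n_barcodes),
    )


@dataclass(frozen=True)
class PoolStructure:
    """Inferred pool composition: per-class fraction and labelling propensity."""

    fractions: np.ndarray
    propensities: np.ndarray

    def as_pool_spec(self) -> dict:
        """Distribution descriptor consumable by :func:`make_pool`."""
        return {
            "kind": "empirical-mixture",
            "fractions": list(map(float, self.fractions)),
            "propensities": list(map(float, self.propensities)),
        }


def infer_pool_structure(fit: MixedPoissonFit) -> PoolStructure:
    """Map a mixture fit back to the structure of the barcode pool.

    In the zero-truncated mixture, component weight w_j is the fraction of
    the pool in class j and rate lambda_j its per-barcode labelling-event
    rate, so the relative labelling propensity of a class-j barcode is
    proportional to lambda_j.  Propensities are normalised to sum to 1.
    """
    prop = fit.rates / fit.rates.sum()
    return PoolStructure(fractions=fit.weights.copy(), propensities=prop)
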