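"""Family-size distributions and the statistics built on them.

The central observable of a barcoded amplification experiment is the
barcode family size: the number of sequencer reads descending from one
initial template molecule.  Under uniform amplification plus random
subsampling its law is a zero-truncated Poisson (ZTP); heterogeneity in
amplification shows up as over-dispersion relative to the best-fitting ZTP.
This module computes the distribution from simulated reads, fits the ZTP by
maximum likelihood, tests the fit by chi-squared, and provides the
coefficient of variation and rank-agreement summaries used to compare runs.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, NamedTuple, Sequence

import numpy as np
from Bio.SeqUtils import gc_fraction as _bio_gc_fraction
from scipy.optimize import brentq, minimize_scalar
from scipy.special import gammaln
from scipy.stats import chi2 as chi2_dist
from scipy.stats import linregress, rankdata

from umisim.barcode_pool import Labelling
from umisim.sample_seq import ReadSet, SampledMolecules, ztp_pmf

__all__ = [
    "FamilySizeDistribution",
    "ZTPFit",
    "GofResult",
    "RunComparison",
    "family_size_distribution",
    "coefficient_of_variation",
    "fit_ztp_mle",
    "ztp_mle_moment",
    "chi_squared_gof",
    "compare_runs",
    "gc_fraction",
]


@dataclass(frozen=True)
class FamilySizeDistribution:
    """Histogram mapping family size k >= 1 to the number of families."""

    counts: dict[int, int]

    def __post_init__(self) -> None:
        if not self.counts:
            raise ValueError("empty family-size distribution")
        if any(k < 1 or c < 0 for k, c in self.counts.items()):
            raise ValueError("family sizes must be >= 1, counts >= 0")

    @property
    def n_families(self) -> int:
        return int(sum(self.counts.values()))

    @property
    def n_reads(self) -> int:
        return int(sum(k * c for k, c in self.counts.items()))

    @property
    def mean(self) -> float:
        return self.n_reads / self.n_families

    def sizes(self) -> np.ndarray:
        """Expand back to one family size per family."""
        ks = np.asarray(sorted(self.counts), dtype=np.int64)
        reps = np.asarray([self.counts[int(k)] for k in ks], dtype=np.int64)
        return np.repeat(ks, reps)

    @classmethod
    def from_sizes(cls, sizes: Sequence[int]) -> "FamilySizeDistribution":
        ks, cs = np.unique(np.asarray(sizes, dtype=np.int64), return_counts=True)
        return cls(dict(zip((int(k) for k in ks), (int(c) for c in cs))))


def family_size_distribution(
    source,
    group_by: str = "lineage",
    barcode_length: int | None = None,
) -> FamilySizeDistribution:
    """Per-group read counts; groups with zero reads are structurally absent.

    ``source`` may be a :class:`~umisim.sample_seq.ReadSet`, a
    :class:`~umisim.sample_seq.SampledMolecules`, a
    :class:`~umisim.barcode_pool.Labelling` (family = molecules per
    barcode) or a plain sequence of per-read group labels.

    ``group_by="lineage"`` groups by simulation ground truth.
    ``group_by="barcode"`` groups by what an experimenter sees: for reads,
    the observed barcode — the first ``barcode_length`` bases including any
    accumulated errors when given, else the assigned barcode id — so clash
    merges families and barcode-position errors split them.
    """
    if group_by not in ("lineage", "barcode"):
        raise ValueError("group_by must be 'lineage' or 'barcode'")
    if isinstance(source, ReadSet):
        if group_by == "lineage":
            labels = source.lineage_ids()
        elif barcode_length is not None:
            labels = np.asarray([r.sequence[:barcode_length] for r in source.reads])
        else:
            labels = source.barcode_ids()
    elif isinstance(source, SampledMolecules):
        if group_by == "lineage":
            return FamilySizeDistribution.from_sizes(
                source.observed_family_sizes()
            )
        bids = np.asarray(
            [lin.barcode_id for lin in source.pool.lineages], dtype=np.int64
        )
        labels = np.repeat(bids, source.counts)
    elif isinstance(source, Labelling):
        return FamilySizeDistribution.from_sizes(source.multiplicities)
    else:
        labels = np.asarray(source)
    if labels.size == 0:
        raise ValueError("no reads to group")
    _, fam = np.unique(labels, return_counts=True)
    return FamilySizeDistribution.from_sizes(fam)


def coefficient_of_variation(
    dist: FamilySizeDistribution, ddof: int = 0
) -> float:
    """Standard deviation of family sizes divided by their mean.

    Population form (denominator n) by default; pass ``ddof=1`` for the
    sample form.
    """
    if dist.n_families < 2:
        raise ValueError("CV needs at least two families")
    sizes = dist.sizes()
    return float(np.std(sizes, ddof=ddof) / np.mean(sizes))


# ---------------------------------------------------------------------------
# Zero-truncated Poisson maximum likelihood and goodness of fit
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ZTPFit:
    """Maximum-likelihood ZTP fit, optionally with chi-squared GOF attached."""

    lam: float
    loglik: float
    boundary: bool = False
    chi2_stat: float | None = None
    chi2_df: int | None = None
    chi2_p: float | None = None


def _ztp_loglik(lam: float, ks: np.ndarray, counts: np.ndarray) -> float:
    n = counts.sum()
    return float(
        np.dot(counts, ks * np.log(lam) - gammaln(ks + 1.0))
        - n * lam
        - n * np.log(-np.expm1(-lam))
    )


def fit_ztp_mle(dist: FamilySizeDistribution) -> ZTPFit:
    """Fit the ZTP rate by bounded 1-D likelihood maximisation.

    The likelihood in lambda is unimodal; the optimum equivalently solves
    the moment condition lambda / (1 - e^-lambda) = sample mean (see
    :func:`ztp_mle_moment`, kept as an independent route).  A sample mean
    of 1 — every family a singleton — pushes lambda to the lower boundary,
    where the ZTP degenerates to a point mass at 1; such fits are flagged.
    """
    ks = np.asarray(sorted(dist.counts), dtype=np.float64)
    counts = np.asarray([dist.counts[int(k)] for k in ks], dtype=np.float64)
    mean = dist.mean
    lo = 1e-8
    if mean <= 1.0 + 1e-12:
        return ZTPFit(lam=lo, loglik=_ztp_loglik(lo, ks, counts), boundary=True)
    hi = max(mean * 2.0, 1.0)
    res = minimize_scalar(
        lambda lam: -_ztp_loglik(lam, ks, counts),
        bounds=(lo, hi),
        method="bounded",
        options={"xatol": 1e-10},
    )
    return ZTPFit(lam=float(res.x), loglik=float(-res.fun))


def ztp_mle_moment(mean: float) -> float:
    """Invert mean = lambda / (1 - e^-lambda) — the ZTP MLE's score equation.

    Independent of the likelihood-maximisation route, and the fast path
    when only the rate is needed.
    """
    if mean < 1.0:
        raise ValueError("a zero-truncated Poisson mean cannot be below 1")
    if mean <= 1.0 + 1e-12:
        return 0.0

    def f(lam: float) -> float:
        return lam / -np.expm1(-lam) - mean

    # mean(lam) > lam, so the root lies in (0, mean)
    return float(brentq(f, 1e-12, mean, xtol=1e-12))


class GofResult(NamedTuple):
    stat: float
    df: int
    p: float


def chi_squared_gof(
    dist: FamilySizeDistribution,
    fit: ZTPFit,
    min_expected: float = 5.0,
) -> GofResult:
    """Pearson chi-squared test of the distribution against the fitted ZTP.

    Bins are family sizes 1, 2, ... with the right tail pooled (and
    under-filled interior bins merged rightward) until every expected count
    is at least ``min_expected``; the final bin absorbs the infinite tail
    so expected counts total n_families exactly.  Degrees of freedom are
    bins - 2: one for the total, one for the fitted rate.
    """
    if fit.lam <= 0 or fit.boundary:
        raise ValueError("GOF needs an interior (non-boundary) ZTP fit")
    kmax = max(dist.counts)
    ks = np.arange(1, kmax + 1)
    observed = np.asarray(
        [dist.counts.get(int(k), 0) for k in ks], dtype=np.float64
    )
    n = dist.n_families
    pk = ztp_pmf(ks, fit.lam)
    expected = n * pk
    # last bin takes the tail mass P(K > kmax)
    expected[-1] += n * max(0.0, 1.0 - pk.sum())

    obs_b, exp_b = _pool_bins(observed, expected, min_expected)
    if len(obs_b) < 3:
        raise ValueError(
            "fewer than 3 bins after pooling; chi-squared GOF not computable"
        )
    stat = float(np.sum((obs_b - exp_b) ** 2 / exp_b))
    df = len(obs_b) - 2
    return GofResult(stat=stat, df=df, p=float(chi2_dist.sf(stat, df)))


def _pool_bins(
    observed: np.ndarray, expected: np.ndarray, min_expected: float
) -> tuple[np.ndarray, np.ndarray]:
    """Merge bins rightward until every expected count >= min_expected."""
    obs: list[float] = []
    exp: list[float] = []
    acc_o = acc_e = 0.0
    for o, e in zip(observed, expected):
        acc_o += o
        acc_e += e
        if acc_e >= min_expected:
            obs.append(acc_o)
            exp.append(acc_e)
            acc_o = acc_e = 0.0
    if acc_e > 0 and obs:
        # leftover right tail folds into the last emitted bin
        obs[-1] += acc_o
        exp[-1] += acc_e
    return np.asarray(obs), np.asarray(exp)


# ---------------------------------------------------------------------------
# Run comparison and sequence utilities
# ---------------------------------------------------------------------------


class RunComparison(NamedTuple):
    n_shared: int
    r_squared: float
    slope: float
    ranks_a: np.ndarray
    ranks_b: np.ndarray


def compare_runs(
    sizes_a: Mapping[int, int], sizes_b: Mapping[int, int]
) -> RunComparison:
    """Rank agreement of per-barcode family sizes between two runs.

    Only barcodes present in both runs enter.  Ranks are ascending and
    dense: tied sizes share a rank and no gap is introduced, so for small
    family sizes the rank equals the size itself.  Returns the R-squared
    (and slope) of the least-squares line through the rank pairs.
    """
    shared = sorted(set(sizes_a) & set(sizes_b))
    if len(shared) < 10:
        raise ValueError(
            f"only {len(shared)} shared barcodes; need at least 10"
        )
    a = np.asarray([sizes_a[b] for b in shared], dtype=np.float64)
    b = np.asarray([sizes_b[b] for b in shared], dtype=np.float64)
    ra = rankdata(a, method="dense")
    rb = rankdata(b, method="dense")
    if np.all(ra == ra[0]) or np.all(rb == rb[0]):
        raise ValueError("degenerate ranking (all ranks tied)")
    res = linregress(ra, rb)
    return RunComparison(
        n_shared=len(shared),
        r_squared=float(res.rvalue**2),
        slope=float(res.slope),
        ranks_a=ra,
        ranks_b=rb,
    )


def gc_fraction(sequence: str) -> float:
    """Fraction of G and C bases in an ACGT sequence."""
    if not sequence:
        raise ValueError("empty sequence")
    if set(sequence) - set("ACGT"):
        raise ValueError("sequence must contain only A, C, G, T")
    return float(_bio_gc_fraction(sequence))
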