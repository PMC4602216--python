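"""Subsampling of the amplified pool and read generation.

Only a fraction of an amplified PCR product ever reaches the sequencer: the
product is diluted and loaded, which amounts to drawing molecules uniformly
at random, without replacement, from the amplified pool.  Lineages none of
whose molecules are drawn are invisible in the output — which is why the
observed family-size law under perfectly uniform amplification is a
*zero-truncated* Poisson with rate equal to the sample ratio (molecules
sequenced / initial molecules), the closed-form reference this module also
provides.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass
from typing import Iterator, Sequence

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
from scipy.stats import poisson

from umisim.pcr_models import AmplifiedPool, mutate_copy

__all__ = [
    "SampleConfig",
    "SampledMolecules",
    "Read",
    "ReadSet",
    "subsample",
    "sequence_reads",
    "ztp_pmf",
    "ztp_moments",
]

PLACEHOLDER_QUALITY = 40  # constant Phred score; qualities are not modelled


@dataclass(frozen=True)
class SampleConfig:
    """How much of the amplified pool is sequenced and how.

    Exactly one of ``sample_size`` (molecules) or ``sample_ratio``
    (relative to the *initial* molecule count, the "sample ratio" r) must
    be given.  ``read_length`` of ``None`` reads the full molecule.
    """

    sample_size: int | None = None
    sample_ratio: float | None = None
    seq_error_rate: float = 0.0
    read_length: int | None = None

    def __post_init__(self) -> None:
        if (self.sample_size is None) == (self.sample_ratio is None):
            raise ValueError("give exactly one of sample_size / sample_ratio")
        if self.sample_size is not None and self.sample_size < 1:
            raise ValueError("sample_size must be >= 1")
        if self.sample_ratio is not None and self.sample_ratio <= 0:
            raise ValueError("sample_ratio must be > 0")
        if not 0.0 <= self.seq_error_rate <= 1.0:
            raise ValueError("seq_error_rate must be in [0, 1]")
        if self.read_length is not None and self.read_length < 1:
            raise ValueError("read_length must be >= 1")

    def resolve_size(self, n_initial: int) -> int:
        if self.sample_size is not None:
            return self.sample_size
        return int(round(self.sample_ratio * n_initial))


@dataclass
class SampledMolecules:
    """Molecules drawn from an amplified pool for sequencing.

    ``counts[i]`` is the number of molecules sampled from lineage i (zeros
    mean the lineage goes unobserved).  On the sequence path the exact
    molecule indices are retained so accumulated PCR errors survive into
    the reads.
    """

    pool: AmplifiedPool
    counts: np.ndarray
    molecule_indices: list[np.ndarray] | None = None

    @property
    def size(self) -> int:
        return int(self.counts.sum())

    def observed_family_sizes(self) -> np.ndarray:
        """Per observed lineage (count > 0), the number of sampled molecules."""
        return self.counts[self.counts > 0]

    def iter_molecules(self) -> Iterator[tuple[int, int, str]]:
        """Yield (lineage index, lineage id, molecule sequence) per sampled
        molecule; requires templates or explicit molecules."""
        for i, lin in enumerate(self.pool.lineages):
            c = int(self.counts[i])
            if c == 0:
                continue
            if lin.molecules is not None and self.molecule_indices is not None:
                for j in self.molecule_indices[i]:
                    yield i, lin.id, lin.molecules[int(j)]
            else:
                if lin.template is None:
                    raise ValueError(
                        "lineage has no sequence; amplify with templates "
                        "(make_lineages(..., with_sequences=True))"
                    )
                for _ in range(c):
                    yield i, lin.id, lin.template


def subsample(
    pool: AmplifiedPool, config: SampleConfig, seed: int | None = None
) -> SampledMolecules:
    """Draw molecules uniformly without replacement from the amplified pool.

    On the count path this is one multivariate-hypergeometric draw over the
    per-lineage copy numbers.  When the pool carries explicit molecules,
    individual molecules are selected so their accumulated errors are kept.
    """
    rng = np.random.default_rng(seed)
    copies = pool.copies
    total = int(copies.sum())
    n_initial = int(pool.per_cycle_population[0])
    size = config.resolve_size(n_initial)
    if size > total:
        raise ValueError(
            f"sample size {size} exceeds amplified pool of {total} molecules"
        )

    has_molecules = any(lin.molecules is not None for lin in pool.lineages)
    if not has_molecules:
        counts = _hypergeometric_counts(copies, total, size, rng)
        return SampledMolecules(pool, counts)

    flat = rng.choice(total, size=size, replace=False)
    bounds = np.cumsum(copies)
    lineage_of = np.searchsorted(bounds, flat, side="right")
    starts = bounds - copies
    counts = np.bincount(lineage_of, minlength=len(copies)).astype(np.int64)
    indices: list[np.ndarray] = [
        np.sort(flat[lineage_of == i] - starts[i]) for i in range(len(copies))
    ]
    return SampledMolecules(pool, counts, indices)


def _hypergeometric_counts(
    copies: np.ndarray, total: int, size: int, rng: np.random.Generator
) -> np.ndarray:
    """Multivariate-hypergeometric draw of ``size`` from lineage copy counts.

    numpy's generator refuses totals of 1e9 and above, which heavy-tailed
    amplification models reach easily.  In that regime the sample is far
    smaller than the pool, so distinct molecule indices are drawn directly
    (uniform integers, duplicates redrawn) — still an exact
    without-replacement sample.
    """
    if total < 1_000_000_000:
        counts = rng.multivariate_hypergeometric(
            copies, size, method="marginals"
        )
        return np.asarray(counts, dtype=np.int64)
    if size > total // 2:
        raise ValueError(
            "sampling more than half of a >=1e9-molecule pool is not "
            "supported; reduce the sample or the amplification"
        )
    chosen = np.unique(rng.integers(0, total, size=size, dtype=np.int64))
    while chosen.size < size:
        extra = rng.integers(0, total, size=size - chosen.size, dtype=np.int64)
        chosen = np.unique(np.concatenate([chosen, extra]))
    bounds = np.cumsum(copies)
    lineage_of = np.searchsorted(bounds, chosen, side="right")
    return np.bincount(lineage_of, minlength=len(copies)).astype(np.int64)


@dataclass(frozen=True)
class Read:
    id: str
    lineage_id: int
    barcode_id: int
    sequence: str
    quality: str


@dataclass
class ReadSet:
    """Simulated sequencer output plus the configuration that produced it."""

    reads: list[Read]
    config: SampleConfig
    seed: int | None = None

    def __len__(self) -> int:
        return len(self.reads)

    def lineage_ids(self) -> np.ndarray:
        return np.asarray([r.lineage_id for r in self.reads], dtype=np.int64)

    def barcode_ids(self) -> np.ndarray:
        return np.asarray([r.barcode_id for r in self.reads], dtype=np.int64)

    def to_fastq(self, path) -> None:
        """Write standard 4-line FASTQ (gzip if the path ends in .gz).

        The header comment carries lineage and barcode ids so ground truth
        survives into downstream analysis.
        """
        records = (
            SeqRecord(
                Seq(r.sequence),
                id=r.id,
                description=f"lineage={r.lineage_id} barcode={r.barcode_id}",
                letter_annotations={
                    "phred_quality": [PLACEHOLDER_QUALITY] * len(r.sequence)
                },
            )
            for r in self.reads
        )
        path = str(path)
        if path.endswith(".gz"):
            with gzip.open(path, "wt") as fh:
                SeqIO.write(records, fh, "fastq")
        else:
            SeqIO.write(records, path, "fastq")


def sequence_reads(
    sampled: SampledMolecules,
    seq_error_rate: float | None = None,
    seed: int | None = None,
    read_length: int | None = None,
) -> ReadSet:
    """Turn each sampled molecule into one read with substitution errors.

    Per-base errors use the same substitution model as PCR replication
    error (uniform choice among the three other bases).  The barcode
    occupies the first L bases of the molecule, so barcode-position errors
    corrupt the observed barcode exactly as they would experimentally.
    """
    if seq_error_rate is None:
        seq_error_rate = 0.0
    rng = np.random.default_rng(seed)
    reads: list[Read] = []
    lineages = sampled.pool.lineages
    for k, (i, lid, seq) in enumerate(sampled.iter_molecules()):
        if read_length is not None:
            seq = seq[:read_length]
        if seq_error_rate > 0:
            seq = mutate_copy(seq, seq_error_rate, rng)
        reads.append(
            Read(
                id=f"sim_{k}",
                lineage_id=lid,
                barcode_id=lineages[i].barcode_id,
                sequence=seq,
                quality="I" * len(seq),  # Phred 40
            )
        )
    if not reads:
        raise ValueError("no molecules were sampled")
    cfg = SampleConfig(
        sample_size=len(reads),
        seq_error_rate=seq_error_rate,
        read_length=read_length,
    )
    return ReadSet(reads, cfg, seed)


# ---------------------------------------------------------------------------
# Zero-truncated Poisson reference law
# ---------------------------------------------------------------------------


def ztp_pmf(k, lam: float):
    """Zero-truncated Poisson pmf: Pois(k; lam) / (1 - e^-lam) for k >= 1.

    The family-size law when every lineage is amplified identically and the
    product is randomly subsampled at rate lam per lineage.
    """
    if lam <= 0:
        raise ValueError("lambda must be > 0")
    k_arr = np.atleast_1d(np.asarray(k))
    out = poisson.pmf(k_arr, lam) / -np.expm1(-lam)
    out = np.where(k_arr >= 1, out, 0.0)
    # non-integer k has probability zero
    out = np.where(np.equal(np.mod(k_arr, 1), 0), out, 0.0)
    return float(out[0]) if np.isscalar(k) else out


def ztp_moments(lam: float) -> tuple[float, float, float]:
    """(mean, variance, CV) of the zero-truncated Poisson.

    mean = lam / (1 - e^-lam); the variance follows from the untruncated
    second moment lam + lam^2 rescaled by the truncation mass.
    """
    if lam <= 0:
        raise ValueError("lambda must be > 0")
    scale = -np.expm1(-lam)  # 1 - e^-lam
    mean = lam / scale
    second = (lam + lam**2) / scale
    var = second - mean**2
    return float(mean), float(var), float(np.sqrt(var) / mean)
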