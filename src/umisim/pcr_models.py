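"""Branching-process models of PCR amplification.

PCR is modelled as a Galton–Watson branching process: in each cycle every
molecule either replicates (offspring 2) or does not (offspring 1), with a
replication probability set by one of six model variants:

1. constant efficiency ``e`` for every molecule in every cycle;
2. as model 1, but a molecule that fails to replicate in a cycle degrades
   with probability ``d`` and leaves the reaction;
3. competition for a fixed resource ``R``: the per-cycle replication
   probability is ``min(1, R / M_t)``, so efficiency collapses once the
   population ``M_t`` outgrows the resource;
4. as model 3, but the resource is consumed (rate ``delta`` per successful
   replication);
5. per-molecule, per-cycle efficiency drawn fresh from a Normal(mu, sigma)
   truncated to [0, 1];
6. inherited efficiency: one truncated-normal draw per *initial* molecule,
   shared by all of its descendants through every cycle — the heritable
   heterogeneity variant.

Two execution paths produce identical statistics: a fast count path (one
binomial draw per lineage per cycle) used when no replication error is
simulated, and a sequence path that materialises every molecule so that
per-base substitution errors can accumulate along the lineage tree.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy.stats import truncnorm

from umisim.barcode_pool import BarcodePool, Labelling

__all__ = [
    "ModelConfig",
    "Lineage",
    "AmplifiedPool",
    "make_lineages",
    "amplify",
    "cycle_model1",
    "cycle_model2",
    "cycle_model3",
    "cycle_model4",
    "cycle_model5",
    "cycle_model6",
    "mutate_copy",
    "expected_final_copies",
    "truncated_normal_mean",
    "POPULATION_CAP",
]

POPULATION_CAP = 10**9  # desk-scale guard: abort rather than swallow memory

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_BASE_INDEX = np.full(256, -1, dtype=np.int8)
for _i, _b in enumerate(b"ACGT"):
    _BASE_INDEX[_b] = _i


@dataclass(frozen=True)
class ModelConfig:
    """Parameters of one amplification run.

    Fields irrelevant to the chosen model are ignored.  ``resource`` is
    expressed as a multiple of the initial molecule count (as in the
    fixed-resource competition model); the absolute resource is computed
    when amplification starts.
    """

    model: int = 1
    cycles: int = 25
    efficiency: float = 0.9  # models 1-2
    degradation: float = 0.0  # model 2
    resource: float = 100.0  # models 3-4, multiple of initial molecules
    resource_decay: float = 0.0  # model 4, consumed per successful replication
    eff_mean: float = 0.9  # models 5-6
    eff_sd: float = 0.1  # models 5-6
    error_rate: float = 0.0  # substitutions per base per cycle
    population_cap: int = POPULATION_CAP  # abort above this many molecules

    def __post_init__(self) -> None:
        if self.model not in range(1, 7):
            raise ValueError(f"model must be 1-6, got {self.model}")
        if self.cycles < 1:
            raise ValueError("cycles must be >= 1")
        for name in ("efficiency", "degradation", "error_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.resource <= 0:
            raise ValueError("resource must be positive")
        if self.resource_decay < 0:
            raise ValueError("resource_decay must be >= 0")
        if self.eff_sd < 0:
            raise ValueError("efficiency sd must be >= 0")
        if self.population_cap < 1:
            raise ValueError("population_cap must be >= 1")


@dataclass
class Lineage:
    """One initial template molecule and everything descended from it."""

    id: int
    barcode_id: int
    copies: int = 1
    inherited_efficiency: float | None = None
    template: str | None = None
    molecules: list[str] | None = None


def make_lineages(
    n: int | None = None,
    labelling: Labelling | None = None,
    pool: BarcodePool | None = None,
    insert: str = "",
    with_sequences: bool = False,
) -> list[Lineage]:
    """Construct initial single-copy lineages.

    Either ``labelling`` (barcode ids as drawn, clashes included) or a plain
    count ``n`` (unique consecutive barcode ids — the idealised
    every-molecule-uniquely-barcoded setting).  When ``with_sequences`` the
    template is the barcode nucleotide string (requires ``pool``) followed
    by ``insert``.
    """
    if labelling is not None:
        barcode_ids = labelling.assignments
    elif n is not None:
        barcode_ids = np.arange(n)
    else:
        raise ValueError("provide either n or a labelling")
    lineages = []
    for i, bid in enumerate(barcode_ids):
        template = None
        if with_sequences:
            if pool is None:
                raise ValueError("sequence templates require a pool")
            template = pool.barcode_string(int(bid)) + insert
        lineages.append(Lineage(id=i, barcode_id=int(bid), template=template))
    return lineages


@dataclass
class AmplifiedPool:
    """Amplification outcome: per-lineage copy numbers plus the trajectory.

    ``per_cycle_population`` has length cycles+1 and starts at the initial
    molecule count (cycle 0).  ``molecules`` is populated only on the
    sequence path.
    """

    lineages: list[Lineage]
    per_cycle_population: np.ndarray
    config: ModelConfig

    @property
    def copies(self) -> np.ndarray:
        return np.asarray([lin.copies for lin in self.lineages], dtype=np.int64)

    @property
    def total_molecules(self) -> int:
        return int(self.copies.sum())


# ---------------------------------------------------------------------------
# Single-cycle kernels (count path); all accept scalar or array copy counts
# ---------------------------------------------------------------------------


def cycle_model1(copies, e: float, rng: np.random.Generator):
    """Constant-efficiency cycle: copies + Binomial(copies, e)."""
    copies = np.asarray(copies)
    return copies + rng.binomial(copies, e)


def cycle_model2(copies, e: float, d: float, rng: np.random.Generator):
    """Target-degradation cycle.

    Molecules that fail to replicate (prob 1-e) degrade with probability d
    and leave the reaction; degradation is only ever attempted on that
    cycle's failures.
    """
    copies = np.asarray(copies)
    s = rng.binomial(copies, e)
    g = rng.binomial(copies - s, d)
    return copies + s - g


def cycle_model3(copies, resource_abs: float, rng: np.random.Generator):
    """Fixed-resource competition cycle: p_t = min(1, R / M_t)."""
    copies = np.asarray(copies)
    m_t = int(copies.sum())
    p_t = min(1.0, resource_abs / m_t) if m_t > 0 else 0.0
    return copies + rng.binomial(copies, p_t)


def cycle_model4(copies, resource_t: float, decay: float, rng: np.random.Generator):
    """Consumable-resource cycle; returns (updated copies, remaining resource)."""
    copies = np.asarray(copies)
    m_t = int(copies.sum())
    p_t = min(1.0, resource_t / m_t) if (m_t > 0 and resource_t > 0) else 0.0
    s = rng.binomial(copies, p_t)
    resource_next = max(0.0, resource_t - decay * float(np.sum(s)))
    return copies + s, resource_next


def cycle_model5(copies, mu: float, sigma: float, rng: np.random.Generator):
    """Variable-efficiency cycle: fresh truncated-Normal(mu, sigma) draw on
    [0, 1] per molecule, every cycle."""
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    copies = np.asarray(copies)
    if sigma == 0:
        return copies + rng.binomial(copies, mu)
    total = int(copies.sum())
    effs = _truncnorm01(mu, sigma, total, rng)
    success = rng.random(total) < effs
    # segment-sum successes back to their lineages
    starts = np.concatenate([[0], np.cumsum(copies)[:-1]])
    gains = np.add.reduceat(success, starts)
    gains[copies == 0] = 0  # reduceat artefact on empty segments
    return copies + gains


def cycle_model6(copies, inherited_eff, rng: np.random.Generator):
    """Inherited-efficiency cycle: per-lineage fixed replication probability."""
    copies = np.asarray(copies)
    eff = np.asarray(inherited_eff, dtype=float)
    if np.any(~np.isfinite(eff)) or np.any((eff < 0) | (eff > 1)):
        raise ValueError("inherited efficiencies must be set and in [0, 1]")
    return copies + rng.binomial(copies, eff)


def _truncnorm01(
    mu: float, sigma: float, size: int, rng: np.random.Generator
) -> np.ndarray:
    """Normal(mu, sigma) truncated (not clipped) to [0, 1]."""
    if sigma == 0:
        if not 0.0 <= mu <= 1.0:
            raise ValueError("degenerate efficiency distribution outside [0, 1]")
        return np.full(size, float(mu))
    a, b = (0.0 - mu) / sigma, (1.0 - mu) / sigma
    return truncnorm.rvs(a, b, loc=mu, scale=sigma, size=size, random_state=rng)


def truncated_normal_mean(mu: float, sigma: float) -> float:
    """Mean of Normal(mu, sigma) truncated to [0, 1].

    The marginal replication probability of the variable-efficiency model —
    useful for matched constant-efficiency comparisons.
    """
    if sigma == 0:
        return float(mu)
    a, b = (0.0 - mu) / sigma, (1.0 - mu) / sigma
    return float(truncnorm.mean(a, b, loc=mu, scale=sigma))


def expected_final_copies(e: float, cycles: int) -> float:
    """Branching expectation of copies after ``cycles`` at efficiency e: (1+e)^c."""
    if not 0.0 <= e <= 1.0:
        raise ValueError("efficiency must be in [0, 1]")
    if cycles < 0:
        raise ValueError("cycles must be >= 0")
    return (1.0 + e) ** cycles


# ---------------------------------------------------------------------------
# Per-base replication error (sequence path)
# ---------------------------------------------------------------------------


def mutate_copy(
    sequence: str, error_rate: float, rng: np.random.Generator
) -> str:
    """Copy a sequence with independent per-base substitution errors.

    Each position is substituted with probability ``error_rate``; a
    substituted position takes one of the three other bases uniformly, so a
    hit always changes the base.  The parent string is untouched.
    """
    if not 0.0 <= error_rate <= 1.0:
        raise ValueError("error_rate must be in [0, 1]")
    encoded = np.frombuffer(sequence.encode("ascii"), dtype=np.uint8)
    idx = _BASE_INDEX[encoded]
    if np.any(idx < 0):
        raise ValueError("sequence must contain only A, C, G, T")
    if error_rate == 0.0:
        return sequence
    hit = rng.random(idx.size) < error_rate
    n_hit = int(hit.sum())
    if n_hit:
        idx = idx.copy()
        idx[hit] = (idx[hit] + rng.integers(1, 4, size=n_hit)) % 4
    return _BASES[idx].tobytes().decode("ascii")


# ---------------------------------------------------------------------------
# Multi-cycle driver
# ---------------------------------------------------------------------------


def amplify(
    lineages: Sequence[Lineage],
    config: ModelConfig,
    seed: int | None = None,
    force_sequence_path: bool = False,
) -> AmplifiedPool:
    """Run ``config.cycles`` cycles of the configured model on the lineages.

    The count path (per-lineage binomial updates) is used when
    ``error_rate == 0``; with replication error every molecule is
    materialised so errors can accumulate along the branching tree.
    ``force_sequence_path`` runs the sequence machinery at zero error, which
    must be statistically indistinguishable from the count path.
    """
    if len(lineages) == 0:
        raise ValueError("need at least one lineage")
    if any(lin.copies < 1 for lin in lineages):
        raise ValueError("every input lineage needs copies >= 1")
    rng = np.random.default_rng(seed)
    sequence_path = force_sequence_path or config.error_rate > 0

    copies0 = np.asarray([lin.copies for lin in lineages], dtype=np.int64)
    n0 = int(copies0.sum())
    resource_abs = config.resource * n0

    out = [replace_lineage(lin) for lin in lineages]
    if config.model == 6:
        effs = _truncnorm01(config.eff_mean, config.eff_sd, len(out), rng)
        for lin, e in zip(out, effs):
            lin.inherited_efficiency = float(e)

    if sequence_path:
        trajectory = _amplify_sequences(out, config, resource_abs, rng)
        return AmplifiedPool(out, np.asarray(trajectory), config)

    copies = copies0.copy()
    trajectory = [n0]
    resource_t = resource_abs
    eff6 = (
        np.asarray([lin.inherited_efficiency for lin in out])
        if config.model == 6
        else None
    )
    for _ in range(config.cycles):
        if config.model == 1:
            copies = cycle_model1(copies, config.efficiency, rng)
        elif config.model == 2:
            copies = cycle_model2(
                copies, config.efficiency, config.degradation, rng
            )
        elif config.model == 3:
            copies = cycle_model3(copies, resource_abs, rng)
        elif config.model == 4:
            copies, resource_t = cycle_model4(
                copies, resource_t, config.resource_decay, rng
            )
        elif config.model == 5:
            copies = cycle_model5(copies, config.eff_mean, config.eff_sd, rng)
        else:
            copies = cycle_model6(copies, eff6, rng)
        total = int(copies.sum())
        if total > config.population_cap:
            raise RuntimeError(
                f"population {total} exceeds cap {config.population_cap}; "
                "reduce cycles or efficiency, or raise "
                "ModelConfig.population_cap"
            )
        trajectory.append(total)
    for lin, c in zip(out, copies):
        lin.copies = int(c)
    return AmplifiedPool(out, np.asarray(trajectory), config)


def replace_lineage(lin: Lineage) -> Lineage:
    mols = list(lin.molecules) if lin.molecules is not None else None
    return Lineage(
        id=lin.id,
        barcode_id=lin.barcode_id,
        copies=lin.copies,
        inherited_efficiency=lin.inherited_efficiency,
        template=lin.template,
        molecules=mols,
    )


def _amplify_sequences(
    lineages: list[Lineage],
    config: ModelConfig,
    resource_abs: float,
    rng: np.random.Generator,
) -> list[int]:
    """Sequence-path amplification: molecules are explicit strings.

    A successful replication copies the parent and then mutates the copy;
    existing molecules are never re-mutated, so errors propagate only to
    descendants — exactly the lineage-tree error structure of PCR.
    """
    for lin in lineages:
        if lin.molecules is None:
            if lin.template is None:
                raise ValueError(
                    "sequence path needs templates; build lineages with "
                    "with_sequences=True"
                )
            lin.molecules = [lin.template] * lin.copies
    total = sum(len(lin.molecules) for lin in lineages)
    trajectory = [total]
    resource_t = resource_abs
    for _ in range(config.cycles):
        m_t = total
        successes_this_cycle = 0
        if config.model in (3, 4):
            level = resource_t if config.model == 4 else resource_abs
            p_global = min(1.0, level / m_t) if (m_t > 0 and level > 0) else 0.0
        for lin in lineages:
            mols = lin.molecules
            n = len(mols)
            if n == 0:
                continue
            if config.model == 1:
                rep = rng.random(n) < config.efficiency
            elif config.model == 2:
                u = rng.random(n)
                rep = u < config.efficiency
                failed = ~rep
                degraded = failed & (rng.random(n) < config.degradation)
                if degraded.any():
                    mols = [m for m, dgd in zip(mols, degraded) if not dgd]
            elif config.model in (3, 4):
                rep = rng.random(n) < p_global
            elif config.model == 5:
                effs = _truncnorm01(config.eff_mean, config.eff_sd, n, rng)
                rep = rng.random(n) < effs
            else:
                rep = rng.random(n) < lin.inherited_efficiency
            n_rep = int(rep.sum())
            successes_this_cycle += n_rep
            children = [
                mutate_copy(lin.molecules[i], config.error_rate, rng)
                for i in np.flatnonzero(rep)
            ]
            lin.molecules = mols + children
            lin.copies = len(lin.molecules)
        if config.model == 4:
            resource_t = max(
                0.0, resource_t - config.resource_decay * successes_this_cycle
            )
        total = sum(lin.copies for lin in lineages)
        if total > config.population_cap:
            raise RuntimeError(
                f"population {total} exceeds cap {config.population_cap}"
            )
        trajectory.append(total)
    return trajectory
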