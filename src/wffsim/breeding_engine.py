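"""One generation of the breeding program.

Discrete generations: 3000 male candidates and 3000 dams per generation;
300 sires are truncation-selected on own phenotype (120 for breeding goal
1, 180 for breeding goal 2), 6000 offspring are apportioned to sires by
phenotype decile (popular-stallion skew: the top decile sires 58% of the
crop), matings are random over eligible dams, and offspring genomes are
built by two independent meioses on the genetic map.

Management policies
-------------------
``no_testing``
    the lethal allele is unknown; affected (homozygous) individuals are
    excluded from selection and mating but no carrier information is used;
``avoid_carrier_mating``
    genetic testing avoids carrier-by-carrier matings: carrier sires are
    mated only to noncarrier dams and vice versa;
``exclude_carrier_sires``
    carrier males may not be selected as sires, except for an exemption of
    the top-k males per breeding goal (ranked before exclusion); the
    carrier-mating avoidance of the previous policy is kept for any exempt
    carrier sires.
"""

from __future__ import annotations

import dataclasses
from typing import Union

import numpy as np

from .founder_genomes import FounderPopulation, GeneticMap
from .lethal_allele import AFFECTED, CARRIER, LethalSpec, classify_carriers, viability_filter
from .trait_model import PhenotypeModel, TraitArchitecture, genetic_values, phenotypes

__all__ = [
    "MALE",
    "FEMALE",
    "POLICY_MODES",
    "BreedingConfig",
    "ManagementPolicy",
    "Cohort",
    "SireSelection",
    "SelectionInfeasibleError",
    "MatingInfeasibleError",
    "select_sires",
    "allocate_offspring",
    "mate",
    "meiosis",
    "recombine_gametes",
    "founder_cohort",
    "advance_generation",
]

MALE = 0
FEMALE = 1

POLICY_MODES = ("no_testing", "avoid_carrier_mating", "exclude_carrier_sires")

# Offspring per sire within each phenotype decile (decile 1 = lowest).  The
# lowest three deciles get one offspring per sire and the top decile 116,
# i.e. 30 * 116 = 3480 of 6000 offspring (58%) from the top decile; the
# middle deciles follow a monotone default.
DEFAULT_DECILE_COUNTS = (1, 1, 1, 3, 6, 10, 16, 20, 26, 116)


class SelectionInfeasibleError(RuntimeError):
    """Fewer eligible males than sires to select."""


class MatingInfeasibleError(RuntimeError):
    """A sire has no eligible dam under the active policy."""


@dataclasses.dataclass(frozen=True)
class BreedingConfig:
    """Breeding-scheme constants for one generation step."""

    n_male_candidates: int = 3000
    n_dams: int = 3000
    n_sires: int = 300
    split: tuple[int, int] = (120, 180)  # sires for (goal 1, goal 2)
    n_offspring: int = 6000
    decile_counts: tuple[int, ...] = DEFAULT_DECILE_COUNTS
    n_generations: int = 20
    # Larger goal-2 group is filled first; double-qualifying males are
    # assigned there, goal-1 sires come from the remainder.
    selection_order: tuple[int, int] = (1, 0)

    def __post_init__(self) -> None:
        if sum(self.split) != self.n_sires:
            raise ValueError("split must sum to n_sires")
        if self.n_sires % len(self.decile_counts) != 0:
            raise ValueError("n_sires must be divisible by the number of deciles")
        per_decile = self.n_sires // len(self.decile_counts)
        if per_decile * sum(self.decile_counts) != self.n_offspring:
            raise ValueError(
                "decile counts inconsistent: per-decile sires x sum(counts) "
                f"= {per_decile * sum(self.decile_counts)} != n_offspring = {self.n_offspring}"
            )
        if any(b < a for a, b in zip(self.decile_counts, self.decile_counts[1:])):
            raise ValueError("decile counts must be non-decreasing")
        if sorted(self.selection_order) != [0, 1]:
            raise ValueError("selection_order must be a permutation of (0, 1)")


@dataclasses.dataclass(frozen=True)
class ManagementPolicy:
    mode: str = "no_testing"
    exemption_top_k: int = 0  # per breeding goal, exclude_carrier_sires only

    def __post_init__(self) -> None:
        if self.mode not in POLICY_MODES:
            raise ValueError(f"mode must be one of {POLICY_MODES}, got {self.mode!r}")
        if self.exemption_top_k < 0:
            raise ValueError("exemption_top_k must be >= 0")
        if self.exemption_top_k and self.mode != "exclude_carrier_sires":
            raise ValueError("exemption_top_k is only meaningful in exclude_carrier_sires mode")

    @property
    def avoidance_active(self) -> bool:
        """Carrier x carrier matings forbidden?"""
        return self.mode in ("avoid_carrier_mating", "exclude_carrier_sires")


@dataclasses.dataclass
class Cohort:
    """One discrete generation of individuals."""

    generation: int
    ids: np.ndarray  # (n,) int64, globally unique, monotone within cohort
    sex: np.ndarray  # (n,) int8, MALE/FEMALE
    haplotypes: np.ndarray  # (n, 2, L) int8
    genetic_value: np.ndarray  # (n, 2) index units
    phenotype: np.ndarray  # (n, 2) index units
    status: np.ndarray  # (n,) int8 carrier status
    sire: np.ndarray  # (n,) int64 parent ids, -1 for founders
    dam: np.ndarray

    @property
    def n(self) -> int:
        return int(self.ids.shape[0])

    def males(self) -> np.ndarray:
        return np.flatnonzero(self.sex == MALE)

    def females(self) -> np.ndarray:
        return np.flatnonzero(self.sex == FEMALE)


@dataclasses.dataclass(frozen=True)
class SireSelection:
    """Selected sires: cohort row indices and the goal each was selected for."""

    indices: np.ndarray  # (n_sires,) intp
    goal: np.ndarray  # (n_sires,) int8, 0 or 1


def _ranked(candidates: np.ndarray, phen: np.ndarray, ids: np.ndarray) -> np.ndarray:
    """Candidates ordered by phenotype descending, ties broken by id ascending."""
    order = np.lexsort((ids[candidates], -phen[candidates]))
    return candidates[order]


def select_sires(cohort: Cohort, policy: ManagementPolicy, config: BreedingConfig) -> SireSelection:
    """Truncation-select sires on own phenotype under the management policy.

    The two goal groups are disjoint: the group listed first in
    ``config.selection_order`` (default: goal 2, the larger group) takes the
    top males by its phenotype; the other group selects from the remainder.
    In ``exclude_carrier_sires`` mode a carrier male is eligible only if he
    ranks within the top ``exemption_top_k`` of either goal's phenotype
    ranking, computed before any carrier is excluded.
    """
    males = cohort.males()
    viable = males[viability_filter(cohort.status[males])]

    if policy.mode == "exclude_carrier_sires":
        exempt = np.zeros(cohort.n, dtype=bool)
        k = policy.exemption_top_k
        if k > 0:
            for g in (0, 1):
                top = _ranked(viable, cohort.phenotype[:, g], cohort.ids)[:k]
                exempt[top] = True
        carrier = cohort.status[viable] == CARRIER
        eligible = viable[~carrier | exempt[viable]]
    else:
        eligible = viable

    if eligible.size < config.n_sires:
        raise SelectionInfeasibleError(
            f"only {eligible.size} eligible males for {config.n_sires} sire slots "
            f"(policy {policy.mode}, k={policy.exemption_top_k})"
        )

    indices = np.empty(config.n_sires, dtype=np.intp)
    goals = np.empty(config.n_sires, dtype=np.int8)
    remaining = eligible
    pos = 0
    for g in config.selection_order:
        n_g = config.split[g]
        chosen = _ranked(remaining, cohort.phenotype[:, g], cohort.ids)[:n_g]
        indices[pos : pos + n_g] = chosen
        goals[pos : pos + n_g] = g
        pos += n_g
        remaining = np.setdiff1d(remaining, chosen, assume_unique=True)
    return SireSelection(indices=indices, goal=goals)


def allocate_offspring(
    selection: SireSelection, cohort: Cohort, config: BreedingConfig
) -> np.ndarray:
    """Per-sire offspring quota from pooled own-goal phenotype deciles.

    All selected sires are pooled and ranked by the phenotype for the goal
    they were selected on (both goals share the index scale, so the pooled
    ranking is well defined).  Decile 1 (lowest 30) receives
    ``decile_counts[0]`` offspring per sire, and so on.  Quotas are aligned
    with ``selection.indices`` and sum to ``n_offspring``.
    """
    n = selection.indices.size
    if n != config.n_sires:
        raise ValueError(f"expected {config.n_sires} sires, got {n}")
    own_goal_phen = cohort.phenotype[selection.indices, selection.goal.astype(np.intp)]
    order = np.lexsort((cohort.ids[selection.indices], own_goal_phen))  # ascending
    per_decile = n // len(config.decile_counts)
    quotas = np.empty(n, dtype=np.int64)
    quotas[order] = np.repeat(np.asarray(config.decile_counts, dtype=np.int64), per_decile)
    assert quotas.sum() == config.n_offspring
    return quotas


def mate(
    selection: SireSelection,
    quotas: np.ndarray,
    cohort: Cohort,
    policy: ManagementPolicy,
    seed: Union[int, np.random.Generator, None] = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Draw one dam per offspring slot, uniformly with replacement.

    Returns ``(sire_rows, dam_rows)`` cohort row indices of length
    ``quotas.sum()``.  Affected dams are never eligible.  When carrier
    avoidance is active, offspring slots of carrier sires draw only from
    noncarrier dams (and carrier dams are thereby only ever mated to
    noncarrier sires).
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    females = cohort.females()
    dams_all = females[viability_filter(cohort.status[females])]
    if dams_all.size == 0:
        raise MatingInfeasibleError("no eligible dams")

    sire_rows = np.repeat(selection.indices, quotas)
    dam_rows = dams_all[rng.integers(0, dams_all.size, size=sire_rows.size)]

    if policy.avoidance_active:
        carrier_slot = cohort.status[sire_rows] == CARRIER
        n_c = int(carrier_slot.sum())
        if n_c:
            dams_nc = dams_all[cohort.status[dams_all] != CARRIER]
            if dams_nc.size == 0:
                raise MatingInfeasibleError("carrier sire has no noncarrier dam available")
            dam_rows[carrier_slot] = dams_nc[rng.integers(0, dams_nc.size, size=n_c)]
    return sire_rows, dam_rows


def meiosis(
    parent_haplotypes: np.ndarray,
    gmap: GeneticMap,
    seed: Union[int, np.random.Generator, None] = None,
    return_crossovers: bool = False,
):
    """One gamete from a parent's two haplotypes, explicit crossover model.

    Per chromosome the crossover count is Poisson with mean chrom_length in
    Morgan (1 for 100 cM), crossover positions are uniform with no
    interference, the starting haplotype is a fair coin, and the gamete
    switches haplotype at every crossover in position order.

    This explicit single-gamete routine is the reference implementation;
    the batch path :func:`recombine_gametes` samples the same law directly
    at the marker loci (see its docstring).
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    if parent_haplotypes.shape[0] != 2:
        raise ValueError("parent must have exactly two haplotypes")
    L = gmap.n_loci
    gamete = np.empty(L, dtype=np.int8)
    crossovers: list[np.ndarray] = []
    mean_xo = gmap.chrom_length / 100.0  # Morgan
    for sl in gmap.chromosome_slices():
        k = rng.poisson(mean_xo)
        xo = np.sort(rng.uniform(0.0, gmap.chrom_length, size=k))
        start = int(rng.integers(0, 2))
        source = (start + np.searchsorted(xo, gmap.position_cm[sl])) % 2
        idx = np.arange(sl.start, sl.stop)
        gamete[sl] = parent_haplotypes[source, idx]
        crossovers.append(xo)
    if return_crossovers:
        return gamete, crossovers
    return gamete


def recombine_gametes(
    parents: np.ndarray, gmap: GeneticMap, rng: np.random.Generator
) -> np.ndarray:
    """Vectorized gametes for a batch of parents, shape (n, 2, L) -> (n, L).

    Samples the marginal law of the Poisson/no-interference crossover model
    at the marker loci: crossover counts in disjoint intervals are
    independent Poisson variables, and only the parity of the count between
    adjacent markers matters for the allele outcome, with
    P(odd) = (1 - exp(-2d)) / 2 for an interval of d Morgan (the Haldane
    map function).  The source haplotype at the first marker is a fair
    coin and flips independently per interval with that probability.
    """
    n, two, L = parents.shape
    if two != 2:
        raise ValueError("parents must have shape (n, 2, n_loci)")
    out = np.empty((n, L), dtype=np.int8)
    for sl in gmap.chromosome_slices():
        m = sl.stop - sl.start
        d_morgan = np.diff(gmap.position_cm[sl]) / 100.0
        p_switch = np.empty(m)
        p_switch[0] = 0.5
        p_switch[1:] = 0.5 * (1.0 - np.exp(-2.0 * d_morgan))
        switches = rng.random((n, m)) < p_switch
        source = np.cumsum(switches, axis=1) & 1  # parity
        block = parents[:, :, sl]
        out[:, sl] = np.where(source == 1, block[:, 1, :], block[:, 0, :])
    return out


def _assign_sexes(n: int, rng: np.random.Generator) -> np.ndarray:
    """Random permutation of an exact 50:50 split."""
    sex = np.empty(n, dtype=np.int8)
    half = n // 2
    sex[:half] = MALE
    sex[half:] = FEMALE
    return sex[rng.permutation(n)]


def _make_ids(generation: int, n: int) -> np.ndarray:
    return np.arange(n, dtype=np.int64) + np.int64(generation) * 1_000_000


def founder_cohort(
    pop: FounderPopulation,
    arch: TraitArchitecture,
    lethal: LethalSpec,
    model: PhenotypeModel,
    rng: np.random.Generator,
) -> Cohort:
    """Generation-0 cohort assembled from founder haplotypes."""
    n = pop.n_founders
    hap = np.ascontiguousarray(
        pop.haplotypes.reshape(n, 2, pop.n_loci)
    )
    gv = genetic_values(hap, arch)
    return Cohort(
        generation=0,
        ids=_make_ids(0, n),
        sex=_assign_sexes(n, rng),
        haplotypes=hap,
        genetic_value=gv,
        phenotype=phenotypes(gv, model, rng),
        status=classify_carriers(hap, lethal),
        sire=np.full(n, -1, dtype=np.int64),
        dam=np.full(n, -1, dtype=np.int64),
    )


def advance_generation(
    cohort: Cohort,
    gmap: GeneticMap,
    arch: TraitArchitecture,
    lethal: LethalSpec,
    model: PhenotypeModel,
    policy: ManagementPolicy,
    config: BreedingConfig,
    rng: np.random.Generator,
) -> Cohort:
    """One full generation step; the previous cohort leaves the breeding pool."""
    selection = select_sires(cohort, policy, config)
    quotas = allocate_offspring(selection, cohort, config)
    sire_rows, dam_rows = mate(selection, quotas, cohort, policy, rng)

    paternal = recombine_gametes(cohort.haplotypes[sire_rows], gmap, rng)
    maternal = recombine_gametes(cohort.haplotypes[dam_rows], gmap, rng)
    hap = np.stack([paternal, maternal], axis=1)

    gv = genetic_values(hap, arch)
    n = hap.shape[0]
    return Cohort(
        generation=cohort.generation + 1,
        ids=_make_ids(cohort.generation + 1, n),
        sex=_assign_sexes(n, rng),
        haplotypes=hap,
        genetic_value=gv,
        phenotype=phenotypes(gv, model, rng),
        status=classify_carriers(hap, lethal),
        sire=cohort.ids[sire_rows],
        dam=cohort.ids[dam_rows],
    )
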