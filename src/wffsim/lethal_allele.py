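"""Recessive lethal allele: locus choice, carrier status, lethality.

The lethal allele is fully recessive and fully penetrant: homozygotes are
"affected" and never breed, heterozygotes ("carriers") are viable.  The
locus is picked from founders with an observed carrier frequency of about
0.10 (window 0.08-0.12), in one of three modes:

``neutral``
    a uniformly random eligible neutral locus - no trait effects, no
    balancing selection;
``balancing``
    the eligible QTL whose effect on breeding goal 1 is largest - its own
    favorable effect opposes the lethality, the balancing-selection setup;
``wffs_like``
    as ``balancing``, but the locus's trait effects are replaced by exactly
    +7 index units per allele copy on goal 1 and 0 on goal 2, matching the
    estimated carrier-genotype association for dressage-type traits.
"""

from __future__ import annotations

import dataclasses
from typing import Union

import numpy as np

from .founder_genomes import (
    NEUTRAL,
    QTL,
    FounderPopulation,
    GeneticMap,
    candidate_lethal_loci,
    carrier_frequency_at_locus,
)
from .trait_model import TraitArchitecture

__all__ = [
    "NONCARRIER",
    "CARRIER",
    "AFFECTED",
    "LethalSpec",
    "LETHAL_MODES",
    "WFFS_EFFECT_OVERRIDE",
    "choose_lethal_locus",
    "classify_carriers",
    "viability_filter",
    "apply_wffs_override",
]

# Carrier status codes (== lethal-allele dosage).
NONCARRIER = 0
CARRIER = 1
AFFECTED = 2

LETHAL_MODES = ("neutral", "balancing", "wffs_like")

# Index-unit effect per copy of the lethal allele in wffs_like mode:
# +7 on goal 1, none on goal 2.  Because homozygotes never breed, this makes
# the carrier-vs-noncarrier contrast exactly +7 index units on goal 1.
WFFS_EFFECT_OVERRIDE = (7.0, 0.0)


@dataclasses.dataclass(frozen=True)
class LethalSpec:
    """Chosen lethal locus and how it interacts with the trait model."""

    locus: int  # row index in the map the spec was chosen on
    locus_id: int  # stable map identifier
    mode: str
    founder_carrier_freq: float
    carrier_window: tuple[float, float] = (0.08, 0.12)
    effect_override: tuple[float, float] | None = None  # index units per copy

    def remap(self, gmap: GeneticMap) -> "LethalSpec":
        row = int(gmap.rows_for_locus_ids(np.array([self.locus_id]))[0])
        return dataclasses.replace(self, locus=row)

    def to_manifest(self) -> dict:
        return {
            "locus_id": int(self.locus_id),
            "mode": self.mode,
            "founder_carrier_freq": float(self.founder_carrier_freq),
            "carrier_window": list(self.carrier_window),
            "effect_override": None
            if self.effect_override is None
            else list(self.effect_override),
        }


def choose_lethal_locus(
    pop: FounderPopulation,
    gmap: GeneticMap,
    arch: TraitArchitecture,
    mode: str = "neutral",
    seed: Union[int, np.random.Generator, None] = None,
    carrier_window: tuple[float, float] = (0.08, 0.12),
) -> LethalSpec:
    """Pick the lethal locus for one simulation replicate.

    Raises :class:`~wffsim.founder_genomes.NoEligibleLethalLocusError` when
    no locus of the required category lies in the carrier window; the
    experiment runner resamples founders in that case.
    """
    if mode not in LETHAL_MODES:
        raise ValueError(f"mode must be one of {LETHAL_MODES}, got {mode!r}")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed

    if mode == "neutral":
        eligible = candidate_lethal_loci(pop, gmap, carrier_window, NEUTRAL)
        locus = int(rng.choice(eligible))
        override = None
    else:
        # "largest positive (favorable) effect" is only meaningful among
        # causative loci; the index gain is positive, so the argmax of the
        # raw goal-1 effect is the argmax on the index scale too.
        eligible = candidate_lethal_loci(pop, gmap, carrier_window, QTL)
        qtl_pos = gmap.rows_for_locus_ids(gmap.locus_id[eligible])
        effect_g1 = np.empty(eligible.size)
        row_of = {int(r): i for i, r in enumerate(arch.qtl_rows)}
        for i, r in enumerate(qtl_pos):
            effect_g1[i] = arch.effects[row_of[int(r)], 0]
        locus = int(eligible[int(np.argmax(effect_g1))])
        override = WFFS_EFFECT_OVERRIDE if mode == "wffs_like" else None

    return LethalSpec(
        locus=locus,
        locus_id=int(gmap.locus_id[locus]),
        mode=mode,
        founder_carrier_freq=carrier_frequency_at_locus(pop, locus),
        carrier_window=carrier_window,
        effect_override=override,
    )


def apply_wffs_override(arch: TraitArchitecture, spec: LethalSpec) -> TraitArchitecture:
    """Replace the lethal QTL's trait effects by the fixed index-unit override.

    The locus's raw bivariate effect is zeroed *before* scaling calibration,
    and the override is injected post-scaling so "+7" stays exactly +7 index
    units per allele copy.  Only the lethal locus's row changes.
    """
    if spec.effect_override is None:
        return arch
    pos = np.flatnonzero(arch.qtl_rows == spec.locus)
    if pos.size != 1:
        raise ValueError("override locus is not a QTL of this architecture")
    effects = arch.effects.copy()
    effects[pos[0], :] = 0.0
    return dataclasses.replace(
        arch,
        effects=effects,
        override_row=int(spec.locus),
        override_effects=np.asarray(spec.effect_override, dtype=float),
    )


def classify_carriers(haplotypes: np.ndarray, spec_or_locus: Union[LethalSpec, int]) -> np.ndarray:
    """Carrier status per individual from lethal-allele dosage.

    Dosage 0 -> NONCARRIER, 1 -> CARRIER, 2 -> AFFECTED.
    """
    locus = spec_or_locus.locus if isinstance(spec_or_locus, LethalSpec) else int(spec_or_locus)
    if haplotypes.ndim != 3 or haplotypes.shape[1] != 2:
        raise ValueError("haplotypes must have shape (n, 2, n_loci)")
    return (haplotypes[:, 0, locus] + haplotypes[:, 1, locus]).astype(np.int8)


def viability_filter(statuses: np.ndarray) -> np.ndarray:
    """Boolean mask of breeding-eligible individuals (not affected).

    Affected individuals stay in the cohort record (they are counted as
    born) but are never selectable as sires nor usable as dams.
    """
    return np.asarray(statuses) != AFFECTED
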