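"""Bivariate trait architecture, genetic values and phenotypes.

Two correlated breeding goals (goal 1 ~ dressage-type merit, goal 2 ~
show-jumping merit) are controlled by additive QTL whose effect pairs are
drawn from a bivariate normal distribution with correlation rho (default
0.3).  Raw genetic values are mapped by a frozen affine scaling onto the
index scale used in routine genetic evaluation: founder mean 100, founder
genetic standard deviation 20 per goal.  Phenotypes add independent normal
noise calibrated to heritability 0.3 on the founder genetic variance.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Optional, Union

import numpy as np
import pandas as pd

from .founder_genomes import GeneticMap

__all__ = [
    "INDEX_MEAN",
    "INDEX_SD",
    "TraitArchitecture",
    "PhenotypeModel",
    "draw_qtl_effects",
    "calibrate_scaling",
    "genetic_values",
    "phenotypes",
    "realized_genetic_correlation",
    "save_architecture",
]

INDEX_MEAN = 100.0
INDEX_SD = 20.0


@dataclasses.dataclass
class TraitArchitecture:
    """Additive QTL effects for the two breeding goals plus index scaling.

    ``qtl_locus_ids`` are stable locus identifiers from the genetic map;
    ``qtl_rows`` are the corresponding row indices into whatever map/hap
    matrix the architecture is currently attached to (remap with
    :meth:`remap` after subsetting loci).  ``effects`` are in raw
    (pre-scaling) units; ``offset``/``gain`` hold the frozen affine scaling
    per goal once :func:`calibrate_scaling` has run.

    ``override_row``/``override_effects`` implement a post-scaling additive
    override for one locus (used for the lethal allele in the
    effect-override scenario): each copy of the derived allele at that locus
    adds ``override_effects`` index units on top of the scaled genetic
    value.
    """

    qtl_locus_ids: np.ndarray  # (Q,) int64
    qtl_rows: np.ndarray  # (Q,) intp
    effects: np.ndarray  # (Q, 2) float64, raw units
    effect_correlation: float
    offset: Optional[np.ndarray] = None  # (2,)
    gain: Optional[np.ndarray] = None  # (2,)
    override_row: Optional[int] = None
    override_effects: Optional[np.ndarray] = None  # (2,) index units per allele copy

    @property
    def n_qtl(self) -> int:
        return int(self.qtl_rows.shape[0])

    @property
    def is_calibrated(self) -> bool:
        return self.offset is not None and self.gain is not None

    def remap(self, gmap: GeneticMap) -> "TraitArchitecture":
        """Re-attach QTL rows (and the override row) to a subset map."""
        rows = gmap.rows_for_locus_ids(self.qtl_locus_ids)
        override_row = self.override_row
        if override_row is not None:
            # override row is identified through its position in qtl rows
            pos = int(np.flatnonzero(self.qtl_rows == override_row)[0])
            override_row = int(rows[pos])
        return dataclasses.replace(self, qtl_rows=rows, override_row=override_row)


@dataclasses.dataclass(frozen=True)
class PhenotypeModel:
    """Additive phenotype model: genetic value plus normal noise.

    The environmental SD is fixed from the founder genetic SD (20 index
    units) and the heritability: sd_e = 20 * sqrt((1 - h2) / h2), about
    30.55 index units at h2 = 0.3.  It is *not* re-tuned as genetic
    variance erodes in later generations.
    """

    h2: tuple[float, float] = (0.3, 0.3)

    def __post_init__(self) -> None:
        for h in self.h2:
            if not 0.0 < h <= 1.0:
                raise ValueError(f"heritability must be in (0, 1], got {h}")

    @property
    def environmental_sd(self) -> np.ndarray:
        h2 = np.asarray(self.h2, dtype=float)
        return INDEX_SD * np.sqrt((1.0 - h2) / h2)


def draw_qtl_effects(
    gmap: GeneticMap,
    rho: float = 0.3,
    seed: Union[int, np.random.Generator, None] = None,
) -> TraitArchitecture:
    """Draw i.i.d. bivariate-normal effect pairs for every QTL on the map.

    Effects have zero mean, unit variance per goal, and correlation ``rho``.
    The returned architecture is uncalibrated (no index scaling yet).
    """
    if not abs(rho) < 1.0:
        raise ValueError(f"|rho| must be < 1, got {rho}")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    rows = gmap.qtl_indices
    z = rng.standard_normal((rows.size, 2))
    # Cholesky of [[1, rho], [rho, 1]]
    effects = np.column_stack([z[:, 0], rho * z[:, 0] + np.sqrt(1.0 - rho**2) * z[:, 1]])
    return TraitArchitecture(
        qtl_locus_ids=gmap.locus_id[rows].copy(),
        qtl_rows=rows.astype(np.intp),
        effects=effects,
        effect_correlation=float(rho),
    )


def _dosages(haplotypes: np.ndarray, rows: np.ndarray) -> np.ndarray:
    """Allele dosages (0/1/2) at the given loci for (n, 2, L) haplotypes."""
    if haplotypes.ndim != 3 or haplotypes.shape[1] != 2:
        raise ValueError("haplotypes must have shape (n, 2, n_loci)")
    if rows.size and rows.max() >= haplotypes.shape[2]:
        raise ValueError("haplotypes do not cover all requested loci")
    return haplotypes[:, 0, :][:, rows] + haplotypes[:, 1, :][:, rows]


def genetic_values(haplotypes: np.ndarray, arch: TraitArchitecture) -> np.ndarray:
    """Per-individual genetic value pair on the index scale.

    Purely additive: scaled dot product of allele dosage with QTL effects,
    plus the optional post-scaling per-copy override at one locus.
    Requires a calibrated architecture.
    """
    if not arch.is_calibrated:
        raise ValueError("architecture not calibrated; run calibrate_scaling first")
    raw = _dosages(haplotypes, arch.qtl_rows).astype(np.float64) @ arch.effects
    gv = arch.offset + arch.gain * raw
    if arch.override_row is not None:
        dos = (
            haplotypes[:, 0, arch.override_row] + haplotypes[:, 1, arch.override_row]
        ).astype(np.float64)
        gv = gv + dos[:, None] * arch.override_effects
    return gv


def calibrate_scaling(
    arch: TraitArchitecture,
    founder_haplotypes: np.ndarray,
    target_mean: float = INDEX_MEAN,
    target_sd: float = INDEX_SD,
) -> TraitArchitecture:
    """Freeze the affine index scaling on the founder cohort.

    Chooses offset and gain per goal such that founder genetic values have
    exactly ``target_mean`` and population SD ``target_sd``.  The constants
    are frozen: later cohorts are mapped with the same scaling and will in
    general not re-center (that is the point - genetic trend is visible on
    the index scale).

    The post-scaling override locus (if any) is excluded from calibration so
    its effect stays in exact index units.
    """
    raw = _dosages(founder_haplotypes, arch.qtl_rows).astype(np.float64) @ arch.effects
    sd = raw.std(axis=0)  # population SD, ddof=0
    if np.any(sd <= 0):
        raise ValueError("degenerate architecture: zero raw genetic variance")
    gain = target_sd / sd
    offset = target_mean - gain * raw.mean(axis=0)
    return dataclasses.replace(arch, offset=offset, gain=gain)


def phenotypes(
    gv: np.ndarray,
    model: PhenotypeModel,
    seed: Union[int, np.random.Generator, None] = None,
) -> np.ndarray:
    """Phenotype pair: genetic value plus independent normal noise per goal."""
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    sd = model.environmental_sd
    return gv + rng.standard_normal(gv.shape) * sd


def realized_genetic_correlation(gv: np.ndarray) -> float:
    """Pearson correlation of the two true genetic values across a cohort.

    Returns NaN when either goal has zero variance (the correlation is then
    undefined).
    """
    if gv.shape[0] < 3:
        raise ValueError("need at least 3 individuals")
    sds = gv.std(axis=0)
    if np.any(sds == 0):
        return float("nan")
    return float(np.corrcoef(gv[:, 0], gv[:, 1])[0, 1])


def save_architecture(arch: TraitArchitecture, gmap: GeneticMap, path: Union[str, Path]) -> None:
    """Export the architecture as TSV (locus, chromosome, position, effects)."""
    rows = arch.qtl_rows
    pd.DataFrame(
        {
            "locus_id": arch.qtl_locus_ids,
            "chromosome": gmap.chromosome[rows],
            "position_cM": gmap.position_cm[rows],
            "effect_goal1": arch.effects[:, 0],
            "effect_goal2": arch.effects[:, 1],
        }
    ).to_csv(path, sep="\t", index=False)
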