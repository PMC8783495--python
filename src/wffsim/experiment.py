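"""Scenario composition, replicate batches and trajectory summaries.

A scenario is (lethal mode) x (management policy) x (breeding constants).
Each replicate simulates 20 discrete generations from a fresh founder
population and records per-generation statistics; an experiment repeats the
scenario (default 100 replicates) and summarizes each statistic as the mean
and the 5th/95th percentiles across replicates.

Replicate seeds are derived deterministically from the scenario base seed
through ``numpy.random.SeedSequence([base_seed, replicate, attempt])``, so a
(scenario, seed) pair reproduces every trajectory bit-identically, and
founder resampling (when no locus falls in the lethal carrier window) is
itself reproducible.

Performance note: once the lethal locus is chosen, only the causative loci
plus the lethal locus are tracked through meiosis.  Untracked neutral loci
have no trait effects and enter no reported statistic, so dropping them
changes no output; in balancing/wffs modes (where the lethal is itself a
QTL) founders are sampled at causative loci only, which is distributionally
identical because founder loci are independent given the map.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Optional, Union

import numpy as np
import pandas as pd
import yaml

from . import breeding_engine as be
from . import founder_genomes as fg
from . import lethal_allele as la
from . import trait_model as tm

__all__ = [
    "ScenarioConfig",
    "ExperimentResult",
    "run_replicate",
    "run_experiment",
    "summarize",
    "top_fraction_carrier_freq",
    "cohort_statistics",
    "STATISTICS",
]

STATISTICS = (
    "n_born",
    "n_affected",
    "carrier_freq",
    "mean_gv_goal1",
    "mean_gv_goal2",
    "genetic_correlation",
    "top10pct_carrier_freq_goal1",
    "top10pct_carrier_freq_goal2",
)

MAX_FOUNDER_ATTEMPTS = 100


@dataclasses.dataclass(frozen=True)
class ScenarioConfig:
    """Everything that determines one simulation experiment.

    A (scenario, base_seed, replicate index) triple fully determines a
    replicate trajectory.
    """

    lethal_mode: str = "neutral"  # neutral | balancing | wffs_like
    policy: be.ManagementPolicy = dataclasses.field(default_factory=be.ManagementPolicy)
    breeding: be.BreedingConfig = dataclasses.field(default_factory=be.BreedingConfig)
    phenotype_model: tm.PhenotypeModel = dataclasses.field(default_factory=tm.PhenotypeModel)
    effect_correlation: float = 0.3
    carrier_window: tuple[float, float] = (0.08, 0.12)
    n_chromosomes: int = 30
    chrom_length: float = 100.0
    n_qtl_per_chrom: int = 3
    n_neutral_per_chrom: int = 400
    spectrum: fg.SpectrumSpec = "generic"
    n_replicates: int = 100
    n_generations: int = 20
    base_seed: int = 0

    def __post_init__(self) -> None:
        if self.lethal_mode not in la.LETHAL_MODES:
            raise ValueError(f"lethal_mode must be one of {la.LETHAL_MODES}")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")

    def to_manifest(self) -> dict:
        return {
            "lethal_mode": self.lethal_mode,
            "policy": {"mode": self.policy.mode, "exemption_top_k": self.policy.exemption_top_k},
            "breeding": dataclasses.asdict(self.breeding),
            "heritability": list(self.phenotype_model.h2),
            "effect_correlation": self.effect_correlation,
            "carrier_window": list(self.carrier_window),
            "genome": {
                "n_chromosomes": self.n_chromosomes,
                "chrom_length_cM": self.chrom_length,
                "n_qtl_per_chrom": self.n_qtl_per_chrom,
                "n_neutral_per_chrom": self.n_neutral_per_chrom,
                "spectrum": str(self.spectrum),
            },
            "n_replicates": self.n_replicates,
            "n_generations": self.n_generations,
            "base_seed": self.base_seed,
        }


@dataclasses.dataclass
class ExperimentResult:
    scenario: ScenarioConfig
    replicates: pd.DataFrame  # long: replicate, generation, one column per statistic
    summary: pd.DataFrame  # long: generation, statistic, mean, p5, p95
    lethal_specs: list[la.LethalSpec]

    def save(self, outdir: Union[str, Path]) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.replicates.to_csv(outdir / "replicates.csv", index=False)
        self.summary.to_csv(outdir / "summary.csv", index=False)
        manifest = self.scenario.to_manifest()
        manifest["lethal_specs"] = [s.to_manifest() for s in self.lethal_specs]
        with open(outdir / "manifest.yaml", "w") as fh:
            yaml.safe_dump(manifest, fh, sort_keys=False)


def top_fraction_carrier_freq(
    phenotype: np.ndarray, status: np.ndarray, goal: int, fraction: float = 0.10
) -> float:
    """Carrier share among the top ``fraction`` of individuals for a goal.

    Individuals are ranked by phenotype for the goal (selection in this
    program is phenotypic); the top ``ceil(fraction * n)`` are kept.
    """
    if not 0.0 < fraction <= 1.0:
        raise ValueError(f"fraction must be in (0, 1], got {fraction}")
    n = phenotype.shape[0]
    if n == 0:
        raise ValueError("empty cohort")
    k = int(np.ceil(fraction * n))
    top = np.argsort(-phenotype[:, goal], kind="stable")[:k]
    return float(np.mean(status[top] == la.CARRIER))


def cohort_statistics(cohort: be.Cohort) -> dict[str, float]:
    """The per-generation statistics recorded along a trajectory."""
    return {
        "n_born": float(cohort.n),
        "n_affected": float(np.sum(cohort.status == la.AFFECTED)),
        "carrier_freq": float(np.mean(cohort.status == la.CARRIER)),
        "mean_gv_goal1": float(cohort.genetic_value[:, 0].mean()),
        "mean_gv_goal2": float(cohort.genetic_value[:, 1].mean()),
        "genetic_correlation": tm.realized_genetic_correlation(cohort.genetic_value),
        "top10pct_carrier_freq_goal1": top_fraction_carrier_freq(
            cohort.phenotype, cohort.status, goal=0
        ),
        "top10pct_carrier_freq_goal2": top_fraction_carrier_freq(
            cohort.phenotype, cohort.status, goal=1
        ),
    }


def _build_replicate_start(
    scenario: ScenarioConfig, rng: np.random.Generator
) -> tuple[fg.GeneticMap, tm.TraitArchitecture, la.LethalSpec, fg.FounderPopulation]:
    """Map, calibrated architecture, lethal spec and founders at tracked loci.

    Raises :class:`~wffsim.founder_genomes.NoEligibleLethalLocusError` if
    the sampled founders offer no locus in the carrier window.
    """
    gmap = fg.build_genetic_map(
        scenario.n_chromosomes,
        scenario.chrom_length,
        scenario.n_qtl_per_chrom,
        scenario.n_neutral_per_chrom,
        rng,
    )
    n_founders = scenario.breeding.n_offspring  # one full cohort, 50:50 sexes
    qtl_map = gmap.subset(gmap.qtl_indices)

    if scenario.lethal_mode == "neutral":
        # Founders are materialized at causative loci; the neutral lethal
        # locus and its genotype column come from the count-based sampler
        # (distributionally identical to the full-matrix path, see
        # sample_neutral_lethal_column).
        qtl_pop = fg.sample_founder_haplotypes(qtl_map, n_founders, scenario.spectrum, rng)
        arch = tm.draw_qtl_effects(gmap, scenario.effect_correlation, rng)
        locus_row, column, _, founder_cf = fg.sample_neutral_lethal_column(
            gmap, n_founders, scenario.spectrum, scenario.carrier_window, rng
        )
        tracked_rows = np.sort(np.append(gmap.qtl_indices, locus_row))
        tracked_map = gmap.subset(tracked_rows)
        insert_at = int(np.searchsorted(tracked_rows, locus_row))
        hap = np.insert(qtl_pop.haplotypes, insert_at, column, axis=1)
        pop = fg.FounderPopulation(
            haplotypes=hap, locus_frequencies=hap.mean(axis=0), n_founders=n_founders
        )
        lethal = la.LethalSpec(
            locus=insert_at,
            locus_id=int(gmap.locus_id[locus_row]),
            mode="neutral",
            founder_carrier_freq=founder_cf,
            carrier_window=scenario.carrier_window,
        )
        arch = arch.remap(tracked_map)
    else:
        pop = fg.sample_founder_haplotypes(qtl_map, n_founders, scenario.spectrum, rng)
        arch = tm.draw_qtl_effects(qtl_map, scenario.effect_correlation, rng)
        lethal = la.choose_lethal_locus(
            pop, qtl_map, arch, scenario.lethal_mode, rng, scenario.carrier_window
        )
        tracked_map = qtl_map  # the lethal is itself a QTL; all loci tracked
        arch = arch.remap(tracked_map)
        lethal = lethal.remap(tracked_map)
    if lethal.effect_override is not None:
        arch = la.apply_wffs_override(arch, lethal)
    founder_hap = pop.haplotypes.reshape(pop.n_founders, 2, pop.n_loci)
    arch = tm.calibrate_scaling(arch, founder_hap)
    return tracked_map, arch, lethal, pop


def run_replicate(
    scenario: ScenarioConfig, replicate_index: int
) -> tuple[pd.DataFrame, la.LethalSpec]:
    """One replicate: generation-0 baseline plus ``n_generations`` steps.

    Returns the per-generation statistics table and the lethal-locus spec
    actually used (including the founder carrier frequency).
    """
    lethal = None
    for attempt in range(MAX_FOUNDER_ATTEMPTS):
        rng = np.random.default_rng(
            np.random.SeedSequence([int(scenario.base_seed), int(replicate_index), attempt])
        )
        try:
            gmap, arch, lethal, pop = _build_replicate_start(scenario, rng)
            break
        except fg.NoEligibleLethalLocusError:
            continue
    if lethal is None:
        raise RuntimeError(
            f"no eligible lethal locus in {MAX_FOUNDER_ATTEMPTS} founder samples "
            f"(replicate {replicate_index})"
        )

    cohort = be.founder_cohort(pop, arch, lethal, scenario.phenotype_model, rng)
    rows = [{"generation": 0, **cohort_statistics(cohort)}]
    for _ in range(scenario.n_generations):
        cohort = be.advance_generation(
            cohort, gmap, arch, lethal, scenario.phenotype_model,
            scenario.policy, scenario.breeding, rng,
        )
        rows.append({"generation": cohort.generation, **cohort_statistics(cohort)})
    df = pd.DataFrame(rows)
    df.insert(0, "replicate", replicate_index)
    return df, lethal


def summarize(replicates: pd.DataFrame, percentiles: tuple[float, float] = (5.0, 95.0)) -> pd.DataFrame:
    """Pointwise mean and empirical percentiles across replicates.

    Percentiles use the linear-interpolation definition (numpy default).
    Input must contain every generation for every replicate (no ragged
    trajectories).
    """
    counts = replicates.groupby("replicate")["generation"].count()
    if counts.nunique() > 1:
        raise ValueError("ragged input: replicates differ in trajectory length")
    lo, hi = percentiles
    records = []
    stats = [c for c in replicates.columns if c not in ("replicate", "generation")]
    grouped = replicates.groupby("generation")
    for gen, block in grouped:
        for stat in stats:
            vals = block[stat].to_numpy(float)
            records.append(
                {
                    "generation": gen,
                    "statistic": stat,
                    "mean": float(np.nanmean(vals)),
                    f"p{lo:g}": float(np.nanpercentile(vals, lo)),
                    f"p{hi:g}": float(np.nanpercentile(vals, hi)),
                }
            )
    return pd.DataFrame(records)


def run_experiment(
    scenario: ScenarioConfig,
    percentiles: tuple[float, float] = (5.0, 95.0),
    progress: bool = False,
) -> ExperimentResult:
    """Run all replicates of a scenario and summarize the trajectories."""
    if scenario.n_replicates < 2:
        raise ValueError("n_replicates must be >= 2 for an experiment summary")
    frames, specs = [], []
    for rep in range(scenario.n_replicates):
        df, spec = run_replicate(scenario, rep)
        frames.append(df)
        specs.append(spec)
        if progress:  # pragma: no cover - cosmetic
            print(f"replicate {rep + 1}/{scenario.n_replicates} done", flush=True)
    replicates = pd.concat(frames, ignore_index=True)
    return ExperimentResult(
        scenario=scenario,
        replicates=replicates,
        summary=summarize(replicates, percentiles),
        lethal_specs=specs,
    )
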