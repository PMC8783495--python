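"""Genetic maps and founder haplotypes.

The breeding simulation starts from a founder population of biallelic
haplotypes laid out on a multi-chromosome genetic map.  Each chromosome
carries a small number of causative loci (QTL) for the two breeding goals
and a larger set of neutral loci with no trait effects; the neutral set is
the candidate pool for a recessive lethal allele that is independent of the
breeding goals.

Instead of running a coalescent simulator, founder allele frequencies are
drawn from a truncated neutral-like site frequency spectrum (density
proportional to 1/q on the segregating range) and alleles are assigned
independently across loci and haplotypes.  Founders therefore carry no
background linkage disequilibrium; linkage builds up in later generations
through meiosis on the genetic map.  Externally generated haplotypes (e.g.
from a coalescent program) can be imported via :func:`load_founders` for
users who need founder LD.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Callable, Sequence, Union

import numpy as np
import pandas as pd

__all__ = [
    "NEUTRAL",
    "QTL",
    "GeneticMap",
    "FounderPopulation",
    "build_genetic_map",
    "sample_founder_haplotypes",
    "carrier_frequency_at_locus",
    "carrier_frequencies",
    "candidate_lethal_loci",
    "sample_neutral_lethal_column",
    "NoEligibleLethalLocusError",
    "save_map",
    "load_map",
    "save_founders",
    "load_founders",
]

# Locus categories (stored as int8 codes).
NEUTRAL = 0
QTL = 1

_CATEGORY_NAMES = {NEUTRAL: "neutral", QTL: "qtl"}
_CATEGORY_CODES = {v: k for k, v in _CATEGORY_NAMES.items()}


class NoEligibleLethalLocusError(RuntimeError):
    """No locus satisfies the requested carrier-frequency window.

    Callers (the experiment runner) react by resampling founders with a
    fresh seed rather than widening the window.
    """


@dataclasses.dataclass(frozen=True)
class GeneticMap:
    """Positions and categories of all simulated loci.

    Loci are sorted by (chromosome, position).  ``locus_id`` is a stable
    identifier that survives :meth:`subset`, so trait architectures built on
    the full map can be remapped onto a subset of tracked loci.
    """

    chromosome: np.ndarray  # (L,) int32, 0-based chromosome index
    position_cm: np.ndarray  # (L,) float64, position in centimorgan
    category: np.ndarray  # (L,) int8, NEUTRAL or QTL
    locus_id: np.ndarray  # (L,) int64, stable identifiers
    n_chromosomes: int
    chrom_length: float  # cM, identical for all chromosomes

    @property
    def n_loci(self) -> int:
        return int(self.chromosome.shape[0])

    @property
    def qtl_indices(self) -> np.ndarray:
        """Row indices of causative loci, in map order."""
        return np.flatnonzero(self.category == QTL)

    @property
    def neutral_indices(self) -> np.ndarray:
        return np.flatnonzero(self.category == NEUTRAL)

    def chromosome_slices(self) -> list[slice]:
        """Contiguous row slice per chromosome (loci are sorted)."""
        bounds = np.searchsorted(self.chromosome, np.arange(self.n_chromosomes + 1))
        return [slice(int(bounds[c]), int(bounds[c + 1])) for c in range(self.n_chromosomes)]

    def subset(self, indices: np.ndarray) -> "GeneticMap":
        """Map restricted to ``indices`` (kept in map order)."""
        idx = np.sort(np.asarray(indices, dtype=np.intp))
        return GeneticMap(
            chromosome=self.chromosome[idx],
            position_cm=self.position_cm[idx],
            category=self.category[idx],
            locus_id=self.locus_id[idx],
            n_chromosomes=self.n_chromosomes,
            chrom_length=self.chrom_length,
        )

    def rows_for_locus_ids(self, locus_ids: np.ndarray) -> np.ndarray:
        """Row indices in this map for the given stable ``locus_id`` values."""
        lookup = {int(l): i for i, l in enumerate(self.locus_id)}
        try:
            return np.array([lookup[int(l)] for l in np.atleast_1d(locus_ids)], dtype=np.intp)
        except KeyError as err:  # pragma: no cover - defensive
            raise KeyError(f"locus_id {err} not present in this map") from None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "locus_id": self.locus_id,
                "chromosome": self.chromosome,
                "position_cM": self.position_cm,
                "category": [_CATEGORY_NAMES[int(c)] for c in self.category],
            }
        )

    def validate(self) -> None:
        if self.n_loci == 0:
            raise ValueError("empty genetic map")
        order = np.lexsort((self.position_cm, self.chromosome))
        if not np.array_equal(order, np.arange(self.n_loci)):
            raise ValueError("loci must be sorted by (chromosome, position)")
        if self.position_cm.min() < 0 or self.position_cm.max() > self.chrom_length:
            raise ValueError("locus positions must lie within [0, chrom_length]")
        for sl in self.chromosome_slices():
            pos = self.position_cm[sl]
            if np.unique(pos).size != pos.size:
                raise ValueError("locus positions must be distinct within a chromosome")


@dataclasses.dataclass
class FounderPopulation:
    """Founder haplotypes: ``(2 * n_founders, n_loci)`` matrix of 0/1 alleles.

    Rows ``2i`` and ``2i + 1`` are the two haplotypes of founder ``i``.
    ``locus_frequencies`` are the realized (column-mean) derived-allele
    frequencies; every locus is guaranteed segregating.
    """

    haplotypes: np.ndarray  # (2N, L) int8
    locus_frequencies: np.ndarray  # (L,) float64
    n_founders: int

    @property
    def n_loci(self) -> int:
        return int(self.haplotypes.shape[1])

    def subset_loci(self, indices: np.ndarray) -> "FounderPopulation":
        idx = np.sort(np.asarray(indices, dtype=np.intp))
        return FounderPopulation(
            haplotypes=np.ascontiguousarray(self.haplotypes[:, idx]),
            locus_frequencies=self.locus_frequencies[idx],
            n_founders=self.n_founders,
        )

    def validate(self) -> None:
        if self.haplotypes.shape[0] % 2 != 0:
            raise ValueError("haplotype count must be even")
        if self.haplotypes.shape[0] != 2 * self.n_founders:
            raise ValueError("haplotype rows must equal 2 * n_founders")
        freqs = self.haplotypes.mean(axis=0)
        if not np.allclose(freqs, self.locus_frequencies):
            raise ValueError("locus_frequencies must equal haplotype column means")
        if np.any(freqs <= 0) or np.any(freqs >= 1):
            raise ValueError("all loci must be segregating")


def build_genetic_map(
    n_chromosomes: int = 30,
    chrom_length: float = 100.0,
    n_qtl: int = 3,
    n_neutral: int = 400,
    seed: Union[int, np.random.Generator, None] = None,
) -> GeneticMap:
    """Draw a genetic map with uniform random locus positions.

    Each of the ``n_chromosomes`` chromosomes of ``chrom_length`` cM carries
    ``n_qtl`` causative loci and ``n_neutral`` neutral loci at uniformly
    drawn, distinct positions.

    Raises
    ------
    ValueError
        If any count is non-positive (``n_neutral`` may be zero) or
        ``chrom_length <= 0``.
    """
    if n_chromosomes < 1 or n_qtl < 1 or n_neutral < 0:
        raise ValueError(
            "n_chromosomes and n_qtl must be >= 1 and n_neutral >= 0; got "
            f"({n_chromosomes}, {n_qtl}, {n_neutral})"
        )
    if chrom_length <= 0:
        raise ValueError(f"chrom_length must be positive, got {chrom_length}")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed

    per_chrom = n_qtl + n_neutral
    chroms, positions, cats = [], [], []
    for c in range(n_chromosomes):
        pos = rng.uniform(0.0, chrom_length, size=per_chrom)
        while np.unique(pos).size != per_chrom:  # essentially never triggers
            pos = rng.uniform(0.0, chrom_length, size=per_chrom)
        cat = np.full(per_chrom, NEUTRAL, dtype=np.int8)
        cat[rng.choice(per_chrom, size=n_qtl, replace=False)] = QTL
        order = np.argsort(pos)
        chroms.append(np.full(per_chrom, c, dtype=np.int32))
        positions.append(pos[order])
        cats.append(cat[order])

    gmap = GeneticMap(
        chromosome=np.concatenate(chroms),
        position_cm=np.concatenate(positions),
        category=np.concatenate(cats),
        locus_id=np.arange(n_chromosomes * per_chrom, dtype=np.int64),
        n_chromosomes=n_chromosomes,
        chrom_length=float(chrom_length),
    )
    gmap.validate()
    return gmap


SpectrumSpec = Union[str, float, Callable[[np.random.Generator, int], np.ndarray]]


def _draw_spectrum(
    spectrum: SpectrumSpec, size: int, n_haplotypes: int, rng: np.random.Generator
) -> np.ndarray:
    """Per-locus derived-allele frequencies from a spectrum specification.

    ``"neutral"`` draws from density proportional to 1/q truncated to
    ``[1/(2N), 1 - 1/(2N)]`` (inverse-CDF sampling, constant-size
    population); ``"generic"`` draws from the frozen bottlenecked
    domestic-population spectrum (see :mod:`wffsim._generic_spectrum`);
    ``"fixed(x)"`` or a float gives every locus frequency x; a callable
    ``f(rng, size)`` is used verbatim.
    """
    lo = 1.0 / n_haplotypes
    hi = 1.0 - lo
    if callable(spectrum):
        q = np.asarray(spectrum(rng, size), dtype=float)
    elif isinstance(spectrum, (int, float)):
        q = np.full(size, float(spectrum))
    elif spectrum == "neutral":
        u = rng.random(size)
        q = lo * (hi / lo) ** u  # CDF of 1/q on [lo, hi] is log-linear
    elif spectrum == "generic":
        from ._generic_spectrum import GENERIC_SPECTRUM_QUANTILES as knots

        u = rng.random(size)
        q = np.interp(u * (knots.size - 1), np.arange(knots.size), knots)
        q = np.clip(q, lo, hi)
    elif spectrum.startswith("fixed(") and spectrum.endswith(")"):
        q = np.full(size, float(spectrum[len("fixed(") : -1]))
    else:
        raise ValueError(f"unknown frequency spectrum {spectrum!r}")
    if np.any(q <= 0.0) or np.any(q >= 1.0):
        raise ValueError("spectrum must place all mass strictly inside (0, 1)")
    return q


def sample_founder_haplotypes(
    gmap: GeneticMap,
    n_founders: int = 6000,
    spectrum: SpectrumSpec = "neutral",
    seed: Union[int, np.random.Generator, None] = None,
) -> FounderPopulation:
    """Sample founder haplotypes with independent loci.

    Each locus gets a derived-allele frequency from ``spectrum`` and alleles
    are Bernoulli draws, independent across loci and haplotypes.  Loci that
    come out monomorphic are redrawn (frequency and alleles) until the whole
    matrix is segregating, so the returned population always supports
    carrier-frequency windows.
    """
    if n_founders < 2:
        raise ValueError(f"n_founders must be >= 2, got {n_founders}")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed

    n_hap = 2 * n_founders
    L = gmap.n_loci
    q = _draw_spectrum(spectrum, L, n_hap, rng)
    # float32 uniforms: halves memory traffic for the (2N, L) draw without
    # changing the Bernoulli law at these frequency scales.
    hap = (rng.random((n_hap, L), dtype=np.float32) < q.astype(np.float32)).view(np.int8)

    for _ in range(1000):
        freqs = hap.mean(axis=0)
        mono = np.flatnonzero((freqs <= 0.0) | (freqs >= 1.0))
        if mono.size == 0:
            break
        q_new = _draw_spectrum(spectrum, mono.size, n_hap, rng)
        hap[:, mono] = (
            rng.random((n_hap, mono.size), dtype=np.float32) < q_new.astype(np.float32)
        ).view(np.int8)
    else:  # pragma: no cover
        raise RuntimeError("could not obtain segregating loci; spectrum too extreme")

    return FounderPopulation(haplotypes=hap, locus_frequencies=freqs, n_founders=n_founders)


def carrier_frequencies(pop: FounderPopulation) -> np.ndarray:
    """Fraction of heterozygous founders at every locus."""
    if pop.haplotypes.shape[0] % 2 != 0:
        raise ValueError("haplotype count must be even")
    het = pop.haplotypes[0::2, :] != pop.haplotypes[1::2, :]
    return het.mean(axis=0)


def carrier_frequency_at_locus(pop: FounderPopulation, locus: int) -> float:
    """Fraction of founders heterozygous at ``locus``."""
    if not 0 <= locus < pop.n_loci:
        raise IndexError(f"locus {locus} out of range for {pop.n_loci} loci")
    if pop.haplotypes.shape[0] % 2 != 0:
        raise ValueError("haplotype count must be even")
    col = pop.haplotypes[:, locus]
    return float(np.mean(col[0::2] != col[1::2]))


def candidate_lethal_loci(
    pop: FounderPopulation,
    gmap: GeneticMap,
    window: tuple[float, float] = (0.08, 0.12),
    category: Union[int, str] = NEUTRAL,
    require_minor: bool = True,
) -> np.ndarray:
    """Loci of ``category`` whose observed carrier frequency falls in ``window``.

    A carrier-frequency window is symmetric in the allele frequency: a
    window around 0.10 admits loci at derived frequency ~0.05 but also
    their mirror images at ~0.95, where most of the population would be
    homozygous for the derived allele.  A segregating recessive *lethal*
    must be the rare allele, so by default (``require_minor``) the derived
    allele is additionally required to be the minor one.

    Raises :class:`NoEligibleLethalLocusError` when the result is empty so
    that the experiment runner can resample founders.
    """
    low, high = window
    if not 0.0 <= low < high <= 1.0:
        raise ValueError(f"carrier window must satisfy 0 <= low < high <= 1, got {window}")
    if isinstance(category, str):
        category = _CATEGORY_CODES[category]
    cf = carrier_frequencies(pop)
    mask = (gmap.category == category) & (cf >= low) & (cf <= high)
    if require_minor:
        mask &= pop.locus_frequencies <= 0.5
    eligible = np.flatnonzero(mask)
    if eligible.size == 0:
        raise NoEligibleLethalLocusError(
            f"no {_CATEGORY_NAMES[int(category)]} locus with carrier frequency in "
            f"[{low}, {high}]; resample founders"
        )
    return eligible


def sample_neutral_lethal_column(
    gmap: GeneticMap,
    n_founders: int,
    spectrum: SpectrumSpec,
    window: tuple[float, float],
    rng: np.random.Generator,
) -> tuple[int, np.ndarray, float, float]:
    """Draw the neutral lethal locus and its founder genotype column directly.

    Count-based equivalent of sampling the full neutral haplotype matrix,
    computing carrier frequencies, and picking a uniformly random locus in
    the carrier window: under independent Bernoulli(q) alleles the per-locus
    genotype counts (n_het, n_hom_derived) are multinomial, eligibility
    depends only on n_het, and the column given its counts is an
    exchangeable assignment with uniform heterozygote phase.  Sampling in
    that factorized order (counts for every neutral locus, then one full
    column for the chosen locus) is therefore distributionally identical to
    the matrix path - including the redraw of monomorphic loci - while
    doing O(loci + founders) work instead of O(loci * founders).

    Returns ``(locus_row, column, q, carrier_freq)`` where ``column`` has
    shape ``(2 * n_founders,)`` in the same haplotype-pair layout as
    :class:`FounderPopulation`.

    Raises :class:`NoEligibleLethalLocusError` when no neutral locus lands
    in the carrier window.
    """
    low, high = window
    if not 0.0 <= low < high <= 1.0:
        raise ValueError(f"carrier window must satisfy 0 <= low < high <= 1, got {window}")
    neutral = gmap.neutral_indices
    if neutral.size == 0:
        raise NoEligibleLethalLocusError("map has no neutral loci")
    N = n_founders
    n_hap = 2 * N

    def draw_counts(size: int):
        q = _draw_spectrum(spectrum, size, n_hap, rng)
        p_het = 2.0 * q * (1.0 - q)
        n_het = rng.binomial(N, p_het)
        n_alt = rng.binomial(N - n_het, q * q / (1.0 - p_het))
        return q, n_het, n_alt

    q, n_het, n_alt = draw_counts(neutral.size)
    for _ in range(1000):
        mono = (n_het == 0) & ((n_alt == 0) | (n_alt == N))
        if not mono.any():
            break
        q[mono], n_het[mono], n_alt[mono] = draw_counts(int(mono.sum()))
    else:  # pragma: no cover
        raise RuntimeError("could not obtain segregating loci; spectrum too extreme")

    cf = n_het / N
    minor = (n_het + 2 * n_alt) <= N  # observed derived-allele frequency <= 0.5
    eligible = np.flatnonzero((cf >= low) & (cf <= high) & minor)
    if eligible.size == 0:
        raise NoEligibleLethalLocusError(
            f"no neutral locus with carrier frequency in [{low}, {high}]; resample founders"
        )
    pick = int(rng.choice(eligible))
    k_het, k_alt = int(n_het[pick]), int(n_alt[pick])

    col = np.zeros((N, 2), dtype=np.int8)
    perm = rng.permutation(N)
    het_rows = perm[:k_het]
    col[het_rows, rng.integers(0, 2, size=k_het)] = 1
    col[perm[k_het : k_het + k_alt], :] = 1
    return int(neutral[pick]), col.reshape(n_hap), float(q[pick]), k_het / N


# ---------------------------------------------------------------------------
# Plain-text import/export (hook for externally simulated founders)

def save_map(gmap: GeneticMap, path: Union[str, Path]) -> None:
    gmap.to_frame().to_csv(path, sep="\t", index=False)


def load_map(path: Union[str, Path], n_chromosomes: int | None = None, chrom_length: float | None = None) -> GeneticMap:
    df = pd.read_csv(path, sep="\t")
    gmap = GeneticMap(
        chromosome=df["chromosome"].to_numpy(np.int32),
        position_cm=df["position_cM"].to_numpy(float),
        category=np.array([_CATEGORY_CODES[c] for c in df["category"]], dtype=np.int8),
        locus_id=df["locus_id"].to_numpy(np.int64),
        n_chromosomes=n_chromosomes or int(df["chromosome"].max()) + 1,
        chrom_length=chrom_length or float(np.ceil(df["position_cM"].max())),
    )
    gmap.validate()
    return gmap


def save_founders(pop: FounderPopulation, path: Union[str, Path]) -> None:
    """One row per haplotype, tab-separated 0/1 alleles."""
    np.savetxt(path, pop.haplotypes, fmt="%d", delimiter="\t")


def load_founders(path: Union[str, Path]) -> FounderPopulation:
    hap = np.loadtxt(path, dtype=np.int8, delimiter="\t", ndmin=2)
    if hap.shape[0] % 2 != 0:
        raise ValueError("haplotype count must be even (two rows per founder)")
    freqs = hap.mean(axis=0)
    if np.any(freqs <= 0) or np.any(freqs >= 1):
        raise ValueError("imported founders contain monomorphic loci")
    return FounderPopulation(haplotypes=hap, locus_frequencies=freqs, n_founders=hap.shape[0] // 2)
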