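"""De-regressed breeding values and weighted carrier-genotype association.

Estimated breeding values (EBV, index scale: population mean 100, genetic
SD 20) mix an animal's own information with information from relatives.  To
associate a single genotyped locus with performance, each EBV is first
de-regressed: the parent-average contribution is removed and the shrinkage
toward the mean undone, yielding a pseudo-record (DEBV) that behaves like
an own performance with a known information content.  Records whose EBV is
parent average only carry no own information and are dropped.

The de-regression follows the information-splitting mixed-model-equations
approach: for animal i with parent-average reliability
r2_PA = (r2_sire + r2_dam) / 4 and lambda = (1 - h2) / h2,

    alpha   = 1 / (0.5 - r2_PA)
    delta   = (0.5 - r2_PA) / (1 - r2_i)
    Z'Z_PA  = lambda * (0.5 * alpha - 4) + 0.5 * lambda * sqrt(alpha^2 + 16 / delta)
    Z'Z_i   = delta * Z'Z_PA + 2 * lambda * (2 * delta - 1)

    y_i     = -2 * lambda * PA + (Z'Z_i + 2 * lambda) * u_i      (EBV deviations)
    DEBV_i  = y_i / Z'Z_i,      r2_DEBV = Z'Z_i / (Z'Z_i + lambda)

For an animal with unknown parents this reduces to simple de-regression
DEBV = u / r2 with Z'Z = lambda * r2 / (1 - r2).  Each DEBV enters a
weighted least-squares model

    DEBV ~ carrier genotype + 5-year birth period,
    w_i = (1 - h2) / ((c + (1 - r2_DEBV) / r2_DEBV) * h2)

where c (default 0.80) is the fraction of genetic variance not accounted
for by the marker.  Least-square means per genotype average the period
levels equally.
"""

from __future__ import annotations

import dataclasses
from typing import Optional, Union

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm

from .trait_model import INDEX_MEAN, INDEX_SD

__all__ = [
    "DEFAULT_C",
    "AssociationResult",
    "SyntheticEBVConfig",
    "parent_average_reliability",
    "garrick_information",
    "filter_pa_only",
    "deregress",
    "deregress_table",
    "record_weight",
    "split_subgroups",
    "assign_periods",
    "weighted_association",
    "generate_synthetic_ebv",
]

DEFAULT_C = 0.80
GENOTYPES = ("N/N", "WFFS/N")

#: Column contract for EBV record tables.
EBV_COLUMNS = (
    "animal", "sire", "dam", "trait", "ebv", "rel", "sire_rel", "dam_rel",
    "birth_year", "genotype", "ebv_show_jumping",
)


def parent_average_reliability(sire_rel, dam_rel):
    """r2_PA = (r2_sire + r2_dam) / 4; missing parent reliabilities count as 0."""
    s = np.nan_to_num(np.asarray(sire_rel, dtype=float))
    d = np.nan_to_num(np.asarray(dam_rel, dtype=float))
    return (s + d) / 4.0


def garrick_information(r2: np.ndarray, r2_pa: np.ndarray, lam: float):
    """Information contents (Z'Z_PA, Z'Z_i) for the de-regression equations.

    Vectorized; entries with r2_pa ~ 0 or r2 ~ 1 use the simple-deregression
    limit Z'Z = lambda * r2 / (1 - r2) (infinite for r2 = 1).
    """
    r2 = np.asarray(r2, dtype=float)
    r2_pa = np.asarray(r2_pa, dtype=float)
    if np.any(r2_pa >= 0.5):
        raise ValueError("parent-average reliability must be < 0.5")
    simple = (r2_pa <= 1e-12) | (r2 >= 1.0 - 1e-9)
    with np.errstate(divide="ignore", invalid="ignore"):
        alpha = 1.0 / (0.5 - r2_pa)
        delta = (0.5 - r2_pa) / (1.0 - r2)
        zpz_pa = lam * (0.5 * alpha - 4.0) + 0.5 * lam * np.sqrt(alpha**2 + 16.0 / delta)
        zpz = delta * zpz_pa + 2.0 * lam * (2.0 * delta - 1.0)
        zpz_simple = np.where(r2 >= 1.0 - 1e-9, np.inf, lam * r2 / np.maximum(1.0 - r2, 1e-300))
    zpz = np.where(simple, zpz_simple, zpz)
    zpz_pa = np.where(simple, 0.0, zpz_pa)
    return zpz_pa, zpz


def record_weight(r2_debv, h2: float, c: float = DEFAULT_C):
    """WLS weight w = (1 - h2) / ((c + (1 - r2_DEBV) / r2_DEBV) * h2)."""
    r2_debv = np.asarray(r2_debv, dtype=float)
    return (1.0 - h2) / ((c + (1.0 - r2_debv) / r2_debv) * h2)


def filter_pa_only(records: pd.DataFrame, tol: float = 1e-6) -> pd.DataFrame:
    """Drop records whose reliability does not exceed the parent average's.

    An EBV with r2 <= r2_PA (+ tol) contains no own information and cannot
    be de-regressed into a pseudo-record.
    """
    r2_pa = parent_average_reliability(records["sire_rel"], records["dam_rel"])
    return records.loc[records["rel"].to_numpy(float) > r2_pa + tol].copy()


def deregress(
    ebv: float,
    rel: float,
    sire_ebv: float = np.nan,
    dam_ebv: float = np.nan,
    sire_rel: float = np.nan,
    dam_rel: float = np.nan,
    h2: float = 0.3,
    c: float = DEFAULT_C,
) -> dict:
    """De-regress a single EBV; see the module docstring for the equations.

    Returns a dict with ``debv`` (index scale), ``debv_rel`` and ``weight``.
    Raises if the record should have been filtered (r2 <= r2_PA).
    """
    if not 0.0 < h2 < 1.0:
        raise ValueError(f"h2 must be in (0, 1), got {h2}")
    lam = (1.0 - h2) / h2
    r2_pa = float(parent_average_reliability(sire_rel, dam_rel))
    if rel <= r2_pa + 1e-12:
        raise ValueError(
            f"reliability {rel} does not exceed parent-average reliability {r2_pa}; "
            "record should have been removed by filter_pa_only"
        )
    u = ebv - INDEX_MEAN
    if r2_pa <= 1e-12:
        debv_dev = u / rel
        r2_debv = rel
    else:
        pa = (np.nan_to_num(sire_ebv - INDEX_MEAN) + np.nan_to_num(dam_ebv - INDEX_MEAN)) / 2.0
        _, zpz = garrick_information(np.array([rel]), np.array([r2_pa]), lam)
        zpz = float(zpz[0])
        y = -2.0 * lam * pa + (zpz + 2.0 * lam) * u
        debv_dev = y / zpz
        r2_debv = zpz / (zpz + lam)
    return {
        "debv": INDEX_MEAN + debv_dev,
        "debv_rel": r2_debv,
        "weight": float(record_weight(r2_debv, h2, c)),
    }


def deregress_table(
    records: pd.DataFrame,
    h2: float = 0.3,
    c: float = DEFAULT_C,
    parent_ebv: Optional[pd.DataFrame] = None,
) -> pd.DataFrame:
    """Vectorized de-regression of a filtered record table.

    ``records`` needs columns ``ebv``, ``rel``, ``sire_rel``, ``dam_rel``
    and (for animals with known parents) ``sire_ebv``/``dam_ebv``; those
    two can alternatively be merged in from ``parent_ebv`` (columns
    ``animal``, ``ebv``) via the ``sire``/``dam`` id columns.  Adds
    ``debv``, ``debv_rel`` and ``weight`` columns.
    """
    if not 0.0 < h2 < 1.0:
        raise ValueError(f"h2 must be in (0, 1), got {h2}")
    df = records.copy()
    if "sire_ebv" not in df.columns:
        if parent_ebv is not None:
            lookup = parent_ebv.set_index("animal")["ebv"]
            df["sire_ebv"] = df["sire"].map(lookup)
            df["dam_ebv"] = df["dam"].map(lookup)
        else:
            df["sire_ebv"] = np.nan
            df["dam_ebv"] = np.nan
    lam = (1.0 - h2) / h2
    r2 = df["rel"].to_numpy(float)
    r2_pa = parent_average_reliability(df["sire_rel"], df["dam_rel"])
    if np.any(r2 <= r2_pa + 1e-12):
        raise ValueError("records with r2 <= r2_PA present; run filter_pa_only first")
    u = df["ebv"].to_numpy(float) - INDEX_MEAN
    pa = (
        np.nan_to_num(df["sire_ebv"].to_numpy(float) - INDEX_MEAN)
        + np.nan_to_num(df["dam_ebv"].to_numpy(float) - INDEX_MEAN)
    ) / 2.0
    _, zpz = garrick_information(r2, r2_pa, lam)
    simple = r2_pa <= 1e-12
    perfect = np.isinf(zpz)  # r2 = 1: no shrinkage, PA carries no extra weight
    with np.errstate(invalid="ignore", over="ignore"):
        debv_dev = np.where(
            simple,
            u / r2,
            np.where(perfect, u, (-2.0 * lam * pa + (zpz + 2.0 * lam) * u) / zpz),
        )
        r2_debv = np.where(simple, r2, np.where(perfect, 1.0, zpz / (zpz + lam)))
    df["debv"] = INDEX_MEAN + debv_dev
    df["debv_rel"] = r2_debv
    df["weight"] = record_weight(r2_debv, h2, c)
    return df


def split_subgroups(records: pd.DataFrame) -> dict[str, pd.DataFrame]:
    """Partition records into show-jumping (SJ) and non-show-jumping (NS).

    SJ if the show-jumping EBV exceeds the reference population mean of
    100, otherwise NS (the boundary value 100 goes to NS).  Records with a
    missing show-jumping EBV are excluded with a warning.
    """
    sj_ebv = records["ebv_show_jumping"]
    missing = sj_ebv.isna()
    if missing.any():
        import warnings

        warnings.warn(
            f"excluded {int(missing.sum())} record(s) with missing show-jumping EBV",
            stacklevel=2,
        )
        records = records.loc[~missing]
        sj_ebv = records["ebv_show_jumping"]
    is_sj = sj_ebv.to_numpy(float) > INDEX_MEAN
    return {"NS": records.loc[~is_sj].copy(), "SJ": records.loc[is_sj].copy()}


def assign_periods(birth_year: np.ndarray, width: int = 5) -> np.ndarray:
    """Birth-year periods of ``width`` years, anchored at the earliest year."""
    birth_year = np.asarray(birth_year, dtype=int)
    return (birth_year - birth_year.min()) // width


@dataclasses.dataclass(frozen=True)
class AssociationResult:
    """Weighted fixed-effects fit of DEBV on carrier genotype + birth period."""

    trait: str
    n_by_genotype: dict
    contrast: float  # WFFS/N minus N/N, index units
    se: float
    p_genotype: float
    p_period: float
    lsm: dict  # genotype -> (least-square mean, SE)


def weighted_association(
    data: pd.DataFrame,
    trait: str = "trait",
    debv_col: str = "debv",
    weight_col: str = "weight",
) -> AssociationResult:
    """Weighted least squares of DEBV on genotype and birth period.

    ``data`` needs columns ``debv``, ``weight``, ``genotype`` (values
    "N/N"/"WFFS/N") and ``period`` (categorical birth period).  Least-square
    means per genotype average the period levels with equal weight; the
    genotype p-value is the two-sided t-test of the contrast from the
    weighted normal equations, and the period p-value is the joint F-test
    of all period coefficients.
    """
    geno = data["genotype"].to_numpy()
    levels = [g for g in GENOTYPES if g in geno]
    if len(levels) < 2:
        raise ValueError("need both genotype classes present")
    periods = np.sort(data["period"].unique())
    if periods.size < 1:
        raise ValueError("need at least one birth period")

    carrier = (geno == "WFFS/N").astype(float)
    X = [np.ones(len(data)), carrier]
    names = ["intercept", "carrier"]
    for p in periods[1:]:
        X.append((data["period"].to_numpy() == p).astype(float))
        names.append(f"period_{p}")
    X = np.column_stack(X)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError(
            "confounded design: carrier genotype is aliased with birth period "
            f"(periods {periods.tolist()})"
        )

    y = data[debv_col].to_numpy(float)
    w = data[weight_col].to_numpy(float)
    if np.any(w <= 0):
        raise ValueError("weights must be strictly positive")
    res = sm.WLS(y, X, weights=w).fit()

    n_periods = periods.size
    L_nn = np.zeros(X.shape[1])
    L_nn[0] = 1.0
    L_nn[2:] = 1.0 / n_periods
    L_carrier = L_nn.copy()
    L_carrier[1] = 1.0
    cov = res.cov_params()
    lsm = {}
    for g, L in (("N/N", L_nn), ("WFFS/N", L_carrier)):
        lsm[g] = (float(L @ res.params), float(np.sqrt(L @ cov @ L)))

    if n_periods > 1:
        R = np.zeros((n_periods - 1, X.shape[1]))
        for i in range(n_periods - 1):
            R[i, 2 + i] = 1.0
        p_period = float(res.f_test(R).pvalue)
    else:
        p_period = np.nan

    return AssociationResult(
        trait=trait,
        n_by_genotype={g: int(np.sum(geno == g)) for g in levels},
        contrast=float(res.params[1]),
        se=float(res.bse[1]),
        p_genotype=float(res.pvalues[1]),
        p_period=p_period,
        lsm=lsm,
    )


# ---------------------------------------------------------------------------
# Synthetic pedigreed EBV records with known truth

@dataclasses.dataclass(frozen=True)
class SyntheticEBVConfig:
    """Generator settings for synthetic EBV records with a known carrier effect.

    Defaults mirror the dressage-type (NS) subgroup of the motivating data:
    about 621 analyzable animals, carrier fraction 0.106, heritability 0.3,
    marker-unexplained genetic fraction c = 0.80, and an additive carrier
    contrast of +7.46 index units on a 100/20-scaled trait.
    """

    n_animals: int = 621
    delta: float = 7.46  # true carrier-vs-noncarrier contrast, index units
    carrier_frequency: float = 0.106
    h2: float = 0.3
    c: float = DEFAULT_C
    reliability_range: tuple[float, float] = (0.6, 0.9)
    parent_reliability_range: tuple[float, float] = (0.3, 0.7)
    pa_only_fraction: float = 0.2
    known_parent_fraction: float = 0.7  # among non-PA-only animals
    n_periods: int = 6
    period_trend: float = 2.0  # index units of genetic gain per 5-year period
    base_year: int = 1990
    trait: str = "dressage"

    def __post_init__(self) -> None:
        for p in (self.carrier_frequency, self.pa_only_fraction, self.known_parent_fraction):
            if not 0.0 <= p <= 1.0:
                raise ValueError("proportions must lie in [0, 1]")
        if not 0.0 < self.h2 < 1.0:
            raise ValueError("h2 must be in (0, 1)")


def generate_synthetic_ebv(
    config: SyntheticEBVConfig = SyntheticEBVConfig(),
    seed: Union[int, np.random.Generator, None] = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate pedigreed EBV records with a known additive carrier effect.

    True breeding values have genetic SD 20 around a per-period trend (the
    5-year birth-cohort effect) and carriers get ``delta`` added.  The EBV
    of an animal with own information is built by running the
    mixed-model-equations blend *forward*: a pseudo-record
    ``DEBV* = TBV + e`` with the information content implied by the
    animal's reliability is combined with the parent average exactly as the
    de-regression assumes, so :func:`deregress_table` recovers ``DEBV*``
    and the association analysis sees an unbiased, correctly weighted
    response.  For an animal with unknown parents this reduces to
    ``EBV_dev = r2 * TBV + noise`` with noise variance
    ``r2 * (1 - r2) * 400``, the marginal BLUP property.  PA-only animals
    (reliability equal to the parent average's) are emitted for the filter
    to remove and flagged in the truth table.

    Returns ``(records, truth)``: records follow the EBV column contract;
    truth holds tbv deviation, carrier flag, pa_only flag and period.
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    cfg = config
    n = cfg.n_animals
    lam = (1.0 - cfg.h2) / cfg.h2
    var_a = INDEX_SD**2

    carrier = rng.random(n) < cfg.carrier_frequency
    u_cat = rng.random(n)
    pa_only = u_cat < cfg.pa_only_fraction
    has_parents = pa_only | (
        u_cat < cfg.pa_only_fraction + cfg.known_parent_fraction * (1 - cfg.pa_only_fraction)
    )

    period = rng.integers(0, cfg.n_periods, size=n)
    period_effect = cfg.period_trend * period
    birth_year = cfg.base_year + 5 * period + rng.integers(0, 5, size=n)

    dev_s = rng.normal(0.0, INDEX_SD, n)
    dev_d = rng.normal(0.0, INDEX_SD, n)
    mendelian = rng.normal(0.0, np.sqrt(var_a / 2.0), n)
    own_dev = np.where(
        has_parents, 0.5 * (dev_s + dev_d) + mendelian, rng.normal(0.0, INDEX_SD, n)
    )
    tbv = period_effect + own_dev + cfg.delta * carrier

    r2_s = rng.uniform(*cfg.parent_reliability_range, n)
    r2_d = rng.uniform(*cfg.parent_reliability_range, n)
    r2_s = np.where(has_parents, r2_s, np.nan)
    r2_d = np.where(has_parents, r2_d, np.nan)
    r2_pa = parent_average_reliability(r2_s, r2_d)
    pa = np.where(has_parents, 0.5 * (r2_s * dev_s + r2_d * dev_d), 0.0)
    # parent EBVs consistent with the PA actually used
    sire_ebv = np.where(has_parents, INDEX_MEAN + r2_s * dev_s, np.nan)
    dam_ebv = np.where(has_parents, INDEX_MEAN + r2_d * dev_d, np.nan)

    r2 = rng.uniform(*cfg.reliability_range, n)
    r2 = np.clip(np.maximum(r2, r2_pa + 0.05), None, 1.0)
    r2[pa_only] = r2_pa[pa_only]

    _, zpz = garrick_information(
        np.where(pa_only, 0.9, r2), np.where(pa_only, 0.0, r2_pa), lam
    )  # placeholder values for pa_only rows, overwritten below
    with np.errstate(divide="ignore"):
        debv_noise_sd = np.sqrt(lam * var_a / zpz)
    debv_true = tbv + rng.standard_normal(n) * debv_noise_sd

    simple = (~has_parents) | (r2 >= 1.0 - 1e-9)
    with np.errstate(invalid="ignore"):
        u = np.where(
            simple,
            r2 * debv_true,
            (zpz * debv_true + 2.0 * lam * pa) / (zpz + 2.0 * lam),
        )
    u[pa_only] = pa[pa_only]
    debv_true[pa_only] = np.nan

    records = pd.DataFrame(
        {
            "animal": np.arange(1, n + 1),
            "sire": np.where(has_parents, np.arange(n + 1, 2 * n + 1), 0),
            "dam": np.where(has_parents, np.arange(2 * n + 1, 3 * n + 1), 0),
            "trait": cfg.trait,
            "ebv": INDEX_MEAN + u,
            "rel": r2,
            "sire_rel": r2_s,
            "dam_rel": r2_d,
            "sire_ebv": sire_ebv,
            "dam_ebv": dam_ebv,
            "birth_year": birth_year,
            "genotype": np.where(carrier, "WFFS/N", "N/N"),
            "ebv_show_jumping": rng.normal(INDEX_MEAN, INDEX_SD, n),
        }
    )
    truth = pd.DataFrame(
        {
            "animal": records["animal"],
            "tbv_dev": tbv,
            "carrier": carrier,
            "pa_only": pa_only,
            "has_parents": has_parents,
            "period": period,
            "debv_true": debv_true,
        }
    )
    return records, truth
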