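"""Genotype-age-at-onset association and frequency comparisons.

The association model is ordinary least squares of age-at-onset (AAO,
years) on a genotype dosage, optionally with covariates:

    AAO_i = beta0 + beta * dosage_i + gamma' c_i + eps_i

under one of three codings of the biallelic genotype: additive
(dosage = number of alternate alleles, 0/1/2), dominant (het and hom-alt
collapse to 1), or recessive (only hom-alt is 1). ``beta`` is the
modeled AAO shift per dosage unit; significance is a two-sided t-test on
that coefficient. No covariates are fitted by default and AAO is used in
raw years.

Frequency comparisons between a cohort and a reference population use a
chi-square test on the 2xk genotype-count table without continuity
correction, falling back to a Fisher exact test (hypergeometric for 2x2,
full enumeration over the margin-conditional table network for 2x3)
whenever any expected cell is below 5.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Optional, Sequence

import numpy as np
import statsmodels.api as sm
from scipy import stats
from scipy.special import gammaln

from .cohort_io import ReferenceCounts
from .variant_model import Genotype, GenotypeState, genotype_state

__all__ = [
    "GenotypeCoding",
    "RegressionResult",
    "FrequencyTestResult",
    "FrequencyMethod",
    "encode",
    "fit_aao",
    "genotype_frequency_test",
    "homozygote_frequency",
    "cohort_homozygote_fraction",
    "percent_half_up",
]


class GenotypeCoding(enum.Enum):
    """Dosage coding of a biallelic genotype for regression."""

    ADDITIVE = "additive"
    DOMINANT = "dominant"
    RECESSIVE = "recessive"


_DOSAGE = {
    GenotypeCoding.ADDITIVE: {
        GenotypeState.HOM_REF: 0,
        GenotypeState.HET: 1,
        GenotypeState.HOM_ALT: 2,
    },
    GenotypeCoding.DOMINANT: {
        GenotypeState.HOM_REF: 0,
        GenotypeState.HET: 1,
        GenotypeState.HOM_ALT: 1,
    },
    GenotypeCoding.RECESSIVE: {
        GenotypeState.HOM_REF: 0,
        GenotypeState.HET: 0,
        GenotypeState.HOM_ALT: 1,
    },
}


def encode(g: Genotype, coding: GenotypeCoding) -> Optional[int]:
    """Dosage of a biallelic genotype under a coding; missing propagates as None."""
    state = genotype_state(g)
    if state is GenotypeState.MISSING:
        return None
    return _DOSAGE[coding][state]


@dataclass(slots=True)
class RegressionResult:
    """OLS fit of AAO on genotype dosage.

    ``degenerate`` marks a fit that could not be performed because the
    dosage had zero variance after dropping missing values (e.g. no
    homozygous-alternate carriers under the recessive coding); the
    effect fields are then None.
    """

    model: GenotypeCoding
    beta_years: Optional[float]
    se: Optional[float]
    t_stat: Optional[float]
    p_two_sided: Optional[float]
    n: int
    df: int
    n_dropped: int = 0
    degenerate: bool = False
    covariate_betas: dict[str, float] = field(default_factory=dict)


def fit_aao(
    aao: Sequence[float],
    dosage: Sequence[Optional[float]],
    covariates: Optional[np.ndarray] = None,
    covariate_names: Optional[Sequence[str]] = None,
    model: GenotypeCoding = GenotypeCoding.RECESSIVE,
) -> RegressionResult:
    """OLS of age-at-onset on dosage, two-sided t-test on the dosage slope.

    Samples with missing dosage (None/NaN) or missing AAO are dropped
    pairwise and the count reported in ``n_dropped``.
    """
    aao_arr = np.array([np.nan if a is None else float(a) for a in aao], dtype=float)
    dos_arr = np.array(
        [np.nan if d is None else float(d) for d in dosage], dtype=float
    )
    if aao_arr.shape != dos_arr.shape:
        raise ValueError("aao and dosage must have the same length")
    if covariates is not None:
        covariates = np.asarray(covariates, dtype=float)
        if covariates.ndim == 1:
            covariates = covariates[:, None]
        if covariates.shape[0] != aao_arr.shape[0]:
            raise ValueError("covariate rows must match sample count")
    keep = ~np.isnan(aao_arr) & ~np.isnan(dos_arr)
    if covariates is not None:
        keep &= ~np.isnan(covariates).any(axis=1)
    n_dropped = int((~keep).sum())
    y = aao_arr[keep]
    d = dos_arr[keep]
    n = int(y.size)
    k_cov = 0 if covariates is None else covariates.shape[1]
    n_coef = 2 + k_cov
    if n < n_coef + 1:
        raise ValueError(f"need at least {n_coef + 1} complete samples, got {n}")
    if np.ptp(d) == 0:
        return RegressionResult(
            model=model,
            beta_years=None,
            se=None,
            t_stat=None,
            p_two_sided=None,
            n=n,
            df=n - n_coef,
            n_dropped=n_dropped,
            degenerate=True,
        )
    X = np.column_stack([d] + ([covariates[keep]] if k_cov else []))
    X = sm.add_constant(X, prepend=True)
    fit = sm.OLS(y, X).fit()
    names = list(covariate_names) if covariate_names else [
        f"cov{i}" for i in range(k_cov)
    ]
    return RegressionResult(
        model=model,
        beta_years=float(fit.params[1]),
        se=float(fit.bse[1]),
        t_stat=float(fit.tvalues[1]),
        p_two_sided=float(fit.pvalues[1]),
        n=n,
        df=int(fit.df_resid),
        n_dropped=n_dropped,
        covariate_betas={
            name: float(fit.params[2 + i]) for i, name in enumerate(names[:k_cov])
        },
    )


class FrequencyMethod(enum.Enum):
    CHI_SQUARE = "chi_square"
    FISHER_EXACT = "fisher_exact"


@dataclass(slots=True)
class FrequencyTestResult:
    table: np.ndarray
    statistic: Optional[float]
    p: float
    method: FrequencyMethod


def _fisher_exact_2xk(table: np.ndarray) -> float:
    """Two-sided Fisher exact p for a 2xk table by network enumeration.

    Enumerates every table with the observed margins, computes each
    table's conditional (multivariate hypergeometric) probability, and
    sums probabilities not exceeding the observed table's.
    """
    table = np.asarray(table, dtype=np.int64)
    r1 = table[0].sum()
    cols = table.sum(axis=0)
    total = table.sum()
    logdenom = (
        gammaln(total + 1)
        - gammaln(r1 + 1)
        - gammaln(total - r1 + 1)
    )

    def logp_row(row: np.ndarray) -> float:
        lp = -logdenom
        for a, c in zip(row, cols):
            lp += gammaln(c + 1) - gammaln(a + 1) - gammaln(c - a + 1)
        return lp

    lp_obs = logp_row(table[0])
    # enumerate first-row fillings of the columns summing to r1
    k = len(cols)
    p_sum = 0.0
    stack = [(0, r1, [])]
    while stack:
        j, rem, row = stack.pop()
        if j == k - 1:
            if rem <= cols[j]:
                full = np.array(row + [rem])
                lp = logp_row(full)
                # relative tie tolerance, as in standard exact-test practice
                if lp <= lp_obs + 1e-7:
                    p_sum += float(np.exp(lp))
            continue
        upper = min(rem, int(cols[j]))
        lower = max(0, rem - int(cols[j:].sum() - cols[j]))
        for a in range(lower, upper + 1):
            stack.append((j + 1, rem - a, row + [a]))
    return min(1.0, p_sum)


def genotype_frequency_test(
    case_counts: Sequence[int], reference_counts: Sequence[int]
) -> FrequencyTestResult:
    """Compare genotype-class counts between a cohort and a reference.

    Chi-square on the 2xk table without continuity correction; the
    approximation is only trusted when every expected cell exceeds 5,
    otherwise the method switches to a Fisher exact test.
    """
    case = np.asarray(case_counts, dtype=np.int64)
    ref = np.asarray(reference_counts, dtype=np.int64)
    if case.shape != ref.shape or case.ndim != 1 or case.size not in (2, 3):
        raise ValueError("expected two count vectors of length 2 or 3")
    if (case < 0).any() or (ref < 0).any():
        raise ValueError("counts must be non-negative")
    table = np.vstack([case, ref])
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        raise ValueError("every row and column margin must be positive")
    expected = stats.contingency.expected_freq(table)
    if (expected <= 5).any():
        if table.shape[1] == 2:
            _, p = stats.fisher_exact(table, alternative="two-sided")
        else:
            p = _fisher_exact_2xk(table)
        return FrequencyTestResult(
            table=table, statistic=None, p=float(p), method=FrequencyMethod.FISHER_EXACT
        )
    chi2, p, _, _ = stats.chi2_contingency(table, correction=False)
    return FrequencyTestResult(
        table=table, statistic=float(chi2), p=float(p), method=FrequencyMethod.CHI_SQUARE
    )


def homozygote_frequency(counts: ReferenceCounts) -> float:
    """Fraction of homozygous-alternate individuals in a reference population.

    gnomAD convention: the number of individuals is total alleles / 2.
    """
    individuals = counts.total_alleles / 2
    return counts.hom_alt_individuals / individuals


def cohort_homozygote_fraction(n_hom: int, n_total: int) -> float:
    """Fraction of homozygous carriers among genotyped cohort members."""
    if n_total <= 0:
        raise ValueError("n_total must be positive")
    if not 0 <= n_hom <= n_total:
        raise ValueError("need 0 <= n_hom <= n_total")
    return n_hom / n_total


def percent_half_up(fraction: float, ndigits: int = 2) -> float:
    """Format a fraction as a percentage rounded half-up to ``ndigits``."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(fraction * 100)).quantize(q, rounding=ROUND_HALF_UP))
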