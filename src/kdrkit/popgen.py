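"""Single-locus population genetics: allele frequencies and Hardy-Weinberg tests.

Two HWE tests are provided. ``hwe_chisq`` is the chi-square goodness-of-fit of
observed genotype counts against expectations computed from the estimated
allele frequencies; the degrees of freedom are exposed because field studies
use either df=1 (the conventional choice: three classes, one estimated
parameter) or df=2 (three classes minus one). ``hwe_exact`` is the
Levene/Haldane conditional exact test: conditioning on the observed allele
counts, the probability of every possible heterozygote count is evaluated and
the p-value is the summed probability of all configurations no more probable
than the observed one.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.special import gammaln
from scipy.stats import chi2 as _chi2

from .datatypes import GenotypeCounts
from .errors import ValidationError


@dataclass(frozen=True)
class AlleleFrequencyResult:
    p_wild: float
    p_mut: float
    n_alleles: int


@dataclass(frozen=True)
class HweResult:
    statistic: float | None
    p_value: float
    df: int | None
    method: str  # "chisq" or "exact"


def allele_frequencies(counts: GenotypeCounts) -> AlleleFrequencyResult:
    """Allele frequencies by gene counting.

    p_mut = (n_het + 2 n_mut_hom) / (2 n).
    """
    counts.require_nonempty()
    n_alleles = 2 * counts.total
    p_mut = (counts.n_het + 2 * counts.n_mut_hom) / n_alleles
    return AlleleFrequencyResult(p_wild=1.0 - p_mut, p_mut=p_mut, n_alleles=n_alleles)


def hwe_chisq(counts: GenotypeCounts, df: int = 2) -> HweResult:
    """Chi-square HWE goodness-of-fit test with caller-chosen df (1 or 2)."""
    counts.require_nonempty()
    if df not in (1, 2):
        raise ValidationError(f"df must be 1 or 2, got {df}")
    freqs = allele_frequencies(counts)
    p, q = freqs.p_wild, freqs.p_mut
    if p == 0.0 or q == 0.0:
        warnings.warn(
            f"locus {counts.locus_name!r} is monomorphic; HWE trivially satisfied",
            stacklevel=2,
        )
        return HweResult(statistic=0.0, p_value=1.0, df=df, method="chisq")
    n = counts.total
    expected = n * np.array([p * p, 2 * p * q, q * q])
    observed = np.array(counts.as_tuple(), dtype=float)
    stat = float(((observed - expected) ** 2 / expected).sum())
    return HweResult(statistic=stat, p_value=float(_chi2.sf(stat, df)), df=df, method="chisq")


def _exact_log_pmf(n_het: int, n: int, n_minor: int) -> float:
    """log P(heterozygote count | n individuals, minor allele count)."""
    n_major = 2 * n - n_minor
    hom_minor = (n_minor - n_het) // 2
    hom_major = (n_major - n_het) // 2
    return float(
        gammaln(n + 1)
        - gammaln(hom_major + 1)
        - gammaln(n_het + 1)
        - gammaln(hom_minor + 1)
        + n_het * np.log(2.0)
        + gammaln(n_minor + 1)
        + gammaln(n_major + 1)
        - gammaln(2 * n + 1)
    )


def hwe_exact(counts: GenotypeCounts) -> HweResult:
    """Conditional exact HWE test (Levene/Haldane).

    Enumerates every heterozygote count compatible with the observed allele
    counts (same parity as the minor-allele count) and sums the probabilities
    of configurations no more probable than the observed one.
    """
    counts.require_nonempty()
    n = counts.total
    n_mut = counts.n_het + 2 * counts.n_mut_hom
    n_minor = min(n_mut, 2 * n - n_mut)
    if n_minor == 0:
        return HweResult(statistic=None, p_value=1.0, df=None, method="exact")
    hets = range(n_minor % 2, n_minor + 1, 2)
    log_probs = {h: _exact_log_pmf(h, n, n_minor) for h in hets}
    log_obs = log_probs[counts.n_het]
    # relative tie tolerance guards against log-space rounding
    p = sum(np.exp(lp) for lp in log_probs.values() if lp <= log_obs + 1e-10)
    return HweResult(statistic=None, p_value=float(min(p, 1.0)), df=None, method="exact")
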