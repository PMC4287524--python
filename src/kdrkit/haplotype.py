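"""Two-locus haplotype-frequency estimation from unphased genotypes, and
linkage-disequilibrium statistics.

The model
---------
Two biallelic loci yield four haplotypes: 11 (wild/wild), 12 (wild/mutant),
21 (mutant/wild) and 22 (mutant/mutant). From an unphased 3x3 genotype table
every cell determines its two haplotypes unambiguously except the double
heterozygote, which is a mixture of the cis (11/22) and trans (12/21)
phases. Under random union of gametes the maximum-likelihood estimate of
f11 satisfies the EM fixed-point condition

    2N f11 = c11 + nDH * f11 f22 / (f11 f22 + f12 f21)

where c11 counts unambiguous 11 haplotypes, nDH is the double-heterozygote
cell, and f12, f21, f22 follow from f11 and the (fixed, observed) allele
frequencies. Clearing denominators gives a cubic in f11 — the closed-form
("cubic equation") estimator familiar from CubeX: every real root with all
four frequencies in [0, 1] is an EM stationary point, and the MLE is the
valid root with the highest multinomial log-likelihood of the observed
table. An independent EM iteration from linkage-equilibrium frequencies is
provided as a cross-check; both routes agree to high precision.

LD statistics are computed on the mutant alleles: D = f22 - p1 p2 (p_i the
mutant-allele frequency at locus i), D' = D / D_max, r^2 = D^2 / (p1 q1 p2 q2),
and chi2 = r^2 * 2N.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .datatypes import TwoLocusCounts
from .errors import MonomorphicLocusError, ValidationError

_HAP_KEYS = ("f_11", "f_12", "f_21", "f_22")


def _genotype_probs(f: np.ndarray) -> np.ndarray:
    """3x3 genotype-class probabilities from haplotype frequencies."""
    f11, f12, f21, f22 = f
    return np.array(
        [
            [f11 * f11, 2 * f11 * f12, f12 * f12],
            [2 * f11 * f21, 2 * (f11 * f22 + f12 * f21), 2 * f12 * f22],
            [f21 * f21, 2 * f21 * f22, f22 * f22],
        ]
    )


def _log_likelihood(table: np.ndarray, f: np.ndarray) -> float:
    probs = _genotype_probs(f)
    with np.errstate(divide="ignore"):
        logp = np.log(np.where(probs > 0, probs, 1.0))
    if np.any((table > 0) & (probs <= 0)):
        return -np.inf
    return float((table * logp).sum())


@dataclass(frozen=True)
class LdStatistics:
    D: float
    D_prime: float
    r_squared: float
    chi_square: float


class HaplotypeResults:
    """Estimates from :class:`HaplotypeFrequencyModel.fit`.

    Attributes
    ----------
    freqs : dict
        Haplotype frequencies keyed ``f_11``..``f_22`` (locus1 allele first;
        1 = wild, 2 = mutant).
    chosen_root, n_valid_roots, all_roots : cubic-root diagnostics.
    log_likelihood : multinomial log-likelihood at the estimate.
    """

    def __init__(self, model, f, method, chosen_root, n_valid_roots, all_roots, log_likelihood):
        self.model = model
        self._f = np.asarray(f, dtype=float)
        self.freqs = dict(zip(_HAP_KEYS, self._f.tolist()))
        self.method = method
        self.chosen_root = chosen_root
        self.n_valid_roots = n_valid_roots
        self.all_roots = tuple(all_roots)
        self.log_likelihood = log_likelihood

    @property
    def frequencies(self) -> np.ndarray:
        return self._f.copy()

    @property
    def n(self) -> int:
        return self.model.n

    @property
    def p_mut1(self) -> float:
        return 1.0 - (self._f[0] + self._f[1])

    @property
    def p_mut2(self) -> float:
        return 1.0 - (self._f[0] + self._f[2])

    def ld(self) -> LdStatistics:
        """D, D', r^2 and chi2 for the mutant-allele association.

        Raises
        ------
        MonomorphicLocusError
            If either locus is fixed — the statistics are undefined.
        """
        p1, p2 = self.p_mut1, self.p_mut2
        q1, q2 = 1.0 - p1, 1.0 - p2
        if min(p1, q1, p2, q2) <= 0.0:
            raise MonomorphicLocusError(
                "LD statistics undefined: a locus is monomorphic "
                f"(mutant frequencies {p1:.4g}, {p2:.4g})"
            )
        D = self._f[3] - p1 * p2
        if D > 0:
            d_max = min(p1 * q2, q1 * p2)
        elif D < 0:
            d_max = min(p1 * p2, q1 * q2)
        else:
            d_max = np.nan
        d_prime = 0.0 if D == 0 else D / d_max
        r2 = D * D / (p1 * q1 * p2 * q2)
        return LdStatistics(
            D=float(D),
            D_prime=float(d_prime),
            r_squared=float(r2),
            chi_square=float(r2 * 2 * self.n),
        )

    def summary(self) -> str:
        lines = [
            "Two-locus haplotype frequency estimate "
            f"({self.model.counts.locus1_name} x {self.model.counts.locus2_name})",
            f"  method: {self.method}   n = {self.n} individuals",
            f"  valid cubic roots: {self.n_valid_roots}   chosen root: {self.chosen_root:.6f}",
            f"  log-likelihood: {self.log_likelihood:.4f}",
        ]
        for k, v in self.freqs.items():
            lines.append(f"  {k} = {v:.4f}")
        try:
            ld = self.ld()
            lines.append(
                f"  D = {ld.D:.4f}   D' = {ld.D_prime:.3f}   "
                f"r^2 = {ld.r_squared:.3f}   chi2 = {ld.chi_square:.2f}"
            )
        except MonomorphicLocusError:
            lines.append("  LD statistics undefined (monomorphic locus)")
        return "\n".join(lines)


class HaplotypeFrequencyModel:
    """Maximum-likelihood haplotype frequencies from a 3x3 genotype table.

    Parameters
    ----------
    counts : TwoLocusCounts
        Individuals cross-classified by genotype at two biallelic loci,
        (wild_hom, het, mut_hom) order on both axes.
    """

    def __init__(self, counts: TwoLocusCounts):
        self.counts = counts
        self.table = counts.matrix.astype(float)
        self.n = counts.total
        r = self.table.sum(axis=1)
        c = self.table.sum(axis=0)
        # wild-allele frequencies at each locus (fixed by the data)
        self.p1_wild = (2 * r[0] + r[1]) / (2 * self.n)
        self.p2_wild = (2 * c[0] + c[1]) / (2 * self.n)
        t = self.table
        # unambiguous haplotype counts
        self.c11 = 2 * t[0, 0] + t[0, 1] + t[1, 0]
        self.c12 = 2 * t[0, 2] + t[0, 1] + t[1, 2]
        self.c21 = 2 * t[2, 0] + t[1, 0] + t[2, 1]
        self.c22 = 2 * t[2, 2] + t[2, 1] + t[1, 2]
        self.n_double_het = t[1, 1]

    @classmethod
    def from_dataframe(cls, df, locus1_name: str = "locus1", locus2_name: str = "locus2"):
        """Build from a 3x3 pandas DataFrame (rows = locus-1 genotypes)."""
        arr = np.asarray(df)
        return cls(TwoLocusCounts(locus1_name, locus2_name, tuple(map(tuple, arr.tolist()))))

    def _freqs_from_f11(self, f11: float) -> np.ndarray:
        return np.array(
            [
                f11,
                self.p1_wild - f11,
                self.p2_wild - f11,
                1.0 - self.p1_wild - self.p2_wild + f11,
            ]
        )

    def _cubic_roots(self) -> np.ndarray:
        N, p1, q1 = self.n, self.p1_wild, self.p2_wild
        c11, ndh = self.c11, self.n_double_het
        coeffs = [
            4.0 * N,
            2 * N * (1 - 2 * p1 - 2 * q1) - 2 * c11 - ndh,
            2 * N * p1 * q1 - c11 * (1 - 2 * p1 - 2 * q1) - ndh * (1 - p1 - q1),
            -c11 * p1 * q1,
        ]
        return np.roots(coeffs)

    def fit(self, method: str = "cubic", tol: float = 1e-12, max_iter: int = 100_000):
        """Estimate haplotype frequencies.

        method="cubic" solves the closed-form cubic and picks the valid root
        with maximum likelihood (ties broken toward larger |D'|);
        method="em" iterates expectation-maximization from linkage
        equilibrium to convergence ``tol``.
        """
        if method not in ("cubic", "em"):
            raise ValidationError(f"unknown method {method!r}")
        eps = 1e-7
        roots = self._cubic_roots()
        lo = max(0.0, self.p1_wild + self.p2_wild - 1.0)
        hi = min(self.p1_wild, self.p2_wild)
        candidates = []
        for z in roots:
            # double roots surface as conjugate pairs with small imaginary part
            if abs(z.imag) > 1e-5:
                continue
            x = float(z.real)
            if not lo - eps <= x <= hi + eps:
                continue
            x = min(max(x, lo), hi)
            if any(abs(x - prev) < 1e-7 for prev, _ in candidates):
                continue
            candidates.append((x, np.clip(self._freqs_from_f11(x), 0.0, 1.0)))
        n_valid = len(candidates)
        if method == "cubic":
            if not candidates:
                raise ValidationError(
                    "no valid cubic root — this should be impossible for a "
                    "well-formed genotype table"
                )
            scored = []
            for root, fc in candidates:
                ll = _log_likelihood(self.table, fc)
                res = HaplotypeResults(self, fc, "cubic", root, n_valid, roots, ll)
                try:
                    abs_dp = abs(res.ld().D_prime)
                except MonomorphicLocusError:
                    abs_dp = 0.0
                scored.append((ll, abs_dp, root, fc))
            ll, _, root, fc = max(scored, key=lambda s: (s[0], s[1]))
            return HaplotypeResults(self, fc, "cubic", root, n_valid, roots, ll)

        # EM from linkage-equilibrium start
        p1, q1 = self.p1_wild, self.p2_wild
        f11 = p1 * q1
        for _ in range(max_iter):
            f = self._freqs_from_f11(f11)
            cis = f[0] * f[3]
            trans = f[1] * f[2]
            denom = cis + trans
            share = 0.5 if denom <= 0 else cis / denom
            f11_new = (self.c11 + self.n_double_het * share) / (2 * self.n)
            if abs(f11_new - f11) < tol:
                f11 = f11_new
                break
            f11 = f11_new
        f = np.clip(self._freqs_from_f11(f11), 0.0, 1.0)
        ll = _log_likelihood(self.table, f)
        return HaplotypeResults(self, f, "em", float(f11), n_valid, roots, ll)


def estimate_haplotypes(counts: TwoLocusCounts, method: str = "cubic") -> HaplotypeResults:
    """Functional shorthand for ``HaplotypeFrequencyModel(counts).fit(method)``."""
    return HaplotypeFrequencyModel(counts).fit(method=method)


def ld_statistics(est: HaplotypeResults) -> LdStatistics:
    """Linkage-disequilibrium statistics of a haplotype estimate."""
    return est.ld()
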