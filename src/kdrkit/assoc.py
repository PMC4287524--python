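"""Bioassay mortality correction and genotype-phenotype association.

The association analysis codes a dead/alive x genotype table under three
genetic models — recessive (mutant homozygotes vs the rest), dominant (any
mutant allele vs none) and additive (each individual contributes its two
alleles) — and reports the odds ratio with a Woolf (log-scale) confidence
interval plus a two-sided Fisher exact p-value. Orientation: OR > 1 means
the mutant class survives exposure more often, i.e. the allele is
protective against the insecticide.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import pandas as pd
from scipy.stats import fisher_exact as _scipy_fisher
from scipy.stats import norm

from .datatypes import PhenoGenoTable, TwoByTwo
from .errors import UndefinedStatisticError, UsageError, ValidationError

GENETIC_MODELS = ("recessive", "dominant", "additive")


@dataclass(frozen=True)
class CorrectedMortality:
    observed_pct: float
    control_pct: float
    corrected_pct: float
    valid: bool


@dataclass(frozen=True)
class OddsRatioResult:
    odds_ratio: float
    ci_low: float
    ci_high: float
    alpha: float
    p_fisher: float
    model: str
    continuity_corrected: bool = False


def abbott_correct(observed_pct: float, control_pct: float) -> CorrectedMortality:
    """Abbott's control-mortality correction for bioassay mortality.

    corrected = (observed - control) / (100 - control) * 100. Following WHO
    test procedure, no correction is applied when control mortality is below
    5%, and the assay is flagged invalid when it exceeds 20%.
    """
    if not (0 <= observed_pct <= 100 and 0 <= control_pct <= 100):
        raise ValidationError("mortality percentages must lie in [0, 100]")
    if control_pct == 100:
        raise UndefinedStatisticError("Abbott correction undefined at 100% control mortality")
    if control_pct < 5:
        corrected = observed_pct
    else:
        corrected = (observed_pct - control_pct) / (100.0 - control_pct) * 100.0
    return CorrectedMortality(
        observed_pct=observed_pct,
        control_pct=control_pct,
        corrected_pct=corrected,
        valid=control_pct <= 20,
    )


def build_model_table(pg: PhenoGenoTable, model: str) -> TwoByTwo:
    """Collapse a dead/alive x genotype table into a 2x2 under a genetic model."""
    if model not in GENETIC_MODELS:
        raise UsageError(f"unknown genetic model {model!r}; choose from {GENETIC_MODELS}")
    d, a = pg.dead, pg.alive
    if model == "recessive":
        return TwoByTwo(
            a=a.n_mut_hom,
            b=d.n_mut_hom,
            c=a.n_wild_hom + a.n_het,
            d=d.n_wild_hom + d.n_het,
        )
    if model == "dominant":
        return TwoByTwo(
            a=a.n_het + a.n_mut_hom,
            b=d.n_het + d.n_mut_hom,
            c=a.n_wild_hom,
            d=d.n_wild_hom,
        )
    return TwoByTwo(  # additive: allele-level counts
        a=2 * a.n_mut_hom + a.n_het,
        b=2 * d.n_mut_hom + d.n_het,
        c=2 * a.n_wild_hom + a.n_het,
        d=2 * d.n_wild_hom + d.n_het,
    )


def odds_ratio_woolf(t: TwoByTwo, alpha: float = 0.05, model: str = "") -> OddsRatioResult:
    """Odds ratio with Woolf logit confidence interval.

    Zero cells get the Haldane-Anscombe 0.5 correction (flagged); a zero
    row or column makes the OR undefined.
    """
    a, b, c, d = t.a, t.b, t.c, t.d
    if min(a + b, c + d, a + c, b + d) == 0:
        raise UndefinedStatisticError("odds ratio undefined: a 2x2 margin is zero")
    corrected = 0 in (a, b, c, d)
    if corrected:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    orr = (a * d) / (b * c)
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    # conventional two-decimal critical value at the standard level, as used
    # in practice when such CIs are reported; exact quantile otherwise
    z = 1.96 if alpha == 0.05 else norm.ppf(1 - alpha / 2)
    return OddsRatioResult(
        odds_ratio=orr,
        ci_low=orr * math.exp(-z * se),
        ci_high=orr * math.exp(z * se),
        alpha=alpha,
        p_fisher=fisher_exact_2x2(t),
        model=model,
        continuity_corrected=corrected,
    )


def fisher_exact_2x2(t: TwoByTwo) -> float:
    """Two-sided Fisher exact p-value (point-probability definition)."""
    if min(t.a + t.b, t.c + t.d) == 0 or min(t.a + t.c, t.b + t.d) == 0:
        warnings.warn("degenerate 2x2 margins; Fisher p = 1", stacklevel=2)
        return 1.0
    return float(_scipy_fisher([[t.a, t.b], [t.c, t.d]], alternative="two-sided")[1])


class AssociationResults:
    """Per-model odds-ratio results from :class:`AssociationModel.fit`."""

    def __init__(self, model, results: list[OddsRatioResult]):
        self.model = model
        self.results = results

    @property
    def table(self) -> pd.DataFrame:
        rows = [
            {
                "insecticide": self.model.pheno_geno.insecticide,
                "locus": self.model.pheno_geno.locus_name,
                "model": r.model,
                "odds_ratio": r.odds_ratio,
                "ci_low": r.ci_low,
                "ci_high": r.ci_high,
                "p_fisher": r.p_fisher,
            }
            for r in self.results
        ]
        return pd.DataFrame(rows)

    def summary(self) -> str:
        pg = self.model.pheno_geno
        lines = [
            f"Genotype-phenotype association: {pg.insecticide} x {pg.locus_name} "
            f"(n = {pg.total})",
            "  (OR > 1: mutant class survives more)",
        ]
        for r in self.results:
            lines.append(
                f"  {r.model:>9s}: OR = {r.odds_ratio:.2f} "
                f"({100 * (1 - r.alpha):.0f}% CI {r.ci_low:.2f}-{r.ci_high:.2f}), "
                f"Fisher p = {r.p_fisher:.4g}"
            )
        return "\n".join(lines)


class AssociationModel:
    """Genotype-resistance association for one insecticide exposure.

    Built from a :class:`PhenoGenoTable`; ``fit`` evaluates the requested
    genetic models and returns an :class:`AssociationResults`.
    """

    def __init__(self, pheno_geno: PhenoGenoTable):
        self.pheno_geno = pheno_geno

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, insecticide: str, locus: str = "locus"):
        """Build from a DataFrame with index dead/alive and columns
        (wild_hom, het, mut_hom)."""
        from .datatypes import GenotypeCounts

        rows = {str(k).lower(): [int(v) for v in df.loc[k]] for k in df.index}
        return cls(
            PhenoGenoTable(
                insecticide=insecticide,
                dead=GenotypeCounts(locus, *rows["dead"]),
                alive=GenotypeCounts(locus, *rows["alive"]),
            )
        )

    def fit(self, models=GENETIC_MODELS, alpha: float = 0.05) -> AssociationResults:
        results = []
        for m in models:
            t = build_model_table(self.pheno_geno, m)
            results.append(odds_ratio_woolf(t, alpha=alpha, model=m))
        return AssociationResults(self, results)
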