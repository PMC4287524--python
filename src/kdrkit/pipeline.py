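"""End-to-end analysis pipeline over the bundled Delhi kdr survey tables
(or user-supplied CSVs of the same shape).

The reproduction profile computes, from raw count tables only:

* per-population 1534C allele frequencies and HWE chi-square tests (df=2,
  the convention the survey's printed p-values follow);
* odds ratios with Woolf CIs and Fisher exact p-values per insecticide
  under the recessive/dominant/additive genetic models;
* exact HWE tests at both loci of the two-locus table, maximum-likelihood
  haplotype frequencies and the D/D'/r^2 linkage statistics.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from . import __version__
from .assoc import GENETIC_MODELS, AssociationModel
from .datatypes import ReportBundle
from .errors import MonomorphicLocusError, UsageError
from .haplotype import HaplotypeFrequencyModel
from .io import bundled_path, load_genotype_counts, load_pheno_geno_tables, load_two_locus_counts
from .popgen import allele_frequencies, hwe_chisq, hwe_exact


@dataclass
class PipelineConfig:
    genotype_counts_path: object = None
    pheno_geno_path: object = None
    two_locus_path: object = None
    models: tuple = GENETIC_MODELS
    hwe_df: int = 2
    alpha: float = 0.05

    def __post_init__(self):
        unknown = [m for m in self.models if m not in GENETIC_MODELS]
        if unknown:
            raise UsageError(f"unknown genetic model(s) {unknown}; choose from {GENETIC_MODELS}")
        if self.genotype_counts_path is None:
            self.genotype_counts_path = bundled_path("table1_genotype_counts.csv")
        if self.pheno_geno_path is None:
            self.pheno_geno_path = bundled_path("table2_pheno_geno.csv")
        if self.two_locus_path is None:
            self.two_locus_path = bundled_path("table3_two_locus.csv")


def reproduce(config: PipelineConfig | None = None) -> ReportBundle:
    """Run the full analysis; every result row carries its input identifier."""
    cfg = config or PipelineConfig()
    bundle = ReportBundle(metadata={"kdrkit_version": __version__, "hwe_df": cfg.hwe_df})

    stage = "allele frequencies / HWE"
    try:
        populations = load_genotype_counts(cfg.genotype_counts_path)
        for gc in populations:
            af = allele_frequencies(gc)
            bundle.allele_frequencies.append(
                {
                    "input": str(cfg.genotype_counts_path),
                    "population": gc.population,
                    "locus": gc.locus_name,
                    "n": gc.total,
                    "p_wild": af.p_wild,
                    "p_mut": af.p_mut,
                }
            )
            hw = hwe_chisq(gc, df=cfg.hwe_df)
            bundle.hwe.append(
                {
                    "input": str(cfg.genotype_counts_path),
                    "population": gc.population,
                    "locus": gc.locus_name,
                    "method": hw.method,
                    "statistic": hw.statistic,
                    "df": hw.df,
                    "p_value": hw.p_value,
                }
            )

        stage = "association"
        for pg in load_pheno_geno_tables(cfg.pheno_geno_path):
            res = AssociationModel(pg).fit(models=cfg.models, alpha=cfg.alpha)
            for row in res.table.to_dict(orient="records"):
                row["input"] = str(cfg.pheno_geno_path)
                bundle.association.append(row)

        stage = "two-locus haplotype/LD"
        tl = load_two_locus_counts(cfg.two_locus_path)
        for margin in (tl.margin1(), tl.margin2()):
            hw = hwe_exact(margin)
            bundle.hwe.append(
                {
                    "input": str(cfg.two_locus_path),
                    "population": "pooled RFLP sample",
                    "locus": margin.locus_name,
                    "method": hw.method,
                    "statistic": hw.statistic,
                    "df": hw.df,
                    "p_value": hw.p_value,
                }
            )
        est = HaplotypeFrequencyModel(tl).fit(method="cubic")
        hap_row = {"input": str(cfg.two_locus_path), "method": est.method, "n": est.n}
        hap_row.update(est.freqs)
        bundle.haplotypes.append(hap_row)
        try:
            ld = est.ld()
            bundle.ld.append(
                {
                    "input": str(cfg.two_locus_path),
                    "loci": f"{tl.locus1_name}/{tl.locus2_name}",
                    "D": ld.D,
                    "D_prime": ld.D_prime,
                    "r_squared": ld.r_squared,
                    "chi_square": ld.chi_square,
                }
            )
        except MonomorphicLocusError:
            pass
    except Exception as e:
        raise type(e)(f"[stage: {stage}] {e}") from e
    return bundle
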