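# Methods

`kdrkit` analyses two-locus knockdown-resistance (kdr) genotyping data of the
type produced by PCR-RFLP surveys of *Aedes aegypti*: the voltage-gated sodium
channel substitutions F1534C (TTC→TGC) and T1520I (ACC→ATC) in domain III.
This note records the statistical models, the numerical choices, and what the
synthetic-data generators do and do not emulate.

## Single-locus analysis

Allele frequencies are obtained by gene counting: with genotype counts
(n_ww, n_het, n_mm) at a biallelic locus, the mutant-allele frequency is
q = (n_het + 2 n_mm) / 2n.

Two Hardy-Weinberg tests are provided.

* **Chi-square goodness of fit** of observed counts against n(p², 2pq, q²).
  The degrees of freedom are a parameter (default 2 in the reproduction
  pipeline, default 1 with a notice in the `hwe` CLI command). The textbook
  choice is df = 1 (three classes, one estimated allele frequency); df = 2 is
  nonetheless common in the insecticide-resistance survey literature and is
  what the bundled survey's printed p-values follow, so the pipeline matches
  it while exposing both. Monomorphic tables return statistic 0, p = 1 with a
  warning.
* **Conditional exact test** (Levene/Haldane). Conditioning on the observed
  allele counts, the heterozygote count h ranges over values with the parity
  of the minor-allele count; each configuration has probability
  n! / (n_ww! h! n_mm!) · 2^h · n_A! n_B! / (2n)! and the p-value sums the
  probabilities of all configurations no more probable than the observed one
  (tie comparison with a 1e-10 log-space tolerance). This is the exact test
  that CubeX-era genotyping studies report as "Fisher's exact" HWE. Note that
  when the observed heterozygote count is the modal configuration — as in the
  bundled T1520 table (155/45/3) — the p-value is exactly 1 by this
  definition; software that breaks ties differently, or estimates the tail by
  Monte Carlo, prints values slightly below 1 (e.g. 0.99) for the same data.

## Two-locus haplotype estimation and LD

With unphased genotypes at two biallelic loci, all cells of the 3×3 table
resolve into haplotypes unambiguously except the double heterozygote, a
mixture of cis (11/22) and trans (12/21) phases. Under random union of
gametes, the MLE of f11 satisfies the EM fixed point

    2N·f11 = c11 + n_DH · f11 f22 / (f11 f22 + f12 f21),

with c11 the unambiguous 11-haplotype count, n_DH the double-heterozygote
count, and the other frequencies pinned to f11 by the observed allele
frequencies. Clearing denominators gives a cubic in f11 (the closed-form
estimator popularised by the CubeX program); every real root with all four
frequencies in [0, 1] is an EM stationary point.

Numerical choices:

* roots come from `numpy.roots`; a root counts as real when |Im| < 1e-5
  (double roots — which arise e.g. at monomorphic loci — surface as conjugate
  pairs with small imaginary parts), is clipped into the feasible interval
  [max(0, p1+p2−1), min(p1, p2)], and near-duplicate roots within 1e-7 are
  merged;
* among valid roots the one maximising the multinomial log-likelihood of the
  observed table is chosen, ties broken toward larger |D′|; all roots and the
  valid-root count are kept as diagnostics;
* the EM cross-check starts from linkage-equilibrium products and iterates to
  1e-12; the test suite requires cubic and EM to agree within 1e-6 on
  randomised tables.

LD statistics on the mutant alleles: D = f22 − p1 p2; D′ = D/D_max with
D_max = min(p1 q2, q1 p2) for D > 0 and min(p1 p2, q1 q2) for D < 0;
r² = D²/(p1 q1 p2 q2); χ² = r²·2N (the allele-level one-degree statistic on
2N gametes). On the bundled two-locus table this gives χ² = 15.68; the value
printed alongside the original survey's D′ (8.02) is not derivable from the
table under either r²·2N or r²·N (≈ 7.84) and is reported here as computed,
not matched. A monomorphic locus raises a typed error for the LD statistics
rather than returning NaN; the haplotype frequencies themselves are still
reported.

## Association analysis

Genetic-model codings of a dead/alive × genotype table: recessive (mutant
homozygote vs rest), dominant (any mutant allele vs none), additive (each
individual contributes two alleles, giving a 2×2 on 2n alleles). The 2×2 is
oriented a = alive·mutant-class, b = dead·mutant-class, c = alive·wild-class,
d = dead·wild-class, so OR = ad/bc > 1 means the mutant class survives more
(the allele is protective). This orientation is stated in every summary
because count tables in the literature rarely make it explicit.

The CI is Woolf's logit interval exp(ln OR ± z·√(1/a+1/b+1/c+1/d)). At the
default α = 0.05 the conventional two-decimal critical value z = 1.96 is used
— this is how such intervals are computed in the survey literature, and the
exact quantile 1.95996 changes the last printed digit of wide intervals (e.g.
45.42 → 45.41). Other α use the exact normal quantile. Zero cells get the
Haldane–Anscombe 0.5 correction and a flag; a zero margin raises. Fisher's
exact two-sided p uses the point-probability definition (the sum of
hypergeometric probabilities no larger than the observed table's), delegated
to `scipy.stats.fisher_exact` and verified against an exact-fraction
enumeration oracle in the tests.

Abbott's correction for bioassay mortality, (T − C)/(100 − C)·100, follows
WHO practice: applied only when control mortality C is in [5%, 20%]; below
5% the observed mortality stands; above 20% the assay is flagged invalid;
C = 100% raises.

## In-silico PCR-RFLP engine

Coordinates are 1-based; a cut "at k" cleaves the top strand after base k, so
fragment lengths are simple differences. Recognition sites are IUPAC strings
scanned on both strands with overlap-aware regular expressions; a site found
on the minus strand reports the top-strand cleavage implied by the enzyme's
bottom-strand cut offset. Complete digestion is assumed — partial-digest
patterns are out of scope. The bundled enzyme table (REBASE-derived) includes
BsaBI (GATNN^NNATC, blunt) and SsiI (C^CG_C, 2-nt 5′ overhang); the engine is
checked against Biopython's `Bio.Restriction` in the tests but does not
depend on it.

In-silico PCR requires the forward primer on the plus strand and the reverse
complement of the reverse primer downstream; both template strands are
searched, exactly one product may result (no product and ambiguous products
raise distinct errors), and a mismatch budget is available for degraded
primer sites.

Assay design (`find_discriminating_enzymes`) keeps enzymes whose cut-site
sets *and* gel-observable band patterns differ between two alleles. Bands
shorter than `min_detectable_bp` (default 50, which removes the 28-bp BsaBI
product — unresolvable on agarose) are masked; an optional `resolution_bp`
merges bands closer than the gel can separate (default 0 = exact). Genotype
calling compares an observed band set with the wild pattern (wild
homozygote), the mutant observable pattern (mutant homozygote) and their
union (heterozygote); anything else is `uninterpretable`, a value rather than
an error.

## Synthetic data

The generators produce every input the pipeline reads, so nothing is
downloaded.

* **Genotypes**: each individual receives two haplotypes drawn from the
  configured frequencies; with probability f (the inbreeding coefficient) the
  second is a copy of the first, producing the excess homozygosity that the
  F1534 survey data show. Only f ∈ [0, 1] is supported — the copy-mixture
  model has no analogue for heterozygote excess, and nothing in scope needs
  one. Defaults are the survey's conditions: n = 203 and haplotype
  frequencies (0.21, 0.66, 0.00, 0.13), which include the structural zero
  (no mutant-1/wild-2 haplotype) that forces D′ = 1.
* **Bioassays**: survival is an independent Bernoulli per individual with a
  genotype-dependent probability, plus an independent control batch; default
  survival (0.5, 0.75, 0.95) for (wild hom, het, mutant hom) encodes strong
  recessive-leaning protection, and control mortality defaults to 2%.
* **Amplicons**: four 171-bp sequences (wild, 1520I, 1534C, double mutant)
  built from a fixed scaffold — the AekdrF primer at the 5′ end, the reverse
  complement of AekdrR at the 3′ end, an ACC codon at 146–148 inside a
  GATNNNN·· context and a TTC codon at 102–104 followed by GG — with
  seeded random filler, regenerated until the wild sequence contains no
  BsaBI/SsiI site and each single-base mutant contains exactly the intended
  site (BsaBI cutting at 143 → fragments 143+28; SsiI at 103 → 103+68).
  These are synthetic sequences satisfying the assay's published constraints,
  not the deposited GenBank haplotypes; tests passing on them show the engine
  reproduces the assay's fragment arithmetic and diagnostic rules, not that
  any natural sequence lacks confounding restriction sites.

All randomness flows through `numpy.random.default_rng` seeded from the
configuration; equal seeds give byte-identical outputs.

What the simulations do *not* emulate: multi-generation population dynamics,
selection, genotyping error, partial digestion, and gel-migration noise.

## Problem sizes

The simulation-based checks use 200 replicates at n = 203 for haplotype
recovery, single runs at n = 5,000 for odds-ratio recovery and n = 10,000 to
50,000 for frequency-margin checks — sizes at which binomial standard errors
make the assertions sharp while the whole suite runs in a few seconds. The
reproduction pipeline itself is deterministic arithmetic on count tables.

## Known limitations

* Biallelic loci only; no phased input; no genome-scale LD scans.
* Exact HWE p-values depend on the tie-handling convention near p = 1 (see
  above).
* The Woolf CI is the only interval offered; exact or score intervals are
  out of scope.
* Printed values in the bundled survey that are internally inconsistent
  (an LD χ² not derivable from the genotype table; two CI digits that do not
  follow from the printed counts under Woolf's formula) are reported as
  computed, with the discrepancy noted here rather than matched.
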