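"""Synthetic-data generators for the analysis pipeline.

Three generators cover every input the pipeline consumes, so tests and
examples run without any downloads:

* two-locus genotype populations drawn from specified haplotype frequencies,
  optionally with excess homozygosity via an inbreeding coefficient;
* genotype-dependent insecticide-bioassay outcomes (dead/alive tables plus a
  control batch);
* 171-bp amplicon sequences satisfying the differential PCR-RFLP design
  constraints of the kdr assay (see :func:`make_amplicon_fixtures`).

All randomness flows through one ``numpy`` generator seeded from the config;
identical seeds give byte-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .datatypes import BioassayRecord, GenotypeCounts, PhenoGenoTable, TwoLocusCounts
from .errors import ValidationError
from .rflp import Amplicon, PrimerPair, find_cut_sites, get_enzyme, reverse_complement

#: primer pair of the kdr domain-III assay
AEKDR_PRIMERS = PrimerPair(
    forward_seq="TGGGAAAGCAGCCGATTC",
    reverse_seq="CCTCCGTCATGAACATTTCC",
    names="AekdrF/AekdrR",
)

AMPLICON_LENGTH = 171

GENOTYPE_INDEX = {"wild_hom": 0, "het": 1, "mut_hom": 2}


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for the synthetic generators.

    Defaults mirror the Delhi survey this package analyses: 203 genotyped
    mosquitoes, haplotype frequencies (f_TF, f_TC, f_IF, f_IC) =
    (0.21, 0.66, 0.00, 0.13) with the wild/wild-mutant orientation of the
    T1520/F1534 loci, and F1534-genotype-dependent survival under DDT
    exposure chosen so the mutant homozygote is strongly protected.
    """

    n_individuals: int = 203
    haplotype_freqs: tuple = (0.21, 0.66, 0.00, 0.13)
    inbreeding_f: float = 0.0
    survival_by_genotype: dict = field(
        default_factory=lambda: {"wild_hom": 0.5, "het": 0.75, "mut_hom": 0.95}
    )
    control_mortality: float = 0.02
    n_control: int = 100
    insecticide: str = "DDT"
    concentration_pct: float = 4.0
    seed: int = 0

    def __post_init__(self):
        f = np.asarray(self.haplotype_freqs, dtype=float)
        if f.shape != (4,) or np.any(f < 0) or abs(f.sum() - 1.0) > 1e-9:
            raise ValidationError("haplotype_freqs must be 4 non-negative values summing to 1")
        if not 0.0 <= self.inbreeding_f <= 1.0:
            raise ValidationError(
                "inbreeding_f must lie in [0, 1] (the copy-mixture model does "
                "not represent heterozygote excess)"
            )
        for g, s in self.survival_by_genotype.items():
            if g not in GENOTYPE_INDEX or not 0.0 <= s <= 1.0:
                raise ValidationError(f"bad survival entry {g!r}: {s!r}")
        if not 0.0 <= self.control_mortality <= 1.0:
            raise ValidationError("control_mortality must lie in [0, 1]")


def _haplotypes_to_genotypes(h1: np.ndarray, h2: np.ndarray) -> np.ndarray:
    """Map haplotype indices (0..3 = 11,12,21,22) to per-locus genotype
    indices (0 = wild hom, 1 = het, 2 = mut hom); returns (n, 2) array."""
    a1 = h1 // 2  # mutant allele at locus 1?
    b1 = h1 % 2  # mutant allele at locus 2?
    a2 = h2 // 2
    b2 = h2 % 2
    return np.stack([a1 + a2, b1 + b2], axis=1)


def simulate_genotypes(cfg: SimulationConfig, rng: np.random.Generator | None = None):
    """Draw a two-locus genotype population.

    Each individual carries two haplotypes: independent draws from the
    configured frequencies, except that with probability ``inbreeding_f``
    the second is a copy of the first (excess homozygosity at both loci).

    Returns ``(TwoLocusCounts, roster)`` where the roster is an (n, 2)
    integer array of per-locus genotype codes (0/1/2 mutant-allele dose).
    """
    rng = rng or np.random.default_rng(cfg.seed)
    f = np.asarray(cfg.haplotype_freqs, dtype=float)
    n = cfg.n_individuals
    h1 = rng.choice(4, size=n, p=f)
    h2 = rng.choice(4, size=n, p=f)
    if cfg.inbreeding_f > 0:
        copy = rng.random(n) < cfg.inbreeding_f
        h2 = np.where(copy, h1, h2)
    roster = _haplotypes_to_genotypes(h1, h2)
    table = np.zeros((3, 3), dtype=int)
    np.add.at(table, (roster[:, 0], roster[:, 1]), 1)
    counts = TwoLocusCounts("locus1", "locus2", tuple(map(tuple, table.tolist())))
    return counts, roster


def simulate_bioassay(roster: np.ndarray, cfg: SimulationConfig, rng=None):
    """Expose a simulated population to an insecticide.

    Each individual survives with the probability configured for its
    locus-2 genotype; an independent control batch dies at
    ``control_mortality``. Returns ``(PhenoGenoTable, BioassayRecord)``.
    """
    rng = rng or np.random.default_rng(cfg.seed + 1)
    surv_by_idx = np.array(
        [cfg.survival_by_genotype[g] for g in ("wild_hom", "het", "mut_hom")]
    )
    p_survive = surv_by_idx[roster[:, 1]]
    alive = rng.random(len(roster)) < p_survive
    dead_counts = np.zeros(3, dtype=int)
    alive_counts = np.zeros(3, dtype=int)
    np.add.at(dead_counts, roster[~alive, 1], 1)
    np.add.at(alive_counts, roster[alive, 1], 1)
    pg = PhenoGenoTable(
        insecticide=cfg.insecticide,
        dead=GenotypeCounts("locus2", *map(int, dead_counts)),
        alive=GenotypeCounts("locus2", *map(int, alive_counts)),
    )
    control_dead = int(rng.binomial(cfg.n_control, cfg.control_mortality))
    rec = BioassayRecord(
        insecticide=cfg.insecticide,
        concentration_pct=cfg.concentration_pct,
        n_exposed=len(roster),
        n_dead=int((~alive).sum()),
        control_n=cfg.n_control,
        control_dead=control_dead,
    )
    return pg, rec


# --- amplicon fixtures -------------------------------------------------------
#
# Synthetic 171-bp amplicon satisfying the assay's printed constraints; the
# real GenBank haplotypes are not reproduced, only the features the RFLP
# design depends on:
#   * starts with AekdrF, ends with the reverse complement of AekdrR;
#   * a T1520-like codon ACC whose C->T second-position change (-> ATC)
#     creates exactly one BsaBI site (GATNN^NNATC) cutting after base 143;
#   * an F1534-like codon TTC whose T->G second-position change (-> TGC)
#     creates exactly one SsiI site (C^CGC, read on the minus strand as GCGG)
#     cutting after base 103;
#   * the wild sequence is cut by neither enzyme.

_FWD = AEKDR_PRIMERS.forward_seq
_REV_RC = reverse_complement(AEKDR_PRIMERS.reverse_seq)

# fixed scaffold, 0-based positions
_POS_1534 = 101  # codon TTC at 102-104 (1-based)
_POS_1520 = 145  # codon ACC at 146-148 (1-based)
_POS_BSABI_GAT = 138  # GAT at 139-141 (1-based)


def _apply_scaffold(filler: str) -> str:
    seq = list(_FWD + filler + _REV_RC)
    assert len(seq) == AMPLICON_LENGTH
    seq[_POS_1534 : _POS_1534 + 3] = "TTC"
    seq[_POS_1534 + 3 : _POS_1534 + 5] = "GG"  # GCGG context once TTC -> TGC
    seq[_POS_BSABI_GAT : _POS_BSABI_GAT + 3] = "GAT"
    seq[_POS_1520 : _POS_1520 + 3] = "ACC"
    return "".join(seq)


def _mutate(seq: str, pos0: int, base: str) -> str:
    return seq[:pos0] + base + seq[pos0 + 1 :]


def make_amplicon_fixtures(seed: int = 0) -> dict:
    """Deterministically build the four assay amplicons.

    Returns a dict with keys ``wild``, ``mut_1520I``, ``mut_1534C`` and
    ``double_mutant`` mapping to 171-bp sequences. Generation draws filler
    bases from a seeded generator and retries until every digest constraint
    holds, so the result is deterministic for a given seed.
    """
    rng = np.random.default_rng(seed)
    bsabi = get_enzyme("BsaBI")
    ssii = get_enzyme("SsiI")
    n_fill = AMPLICON_LENGTH - len(_FWD) - len(_REV_RC)
    for _ in range(10_000):
        filler = "".join(rng.choice(list("ACGT"), size=n_fill))
        wild = _apply_scaffold(filler)
        m1520 = _mutate(wild, _POS_1520 + 1, "T")  # ACC -> ATC
        m1534 = _mutate(wild, _POS_1534 + 1, "G")  # TTC -> TGC
        double = _mutate(m1520, _POS_1534 + 1, "G")
        ok = (
            find_cut_sites(wild, bsabi) == []
            and find_cut_sites(wild, ssii) == []
            and find_cut_sites(m1520, bsabi) == [143]
            and find_cut_sites(m1520, ssii) == []
            and find_cut_sites(m1534, ssii) == [103]
            and find_cut_sites(m1534, bsabi) == []
            and find_cut_sites(double, bsabi) == [143]
            and find_cut_sites(double, ssii) == [103]
        )
        if ok:
            return {
                "wild": wild,
                "mut_1520I": m1520,
                "mut_1534C": m1534,
                "double_mutant": double,
            }
    raise ValidationError(
        "could not satisfy amplicon design constraints — indicates a bug in the scaffold"
    )


def fixture_amplicon(name: str, seed: int = 0) -> Amplicon:
    """One fixture sequence wrapped as an :class:`Amplicon`."""
    seq = make_amplicon_fixtures(seed)[name]
    return Amplicon(sequence=seq, template_start=1, template_end=len(seq))
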