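"""Core domain containers for genotype counts and bioassay tables.

Genotype ordering convention used throughout the package:
(wild homozygote, heterozygote, mutant homozygote) — e.g. FF/FC/CC for the
F1534 locus and TT/TI/II for T1520 of the Aedes aegypti voltage-gated sodium
channel.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ValidationError

GENOTYPE_LABELS = ("wild_hom", "het", "mut_hom")


def _check_count(value, name: str) -> int:
    if isinstance(value, (bool,)) or not float(value).is_integer():
        raise ValidationError(f"{name} must be a non-negative integer, got {value!r}")
    value = int(value)
    if value < 0:
        raise ValidationError(f"{name} must be >= 0, got {value}")
    return value


@dataclass(frozen=True)
class GenotypeCounts:
    """Counts of the three genotypes at one biallelic locus in one population."""

    locus_name: str
    n_wild_hom: int
    n_het: int
    n_mut_hom: int
    population: str = ""

    def __post_init__(self):
        for f in ("n_wild_hom", "n_het", "n_mut_hom"):
            object.__setattr__(self, f, _check_count(getattr(self, f), f))

    @property
    def total(self) -> int:
        return self.n_wild_hom + self.n_het + self.n_mut_hom

    def as_tuple(self) -> tuple[int, int, int]:
        return (self.n_wild_hom, self.n_het, self.n_mut_hom)

    def require_nonempty(self) -> None:
        if self.total == 0:
            raise ValidationError(
                f"genotype table for locus {self.locus_name!r} "
                f"(population {self.population!r}) has total 0"
            )


@dataclass(frozen=True)
class BioassayRecord:
    """One WHO-style susceptibility bioassay: treated and control batches."""

    insecticide: str
    concentration_pct: float
    n_exposed: int
    n_dead: int
    control_n: int
    control_dead: int
    replicates: int = 1

    def __post_init__(self):
        for f in ("n_exposed", "n_dead", "control_n", "control_dead", "replicates"):
            object.__setattr__(self, f, _check_count(getattr(self, f), f))
        if self.n_dead > self.n_exposed:
            raise ValidationError("n_dead exceeds n_exposed")
        if self.control_dead > self.control_n:
            raise ValidationError("control_dead exceeds control_n")

    @property
    def observed_mortality_pct(self) -> float:
        if self.n_exposed == 0:
            raise ValidationError("bioassay with zero exposed mosquitoes")
        return 100.0 * self.n_dead / self.n_exposed

    @property
    def control_mortality_pct(self) -> float:
        if self.control_n == 0:
            return 0.0
        return 100.0 * self.control_dead / self.control_n


@dataclass(frozen=True)
class PhenoGenoTable:
    """Dead/alive x genotype counts for one insecticide exposure."""

    insecticide: str
    dead: GenotypeCounts
    alive: GenotypeCounts

    def __post_init__(self):
        if self.dead.locus_name != self.alive.locus_name:
            raise ValidationError(
                "dead and alive rows refer to different loci: "
                f"{self.dead.locus_name!r} vs {self.alive.locus_name!r}"
            )

    @property
    def locus_name(self) -> str:
        return self.dead.locus_name

    @property
    def total(self) -> int:
        return self.dead.total + self.alive.total


@dataclass(frozen=True)
class TwoByTwo:
    """2x2 contingency table with fixed roles:

    a = alive, mutant class     b = dead, mutant class
    c = alive, wild class       d = dead, wild class

    With this orientation OR = ad/bc > 1 means the mutant class survives
    insecticide exposure more often (protection).
    """

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self):
        for f in "abcd":
            object.__setattr__(self, f, _check_count(getattr(self, f), f))
        if self.a + self.b + self.c + self.d == 0:
            raise ValidationError("empty 2x2 table")

    def as_array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]], dtype=float)

    def transposed(self) -> "TwoByTwo":
        return TwoByTwo(self.a, self.c, self.b, self.d)

    def rows_swapped(self) -> "TwoByTwo":
        return TwoByTwo(self.c, self.d, self.a, self.b)


@dataclass(frozen=True)
class TwoLocusCounts:
    """3x3 table of individuals cross-classified by genotype at two biallelic
    loci; axis order (wild_hom, het, mut_hom) on both axes, locus 1 on rows."""

    locus1_name: str
    locus2_name: str
    counts: tuple  # 3x3 nested tuple of ints

    def __post_init__(self):
        arr = np.asarray(self.counts)
        if arr.shape != (3, 3):
            raise ValidationError(f"two-locus table must be 3x3, got {arr.shape}")
        vals = tuple(
            tuple(_check_count(v, f"counts[{i}][{j}]") for j, v in enumerate(row))
            for i, row in enumerate(arr.tolist())
        )
        object.__setattr__(self, "counts", vals)
        if self.total == 0:
            raise ValidationError("two-locus table has grand total 0")

    @property
    def matrix(self) -> np.ndarray:
        return np.array(self.counts, dtype=int)

    @property
    def total(self) -> int:
        return int(np.asarray(self.counts).sum())

    def margin1(self) -> GenotypeCounts:
        """Genotype counts at locus 1 (row sums)."""
        r = self.matrix.sum(axis=1)
        return GenotypeCounts(self.locus1_name, *map(int, r))

    def margin2(self) -> GenotypeCounts:
        """Genotype counts at locus 2 (column sums)."""
        c = self.matrix.sum(axis=0)
        return GenotypeCounts(self.locus2_name, *map(int, c))


@dataclass
class ReportBundle:
    """Accumulates every result row of a pipeline run, with provenance."""

    allele_frequencies: list = field(default_factory=list)
    hwe: list = field(default_factory=list)
    association: list = field(default_factory=list)
    haplotypes: list = field(default_factory=list)
    ld: list = field(default_factory=list)
    metadata: dict = field(default_factory=dict)

    def is_empty(self) -> bool:
        return not any(
            (self.allele_frequencies, self.hwe, self.association, self.haplotypes, self.ld)
        )
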