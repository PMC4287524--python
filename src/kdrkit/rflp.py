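"""In-silico PCR-RFLP engine.

Implements the computational side of a differential PCR-RFLP genotyping
assay: primer-pair amplification on a template, IUPAC-aware restriction-site
scanning on both strands, complete-digest fragment prediction, a search for
enzymes whose band patterns discriminate two alleles of an amplicon, and
genotype calling from observed gel band patterns.

Coordinates are 1-based; a cut position k means the top strand is cleaved
after base k, so fragment lengths follow from simple differences. For a
recognition site found on the minus strand, the reported coordinate is the
corresponding top-strand cleavage position (derived from the enzyme's
bottom-strand cut offset).
"""

from __future__ import annotations

import csv
import re
from dataclasses import dataclass, field
from importlib import resources

from .errors import (
    AmbiguousProductError,
    PrimerBindingError,
    ValidationError,
)

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}
_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def _check_dna(seq: str, name: str = "sequence", alphabet: str = "ACGT") -> str:
    seq = seq.upper()
    bad = set(seq) - set(alphabet)
    if bad:
        raise ValidationError(f"{name} contains characters outside {alphabet}: {sorted(bad)}")
    return seq


@dataclass(frozen=True)
class RestrictionEnzyme:
    """A restriction enzyme: IUPAC recognition string and cut offsets.

    ``cut_offset_top`` is the number of recognition bases 5' of the top-strand
    cleavage; ``cut_offset_bottom`` the analogue on the bottom strand (counted
    along the recognition 5'->3' on the top strand, from its 3' end).
    """

    name: str
    recognition: str
    cut_offset_top: int
    cut_offset_bottom: int | None = None

    def __post_init__(self):
        rec = _check_dna(self.recognition, "recognition", "".join(IUPAC))
        if not rec:
            raise ValidationError("empty recognition sequence")
        object.__setattr__(self, "recognition", rec)
        if not 0 <= self.cut_offset_top <= len(rec):
            raise ValidationError("cut_offset_top outside recognition sequence")
        if self.cut_offset_bottom is None:
            # default: symmetric cut (blunt only for palindromes)
            object.__setattr__(self, "cut_offset_bottom", len(rec) - self.cut_offset_top)

    @property
    def regex(self) -> re.Pattern:
        return re.compile("(?=(" + "".join(f"[{IUPAC[b]}]" for b in self.recognition) + "))")


@dataclass(frozen=True)
class PrimerPair:
    forward_seq: str
    reverse_seq: str
    names: str = ""

    def __post_init__(self):
        for f in ("forward_seq", "reverse_seq"):
            seq = _check_dna(getattr(self, f), f)
            if len(seq) < 10:
                raise ValidationError(f"{f} shorter than 10 nt")
            object.__setattr__(self, f, seq)


@dataclass(frozen=True)
class Amplicon:
    sequence: str
    template_start: int  # 1-based inclusive
    template_end: int

    def __post_init__(self):
        object.__setattr__(self, "sequence", _check_dna(self.sequence, "amplicon"))
        if self.template_end - self.template_start + 1 != len(self.sequence):
            raise ValidationError("amplicon coordinates inconsistent with sequence length")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class DigestResult:
    cut_positions: tuple  # sorted, 1-based "after base k"
    fragment_lengths: tuple

    @property
    def n_fragments(self) -> int:
        return len(self.fragment_lengths)


@dataclass(frozen=True)
class RflpAssay:
    """A diagnostic digest: one enzyme whose observable band patterns differ
    between the two alleles of a locus."""

    locus_name: str
    enzyme: RestrictionEnzyme
    expected_bands_by_allele: dict  # allele name -> frozenset of lengths
    min_detectable_bp: int = 50

    def pattern(self, allele: str) -> frozenset:
        return self.expected_bands_by_allele[allele]


@dataclass(frozen=True)
class GenotypeCall:
    locus_name: str
    genotype: str  # wild_hom | het | mut_hom | uninterpretable


def find_cut_sites(seq: str, enzyme: RestrictionEnzyme) -> list[int]:
    """Unique top-strand cleavage positions (1-based, cut after base k).

    Both strands are scanned with IUPAC expansion; cuts falling on the
    sequence ends (producing an empty fragment) are discarded.
    """
    seq = _check_dna(seq, "seq")
    L = len(enzyme.recognition)
    cuts = set()
    for m in enzyme.regex.finditer(seq):
        cuts.add(m.start() + enzyme.cut_offset_top)
    rc_pattern = RestrictionEnzyme(
        enzyme.name, reverse_complement(enzyme.recognition), enzyme.cut_offset_top
    )
    for m in rc_pattern.regex.finditer(seq):
        cuts.add(m.start() + (L - enzyme.cut_offset_bottom))
    return sorted(c for c in cuts if 0 < c < len(seq))


def digest(amplicon: Amplicon, enzyme: RestrictionEnzyme) -> DigestResult:
    """Complete digestion: fragment lengths between ordered cut positions."""
    cuts = find_cut_sites(amplicon.sequence, enzyme)
    bounds = [0] + cuts + [len(amplicon)]
    frags = tuple(b - a for a, b in zip(bounds, bounds[1:]))
    return DigestResult(cut_positions=tuple(cuts), fragment_lengths=frags)


def _primer_matches(template: str, primer: str, max_mismatch: int) -> list[int]:
    if max_mismatch == 0:
        return [m.start() for m in re.finditer("(?=" + primer + ")", template)]
    hits = []
    k = len(primer)
    for s in range(len(template) - k + 1):
        mm = sum(1 for a, b in zip(template[s : s + k], primer) if a != b)
        if mm <= max_mismatch:
            hits.append(s)
    return hits


def in_silico_pcr(template: str, primers: PrimerPair, max_mismatch: int = 0) -> Amplicon:
    """Predict the PCR product of a primer pair on a template.

    The forward primer anneals to a plus-strand site and the reverse
    complement of the reverse primer must occur downstream; both template
    strands are searched, so template orientation does not matter. Exactly
    one product must result.
    """
    template = _check_dna(template, "template")
    rev_rc = reverse_complement(primers.reverse_seq)
    products = {}
    for strand in (template, reverse_complement(template)):
        f_hits = _primer_matches(strand, primers.forward_seq, max_mismatch)
        r_hits = _primer_matches(strand, rev_rc, max_mismatch)
        for f in f_hits:
            for r in r_hits:
                end = r + len(rev_rc)
                if end > f + len(primers.forward_seq) and r >= f:
                    products.setdefault(strand[f:end], (f + 1, end))
    if not products:
        raise PrimerBindingError(
            f"primer pair {primers.names or '(unnamed)'} produces no product on this template"
        )
    if len(products) > 1:
        raise AmbiguousProductError(
            f"primer pair predicts {len(products)} distinct products "
            f"(lengths {sorted(len(s) for s in products)})"
        )
    seq, (start, end) = next(iter(products.items()))
    return Amplicon(sequence=seq, template_start=start, template_end=end)


def observable_pattern(lengths, min_detectable_bp: int = 50, resolution_bp: int = 0) -> frozenset:
    """Band pattern as seen on a gel: short fragments below the detection
    limit are dropped; bands closer than ``resolution_bp`` merge into one
    (represented by the longer length)."""
    vis = sorted({l for l in lengths if l >= min_detectable_bp})
    if resolution_bp <= 0 or len(vis) < 2:
        return frozenset(vis)
    merged = [[vis[0]]]
    for l in vis[1:]:
        if l - merged[-1][-1] <= resolution_bp:
            merged[-1].append(l)
        else:
            merged.append([l])
    return frozenset(max(group) for group in merged)


def find_discriminating_enzymes(
    wild: Amplicon,
    mutant: Amplicon,
    db: list[RestrictionEnzyme],
    min_detectable_bp: int = 50,
    resolution_bp: int = 0,
    locus_name: str = "locus",
) -> list[RflpAssay]:
    """Enzymes whose observable band patterns distinguish the two alleles.

    Candidates must differ both in cut-site sets and in gel-observable band
    patterns (after masking fragments below ``min_detectable_bp``); results
    are ranked by decreasing band-size separation between the two patterns.
    """
    if not db:
        raise ValidationError("empty enzyme database")
    if len(wild) != len(mutant):
        raise ValidationError("wild and mutant amplicons differ in length")
    if wild.sequence == mutant.sequence:
        return []
    assays = []
    for enz in db:
        cw = find_cut_sites(wild.sequence, enz)
        cm = find_cut_sites(mutant.sequence, enz)
        if cw == cm:
            continue
        pw = observable_pattern(
            digest(wild, enz).fragment_lengths, min_detectable_bp, resolution_bp
        )
        pm = observable_pattern(
            digest(mutant, enz).fragment_lengths, min_detectable_bp, resolution_bp
        )
        if pw == pm:
            continue
        assays.append(
            RflpAssay(
                locus_name=locus_name,
                enzyme=enz,
                expected_bands_by_allele={"wild": pw, "mutant": pm},
                min_detectable_bp=min_detectable_bp,
            )
        )

    def separation(assay: RflpAssay) -> int:
        pw = assay.pattern("wild")
        pm = assay.pattern("mutant")
        diffs = [abs(a - b) for a in pw ^ pm for b in pw | pm if a != b]
        return min(diffs) if diffs else 0

    return sorted(assays, key=separation, reverse=True)


def call_genotype(assay: RflpAssay, observed_bands) -> GenotypeCall:
    """Diagnose a genotype from an observed band-length set.

    Wild pattern alone -> wild homozygote; mutant pattern alone -> mutant
    homozygote; their union -> heterozygote; anything else is
    uninterpretable.
    """
    obs = frozenset(int(b) for b in observed_bands)
    if not obs:
        raise ValidationError("observed band set is empty")
    wild = assay.pattern("wild")
    mut = assay.pattern("mutant")
    if obs == wild:
        g = "wild_hom"
    elif obs == mut:
        g = "mut_hom"
    elif obs == wild | mut:
        g = "het"
    else:
        g = "uninterpretable"
    return GenotypeCall(locus_name=assay.locus_name, genotype=g)


def load_enzymes(path=None) -> list[RestrictionEnzyme]:
    """Load an enzyme table (CSV: name, recognition, cut_offset_top,
    cut_offset_bottom). Without a path, the bundled REBASE-derived table is
    used (includes BsaBI and SsiI)."""
    if path is None:
        source = resources.files("kdrkit.data").joinpath("enzymes.csv").read_text()
        rows = list(csv.DictReader(source.splitlines()))
    else:
        with open(path, newline="") as fh:
            rows = list(csv.DictReader(fh))
    enzymes = []
    for row in rows:
        enzymes.append(
            RestrictionEnzyme(
                name=row["name"],
                recognition=row["recognition"],
                cut_offset_top=int(row["cut_offset_top"]),
                cut_offset_bottom=int(row["cut_offset_bottom"]),
            )
        )
    return enzymes


def get_enzyme(name: str, db=None) -> RestrictionEnzyme:
    for enz in db or load_enzymes():
        if enz.name.lower() == name.lower():
            return enz
    raise ValidationError(f"enzyme {name!r} not in database")
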