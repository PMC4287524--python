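"""CSV and FASTA readers/writers plus access to the bundled survey tables."""

from __future__ import annotations

import csv
from importlib import resources
from pathlib import Path

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .datatypes import GenotypeCounts, PhenoGenoTable, TwoLocusCounts
from .errors import FormatError, ValidationError

_GC_COLUMNS = ("population", "locus", "n_wild_hom", "n_het", "n_mut_hom")
_PG_COLUMNS = ("insecticide", "locus", "phenotype", "n_wild_hom", "n_het", "n_mut_hom")


def bundled_path(name: str):
    """Path-like handle on one of the bundled survey CSV tables."""
    return resources.files("kdrkit.data").joinpath(name)


def _read_rows(path) -> list[dict]:
    text = path.read_text() if hasattr(path, "read_text") else Path(path).read_text()
    return list(csv.DictReader(text.splitlines()))


def _require_columns(rows: list[dict], required, path) -> None:
    if not rows:
        raise FormatError(f"{path}: empty table")
    missing = [c for c in required if c not in rows[0]]
    if missing:
        raise FormatError(f"{path}: missing column(s) {missing}")


def _parse_count(value, column: str, row_num: int):
    try:
        v = int(value)
    except (TypeError, ValueError):
        raise ValidationError(f"row {row_num}: {column} is not an integer: {value!r}")
    if v < 0:
        raise ValidationError(f"row {row_num}: {column} is negative: {v}")
    return v


def load_genotype_counts(path) -> list[GenotypeCounts]:
    """Read per-population genotype counts (one row per population/locus)."""
    rows = _read_rows(path)
    _require_columns(rows, _GC_COLUMNS, path)
    out = []
    for i, row in enumerate(rows, start=2):  # header is line 1
        counts = GenotypeCounts(
            locus_name=row["locus"],
            population=row["population"],
            n_wild_hom=_parse_count(row["n_wild_hom"], "n_wild_hom", i),
            n_het=_parse_count(row["n_het"], "n_het", i),
            n_mut_hom=_parse_count(row["n_mut_hom"], "n_mut_hom", i),
        )
        if counts.total == 0:
            raise ValidationError(f"row {i}: all genotype counts are zero")
        out.append(counts)
    return out


def write_genotype_counts(records: list[GenotypeCounts], path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(_GC_COLUMNS)
        for r in records:
            w.writerow([r.population, r.locus_name, r.n_wild_hom, r.n_het, r.n_mut_hom])


def load_pheno_geno_tables(path) -> list[PhenoGenoTable]:
    """Read dead/alive x genotype tables; rows pair up by insecticide."""
    rows = _read_rows(path)
    _require_columns(rows, _PG_COLUMNS, path)
    by_key: dict[tuple, dict] = {}
    for i, row in enumerate(rows, start=2):
        pheno = row["phenotype"].strip().lower()
        if pheno not in ("dead", "alive"):
            raise ValidationError(f"row {i}: phenotype must be dead or alive, got {pheno!r}")
        gc = GenotypeCounts(
            locus_name=row["locus"],
            n_wild_hom=_parse_count(row["n_wild_hom"], "n_wild_hom", i),
            n_het=_parse_count(row["n_het"], "n_het", i),
            n_mut_hom=_parse_count(row["n_mut_hom"], "n_mut_hom", i),
        )
        by_key.setdefault((row["insecticide"], row["locus"]), {})[pheno] = gc
    out = []
    for (insecticide, _locus), parts in by_key.items():
        if set(parts) != {"dead", "alive"}:
            raise FormatError(f"{path}: {insecticide}: need one dead and one alive row")
        out.append(PhenoGenoTable(insecticide=insecticide, dead=parts["dead"], alive=parts["alive"]))
    return out


def _genotype_order(labels, wild_allele: str | None):
    """Map genotype labels like TT/TI/II to (wild_hom, het, mut_hom) order."""
    labels = list(labels)
    if len(labels) != 3 or len(set(labels)) != 3:
        raise FormatError(f"expected 3 distinct genotype labels, got {labels}")
    hets = [l for l in labels if len(set(l)) == 2]
    homs = [l for l in labels if len(set(l)) == 1]
    if len(hets) != 1 or len(homs) != 2 or any(len(l) != 2 for l in labels):
        raise FormatError(f"genotype labels must be two-letter XX/XY/YY, got {labels}")
    if wild_allele is None:
        wild_hom = homs[0] if labels.index(homs[0]) < labels.index(homs[1]) else homs[1]
    else:
        matches = [l for l in homs if l[0] == wild_allele]
        if not matches:
            raise FormatError(f"no homozygote label for wild allele {wild_allele!r} in {labels}")
        wild_hom = matches[0]
    mut_hom = next(l for l in homs if l != wild_hom)
    return [labels.index(wild_hom), labels.index(hets[0]), labels.index(mut_hom)]


def load_two_locus_counts(
    path, wild_allele1: str | None = None, wild_allele2: str | None = None
) -> TwoLocusCounts:
    """Read a labelled 3x3 two-locus genotype table.

    The header cell names the loci as ``locus1\\locus2``; row labels are
    locus-1 genotypes, column labels locus-2 genotypes. Rows/columns are
    re-ordered to the (wild_hom, het, mut_hom) convention by label; without
    explicit wild alleles the first homozygote label in file order is taken
    as wild.
    """
    text = path.read_text() if hasattr(path, "read_text") else Path(path).read_text()
    rows = [r for r in csv.reader(text.splitlines()) if r]
    if len(rows) != 4 or any(len(r) != 4 for r in rows):
        raise FormatError(f"{path}: expected a labelled 3x3 block (4x4 cells incl. labels)")
    corner = rows[0][0]
    locus1_name, _, locus2_name = corner.partition("\\")
    locus1_name = locus1_name.strip() or "locus1"
    locus2_name = locus2_name.strip() or "locus2"
    col_labels = [c.strip() for c in rows[0][1:]]
    row_labels = [r[0].strip() for r in rows[1:]]
    try:
        values = [[int(v) for v in r[1:]] for r in rows[1:]]
    except ValueError as e:
        raise ValidationError(f"{path}: non-integer count in 3x3 block ({e})")
    row_order = _genotype_order(row_labels, wild_allele1)
    col_order = _genotype_order(col_labels, wild_allele2)
    matrix = tuple(
        tuple(values[i][j] for j in col_order) for i in row_order
    )
    return TwoLocusCounts(locus1_name, locus2_name, matrix)


def write_two_locus_counts(counts: TwoLocusCounts, path, row_labels, col_labels) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow([f"{counts.locus1_name}\\{counts.locus2_name}", *col_labels])
        for label, row in zip(row_labels, counts.counts):
            w.writerow([label, *row])


def read_fasta(path) -> dict[str, str]:
    """FASTA file -> {record id: uppercase sequence}."""
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(sequences: dict[str, str], path) -> None:
    records = [SeqRecord(Seq(seq), id=name, description="") for name, seq in sequences.items()]
    SeqIO.write(records, str(path), "fasta")
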