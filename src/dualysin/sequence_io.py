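"""Core data model and file formats for the endolysin screening pipeline.

The pipeline operates on cohorts of phage lytic-enzyme genes.  Each gene is
held as a :class:`GeneRecord` carrying the coding sequence (CDS, including
the stop codon), the translated protein, the genus of the phage host (the
organism in which translation initiation would occur naturally) and a family
label separating the endolysin cohort from a negative-control protein family.

Conserved-domain annotations (:class:`DomainHit`) are consumed as precomputed
tabular hits with Pfam-style accessions; a configurable accession-to-category
map assigns each hit a functional role (catalytic, cell-wall binding, phage
tail, or other).  Translation-initiation-rate tables (:class:`TirTable`) allow
externally computed TIR predictions to drive the pipeline instead of the
built-in scorer.

Validation is collect-and-report: records that violate invariants are listed
in :class:`ValidationIssue` entries and excluded from the cohort rather than
aborting the read, so large cohorts surface all problems at once.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

STOP_CODONS = {"TAA", "TAG", "TGA"}
START_CODONS = ("ATG", "GTG", "TTG")
AA_ALPHABET = set("ACDEFGHIKLMNPQRSTVWY")

#: Default accession -> functional category map.  Catalytic and cell-wall
#: binding accessions are the peptidoglycan-hydrolase domains commonly found
#: in endolysins of phages infecting Gram-positive bacteria; the tail set
#: flags virion-structural domains diagnostic of misannotated endolysins.
DEFAULT_CATEGORY_MAP: dict[str, str] = {
    "PF01510": "catalytic",  # Amidase_2
    "PF01520": "catalytic",  # Amidase_3
    "PF05382": "catalytic",  # Amidase_5
    "PF05257": "catalytic",  # CHAP
    "PF01183": "catalytic",  # Glyco_hydro_25
    "PF01551": "catalytic",  # Peptidase_M23
    "PF01832": "catalytic",  # N-acetylglucosaminidase (Mannosyl_glycop)
    "PF00959": "catalytic",  # Phage_lysozyme
    "PF08460": "cwbd",       # bacterial SH3_5
    "PF01473": "cwbd",       # CW_binding_1 (choline-binding repeat)
    "PF05709": "tail",       # Siphovirus-type tail component
    "PF04865": "tail",       # Baseplate_J
    "PF10145": "tail",       # phage-related minor tail protein
    "PF04860": "other",      # Phage_portal (control family marker)
}

CATEGORIES = ("catalytic", "cwbd", "tail", "other")


class ConfigurationError(ValueError):
    """Raised when an input file is structurally unusable (e.g. missing columns)."""


@dataclass
class ValidationIssue:
    """A record-level problem found while reading or validating input."""

    record_id: str
    field: str
    message: str

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"{self.record_id}: [{self.field}] {self.message}"


@dataclass
class GeneRecord:
    """One lytic-enzyme gene: CDS (with stop codon), protein, host and family."""

    gene_id: str
    cds: str
    protein: str
    host_genus: str
    family: str = "endolysin"
    source: str = ""


@dataclass
class DomainHit:
    """A conserved-domain interval on the protein, 1-based inclusive coordinates."""

    accession: str
    name: str
    start_aa: int
    end_aa: int
    evalue: float = 0.0
    category: str = "other"


@dataclass
class TirTable:
    """Precomputed TIR scores keyed by (gene_id, 1-based codon index)."""

    entries: dict[tuple[str, int], float] = field(default_factory=dict)

    def get(self, gene_id: str, codon_index: int) -> float | None:
        return self.entries.get((gene_id, codon_index))

    @property
    def genes(self) -> set[str]:
        return {g for g, _ in self.entries}


@dataclass
class Cohort:
    """Validated gene records plus the issues found while reading them."""

    records: list[GeneRecord]
    issues: list[ValidationIssue] = field(default_factory=list)

    def __iter__(self):
        return iter(self.records)

    def __len__(self) -> int:
        return len(self.records)


def translate_cds(cds: str) -> str:
    """Translate a CDS with the bacterial code (table 11), dropping the stop.

    The first codon is read as Met regardless of whether it is ATG, GTG or
    TTG, matching initiator-tRNA behaviour.
    """
    body = cds[:-3]
    aa = str(Seq(body).translate(table=11))
    if aa:
        aa = "M" + aa[1:]
    return aa


def validate_gene(rec: GeneRecord) -> list[ValidationIssue]:
    """Check the CDS/protein consistency invariants of a single record."""
    issues: list[ValidationIssue] = []

    def bad(fieldname: str, msg: str) -> None:
        issues.append(ValidationIssue(rec.gene_id, fieldname, msg))

    if not rec.host_genus:
        bad("host_genus", "host genus is empty")
    cds = rec.cds.upper()
    if not cds:
        bad("cds", "empty CDS")
        return issues
    if set(cds) - set("ACGT"):
        bad("cds", "non-ACGT characters in CDS")
        return issues
    if len(cds) % 3 != 0:
        bad("cds", f"CDS length {len(cds)} not divisible by 3")
        return issues
    if cds[-3:] not in STOP_CODONS:
        bad("cds", f"CDS does not end with a stop codon (last codon {cds[-3:]})")
        return issues
    if cds[:3] not in START_CODONS:
        bad("cds", f"first codon {cds[:3]} is not ATG/GTG/TTG")
    protein = rec.protein.upper()
    if set(protein) - AA_ALPHABET:
        bad("protein", "non-standard amino acid letters in protein")
        return issues
    if len(cds) != 3 * (len(protein) + 1):
        bad(
            "cds",
            f"CDS length {len(cds)} inconsistent with protein length "
            f"{len(protein)} (expected {3 * (len(protein) + 1)})",
        )
        return issues
    translated = translate_cds(cds)
    if "*" in translated:
        bad("cds", "internal stop codon in CDS")
    elif translated != protein:
        bad("protein", "translation of CDS does not match protein sequence")
    return issues


# ---------------------------------------------------------------------------
# cohort reading / writing
# ---------------------------------------------------------------------------

METADATA_COLUMNS = ("gene_id", "host_genus", "family")


def read_cohort(
    fasta_cds: str | Path,
    fasta_protein: str | Path,
    metadata_tsv: str | Path,
) -> Cohort:
    """Assemble a cohort from CDS FASTA, protein FASTA and a metadata TSV.

    One record is produced per metadata row; records failing the CDS/protein
    consistency invariants are reported in ``Cohort.issues`` and excluded.
    """
    try:
        meta = pd.read_csv(metadata_tsv, sep="\t", dtype=str)
    except pd.errors.EmptyDataError:
        logger.warning("metadata file %s is empty; cohort is empty", metadata_tsv)
        return Cohort(records=[])
    missing = [c for c in METADATA_COLUMNS if c not in meta.columns]
    if missing:
        raise ConfigurationError(
            f"metadata file {metadata_tsv} lacks required column(s): {missing}"
        )
    if meta.empty:
        logger.warning("metadata file %s has no rows; cohort is empty", metadata_tsv)
        return Cohort(records=[])

    cds_by_id = {r.id: str(r.seq).upper() for r in SeqIO.parse(str(fasta_cds), "fasta")}
    prot_by_id = {
        r.id: str(r.seq).upper() for r in SeqIO.parse(str(fasta_protein), "fasta")
    }

    records: list[GeneRecord] = []
    issues: list[ValidationIssue] = []
    for row in meta.itertuples(index=False):
        gid = row.gene_id
        cds = cds_by_id.get(gid)
        prot = prot_by_id.get(gid)
        if cds is None:
            issues.append(ValidationIssue(gid, "cds", "no CDS FASTA entry"))
            continue
        if prot is None:
            issues.append(ValidationIssue(gid, "protein", "no protein FASTA entry"))
            continue
        rec = GeneRecord(
            gene_id=gid,
            cds=cds,
            protein=prot,
            host_genus=row.host_genus if isinstance(row.host_genus, str) else "",
            family=row.family if isinstance(row.family, str) else "endolysin",
            source=getattr(row, "source", "") or "",
        )
        rec_issues = validate_gene(rec)
        if rec_issues:
            issues.extend(rec_issues)
        else:
            records.append(rec)
    return Cohort(records=records, issues=issues)


def write_cohort(records: Iterable[GeneRecord], outdir: str | Path) -> dict[str, Path]:
    """Write a cohort as cds.fasta / proteins.fasta / metadata.tsv under *outdir*."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    records = list(records)
    paths = {
        "cds": outdir / "cds.fasta",
        "protein": outdir / "proteins.fasta",
        "metadata": outdir / "metadata.tsv",
    }
    SeqIO.write(
        (SeqRecord(Seq(r.cds), id=r.gene_id, description="") for r in records),
        str(paths["cds"]),
        "fasta",
    )
    SeqIO.write(
        (SeqRecord(Seq(r.protein), id=r.gene_id, description="") for r in records),
        str(paths["protein"]),
        "fasta",
    )
    pd.DataFrame(
        {
            "gene_id": [r.gene_id for r in records],
            "host_genus": [r.host_genus for r in records],
            "family": [r.family for r in records],
            "source": [r.source for r in records],
        }
    ).to_csv(paths["metadata"], sep="\t", index=False)
    return paths


# ---------------------------------------------------------------------------
# domain hits
# ---------------------------------------------------------------------------


def load_category_map(path: str | Path | None) -> dict[str, str]:
    """Load an accession->category JSON map; fall back to the built-in default."""
    if path is None:
        return dict(DEFAULT_CATEGORY_MAP)
    with open(path) as fh:
        raw = json.load(fh)
    for acc, cat in raw.items():
        if cat not in CATEGORIES:
            raise ConfigurationError(
                f"category map entry {acc!r}: unknown category {cat!r}"
            )
    return dict(raw)


def read_domains(
    domtbl_path: str | Path,
    category_map: Mapping[str, str] | None = None,
    protein_lengths: Mapping[str, int] | None = None,
) -> tuple[dict[str, list[DomainHit]], list[ValidationIssue]]:
    """Parse a whitespace-delimited domain-hit table.

    Expected columns (domtblout-style, ``#`` comments ignored)::

        gene_id  accession  name  start_aa  end_aa  evalue

    Hits are returned sorted by ``start_aa``; overlapping hits are permitted.
    Categories are assigned from *category_map* (default ``other``).  When
    *protein_lengths* is given, hits with coordinates outside the protein are
    reported as validation issues and dropped.
    """
    cmap = dict(DEFAULT_CATEGORY_MAP) if category_map is None else dict(category_map)
    hits: dict[str, list[DomainHit]] = {}
    issues: list[ValidationIssue] = []
    with open(domtbl_path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) < 6:
                issues.append(
                    ValidationIssue(f"line {lineno}", "format", "fewer than 6 columns")
                )
                continue
            gid, acc, name = parts[0], parts[1], parts[2]
            try:
                start, end = int(parts[3]), int(parts[4])
                evalue = float(parts[5])
            except ValueError:
                issues.append(
                    ValidationIssue(gid, "format", f"unparseable numbers on line {lineno}")
                )
                continue
            if start < 1 or end < start:
                issues.append(
                    ValidationIssue(
                        gid, "coords", f"invalid interval {start}-{end} (line {lineno})"
                    )
                )
                continue
            if protein_lengths is not None and gid in protein_lengths:
                if end > protein_lengths[gid]:
                    issues.append(
                        ValidationIssue(
                            gid,
                            "coords",
                            f"hit {acc} {start}-{end} exceeds protein length "
                            f"{protein_lengths[gid]}",
                        )
                    )
                    continue
            if evalue < 0:
                issues.append(
                    ValidationIssue(gid, "evalue", f"negative evalue on line {lineno}")
                )
                continue
            hits.setdefault(gid, []).append(
                DomainHit(
                    accession=acc,
                    name=name,
                    start_aa=start,
                    end_aa=end,
                    evalue=evalue,
                    category=cmap.get(acc, "other"),
                )
            )
    for gid in hits:
        hits[gid].sort(key=lambda h: (h.start_aa, h.end_aa, h.accession))
    return hits, issues


def write_domains(hits: Mapping[str, Iterable[DomainHit]], path: str | Path) -> Path:
    """Write domain hits in the format :func:`read_domains` parses."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("# gene_id accession name start_aa end_aa evalue\n")
        for gid in sorted(hits):
            for h in hits[gid]:
                fh.write(
                    f"{gid}\t{h.accession}\t{h.name}\t{h.start_aa}\t{h.end_aa}\t"
                    f"{h.evalue:.3g}\n"
                )
    return path


# ---------------------------------------------------------------------------
# TIR tables
# ---------------------------------------------------------------------------


def read_tir_table(tsv: str | Path) -> TirTable:
    """Read a TIR table TSV with columns gene_id, codon_index, tir.

    Raises on duplicate keys, non-positive TIR values and unparseable rows,
    naming the offending key or line.
    """
    table = TirTable()
    with open(tsv) as fh:
        header = fh.readline().strip().split("\t")
        required = ["gene_id", "codon_index", "tir"]
        if [c for c in required if c not in header]:
            raise ConfigurationError(
                f"TIR table {tsv} must have columns {required}, got {header}"
            )
        idx = {c: header.index(c) for c in required}
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            gid = parts[idx["gene_id"]]
            try:
                codon = int(parts[idx["codon_index"]])
                tir = float(parts[idx["tir"]])
            except (ValueError, IndexError) as exc:
                raise ValueError(f"TIR table {tsv} line {lineno}: {exc}") from exc
            if tir <= 0:
                raise ValueError(
                    f"TIR table {tsv} line {lineno}: non-positive TIR for "
                    f"({gid}, {codon})"
                )
            key = (gid, codon)
            if key in table.entries:
                raise ValueError(f"TIR table {tsv}: duplicate key {key}")
            table.entries[key] = tir
    return table


def write_tir_table(table: TirTable, path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("gene_id\tcodon_index\ttir\n")
        for (gid, codon), tir in sorted(table.entries.items()):
            fh.write(f"{gid}\t{codon}\t{tir!r}\n")
    return path
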