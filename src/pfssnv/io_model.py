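"""Domain types and tabular I/O for protein-coordinate SNV analysis.

All coordinates are 1-based, inclusive, protein space. Variants, functional
sites and the proteome are exchanged as plain text (FASTA and tab-delimited
tables with a mandatory header row; ``#``-prefixed lines are comments).

Rows that fail validation are never silently dropped: every reader that can
reject input returns a :class:`RejectionReport` alongside its records, so
``len(accepted) + len(rejected)`` always equals the number of input rows.
"""

from __future__ import annotations

import csv
from collections import defaultdict
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Mapping

from Bio import SeqIO

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
STOP = "*"
VALID_RESIDUES = frozenset(AMINO_ACIDS) | {"X"}

ORIGINS = ("somatic", "germline")
CONSEQUENCES = ("synonymous", "non-synonymous", "stop")

#: sentinel DO-slim bucket for somatic cancer terms absent from the mapping
UNMAPPED = "unmapped"

SITE_TYPES = (
    "acetylation",
    "ubiquitination",
    "phosphorylation",
    "n_glycosylation",
    "o_glycosylation",
    "methylation",
    "crotonylation",
    "nitrosylation",
    "active_site",
    "binding_site",
    "other",
)


class PfsSnvError(Exception):
    """Base class for hard errors raised by this package."""


@dataclass(frozen=True)
class ProteinRecord:
    """A single protein sequence keyed by accession."""

    accession: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.sequence:
            raise PfsSnvError(f"empty sequence for accession {self.accession}")
        bad = set(self.sequence) - VALID_RESIDUES
        if bad:
            raise PfsSnvError(
                f"invalid residues {sorted(bad)} in accession {self.accession}"
            )

    def __len__(self) -> int:
        return len(self.sequence)

    def residue(self, position: int) -> str:
        """Residue at a 1-based position."""
        if not 1 <= position <= len(self.sequence):
            raise PfsSnvError(
                f"position {position} out of range for {self.accession} "
                f"(length {len(self.sequence)})"
            )
        return self.sequence[position - 1]


class ProteinSet:
    """An accession-unique collection of :class:`ProteinRecord`."""

    def __init__(self, records: Iterable[ProteinRecord] = ()) -> None:
        self._records: dict[str, ProteinRecord] = {}
        for rec in records:
            self.add(rec)

    def add(self, record: ProteinRecord) -> None:
        if record.accession in self._records:
            raise PfsSnvError(f"duplicate accession {record.accession}")
        self._records[record.accession] = record

    def __len__(self) -> int:
        return len(self._records)

    def __contains__(self, accession: str) -> bool:
        return accession in self._records

    def __getitem__(self, accession: str) -> ProteinRecord:
        return self._records[accession]

    def __iter__(self) -> Iterator[ProteinRecord]:
        return iter(self._records.values())

    @property
    def accessions(self) -> list[str]:
        return list(self._records)

    @property
    def total_length(self) -> int:
        """Total number of residues across all proteins."""
        return sum(len(r) for r in self._records.values())

    def residue_counts(self) -> dict[str, int]:
        """Count of each residue letter over the whole proteome."""
        counts: dict[str, int] = defaultdict(int)
        for rec in self:
            for aa in rec.sequence:
                counts[aa] += 1
        return dict(counts)


@dataclass
class SNVRecord:
    """One protein-coordinate variant observation (pre-collapse).

    ``alt_aa`` equals ``ref_aa`` for synonymous records and ``*`` for
    stop-gain records. ``do_slim`` stays empty until
    :func:`map_cancer_terms` runs (and always for germline records).
    """

    accession: str
    position: int
    ref_aa: str
    alt_aa: str
    origin: str
    consequence: str
    cancer_term: str = ""
    do_slim: str = ""
    patient_id: str = ""
    source: str = ""
    gene: str = ""
    maf: float | None = None
    gain_phospho: bool = False


@dataclass
class CollapsedVariant:
    """A unique variant with its provenance aggregated across observations."""

    accession: str
    position: int
    ref_aa: str
    alt_aa: str
    consequence: str
    origin: str
    sources: set[str] = field(default_factory=set)
    patients_by_cancer: dict[str, set[str]] = field(default_factory=dict)
    gene: str = ""
    gain_phospho: bool = False

    @property
    def key(self) -> tuple[str, int, str, str, str, str]:
        return (
            self.accession,
            self.position,
            self.ref_aa,
            self.alt_aa,
            self.consequence,
            self.origin,
        )

    @property
    def cancer_type_count(self) -> int:
        """Number of distinct DO-slim terms with at least one patient."""
        return sum(1 for pats in self.patients_by_cancer.values() if pats)

    @property
    def n_patients(self) -> int:
        return sum(len(p) for p in self.patients_by_cancer.values())

    def patients_in(self, cancer: str) -> set[str]:
        return self.patients_by_cancer.get(cancer, set())


@dataclass(frozen=True)
class FunctionalSite:
    """One annotated functional residue (PTM, active or binding site)."""

    accession: str
    position: int
    site_type: str
    sources: frozenset[str] = frozenset()
    tolerated_residues: frozenset[str] = frozenset()


@dataclass(frozen=True)
class Rejection:
    row: int
    code: str
    detail: str = ""


@dataclass
class RejectionReport:
    rejections: list[Rejection] = field(default_factory=list)

    def add(self, row: int, code: str, detail: str = "") -> None:
        self.rejections.append(Rejection(row, code, detail))

    def __len__(self) -> int:
        return len(self.rejections)

    def codes(self) -> list[str]:
        return [r.code for r in self.rejections]

    def write(self, path: str | Path) -> None:
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
            writer.writerow(["row", "code", "detail"])
            for r in self.rejections:
                writer.writerow([r.row, r.code, r.detail])


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def _accession_from_header(header: str, uniprot_headers: bool) -> str:
    token = header.split()[0]
    if uniprot_headers and "|" in token:
        parts = token.split("|")
        if len(parts) >= 2 and parts[1]:
            return parts[1]
    return token


def read_proteome(path: str | Path, uniprot_headers: bool = False) -> ProteinSet:
    """Read a proteome FASTA into a :class:`ProteinSet`.

    The accession is the first whitespace-delimited header token; with
    ``uniprot_headers=True`` the second pipe-delimited field of that token
    is used instead (``sp|P04637|P53_HUMAN`` -> ``P04637``).
    """
    proteome = ProteinSet()
    for rec in SeqIO.parse(str(path), "fasta"):
        accession = _accession_from_header(rec.description, uniprot_headers)
        proteome.add(ProteinRecord(accession, str(rec.seq).upper()))
    if len(proteome) == 0:
        raise PfsSnvError(f"no FASTA records in {path}")
    return proteome


def write_proteome(proteome: ProteinSet, path: str | Path) -> None:
    with open(path, "w") as fh:
        for rec in proteome:
            fh.write(f">{rec.accession}\n")
            seq = rec.sequence
            for i in range(0, len(seq), 60):
                fh.write(seq[i : i + 60] + "\n")


# ---------------------------------------------------------------------------
# SNV table
# ---------------------------------------------------------------------------

SNV_COLUMNS = [
    "accession",
    "position",
    "ref_aa",
    "alt_aa",
    "origin",
    "consequence",
    "cancer_term",
    "do_slim",
    "patient_id",
    "source",
    "gene",
    "maf",
    "gain_phospho",
]

_REQUIRED_SNV_COLUMNS = SNV_COLUMNS[:6]


def _read_tsv_rows(path: str | Path) -> tuple[list[str], list[dict[str, str]]]:
    with open(path, newline="") as fh:
        lines = [ln for ln in fh if ln.strip() and not ln.startswith("#")]
    reader = csv.DictReader(lines, delimiter="\t")
    if reader.fieldnames is None:
        raise PfsSnvError(f"missing header row in {path}")
    return list(reader.fieldnames), list(reader)


def read_snv_table(
    path: str | Path, proteome: ProteinSet
) -> tuple[list[SNVRecord], RejectionReport]:
    """Read and validate a tab-delimited SNV table against a proteome.

    Rows failing validation land in the rejection report with a reason
    code (``BAD_POSITION``, ``UNKNOWN_ACCESSION``, ``OUT_OF_RANGE``,
    ``REF_MISMATCH``, ``BAD_ORIGIN``, ``BAD_CONSEQUENCE``,
    ``ALT_INCONSISTENT``); accepted + rejected = input rows.
    """
    header, rows = _read_tsv_rows(path)
    missing = [c for c in _REQUIRED_SNV_COLUMNS if c not in header]
    if missing:
        raise PfsSnvError(f"SNV table missing columns: {missing}")

    records: list[SNVRecord] = []
    report = RejectionReport()
    for idx, row in enumerate(rows, start=1):
        accession = row["accession"].strip()
        try:
            position = int(row["position"])
            if position < 1:
                raise ValueError
        except (ValueError, TypeError):
            report.add(idx, "BAD_POSITION", repr(row.get("position")))
            continue
        if accession not in proteome:
            report.add(idx, "UNKNOWN_ACCESSION", accession)
            continue
        protein = proteome[accession]
        if position > len(protein):
            report.add(idx, "OUT_OF_RANGE", f"{accession}:{position}")
            continue
        ref_aa = row["ref_aa"].strip().upper()
        alt_aa = row["alt_aa"].strip().upper()
        if protein.residue(position) != ref_aa:
            report.add(
                idx,
                "REF_MISMATCH",
                f"{accession}:{position} expected "
                f"{protein.residue(position)}, got {ref_aa}",
            )
            continue
        origin = row["origin"].strip().lower()
        if origin not in ORIGINS:
            report.add(idx, "BAD_ORIGIN", origin)
            continue
        consequence = row["consequence"].strip().lower()
        if consequence not in CONSEQUENCES:
            report.add(idx, "BAD_CONSEQUENCE", consequence)
            continue
        if consequence == "synonymous" and ref_aa != alt_aa:
            report.add(idx, "ALT_INCONSISTENT", f"synonymous {ref_aa}!={alt_aa}")
            continue
        if consequence == "non-synonymous" and (
            ref_aa == alt_aa or alt_aa not in VALID_RESIDUES
        ):
            report.add(idx, "ALT_INCONSISTENT", f"non-synonymous {ref_aa}>{alt_aa}")
            continue
        if consequence == "stop" and alt_aa != STOP:
            report.add(idx, "ALT_INCONSISTENT", f"stop alt {alt_aa!r}")
            continue
        maf_raw = (row.get("maf") or "").strip()
        maf = float(maf_raw) if maf_raw else None
        records.append(
            SNVRecord(
                accession=accession,
                position=position,
                ref_aa=ref_aa,
                alt_aa=alt_aa,
                origin=origin,
                consequence=consequence,
                cancer_term=(row.get("cancer_term") or "").strip(),
                do_slim=(row.get("do_slim") or "").strip(),
                patient_id=(row.get("patient_id") or "").strip(),
                source=(row.get("source") or "").strip(),
                gene=(row.get("gene") or "").strip(),
                maf=maf,
                gain_phospho=(row.get("gain_phospho") or "").strip().lower()
                in ("1", "true", "yes"),
            )
        )
    return records, report


def write_snv_table(records: Iterable[SNVRecord], path: str | Path) -> None:
    """Write SNV records back to TSV (round-trips with :func:`read_snv_table`)."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(SNV_COLUMNS)
        for r in records:
            writer.writerow(
                [
                    r.accession,
                    r.position,
                    r.ref_aa,
                    r.alt_aa,
                    r.origin,
                    r.consequence,
                    r.cancer_term,
                    r.do_slim,
                    r.patient_id,
                    r.source,
                    r.gene,
                    "" if r.maf is None else repr(r.maf),
                    "1" if r.gain_phospho else "",
                ]
            )


# ---------------------------------------------------------------------------
# DO-slim cancer-term mapping
# ---------------------------------------------------------------------------

def read_do_slim_mapping(path: str | Path) -> dict[str, str]:
    """Read a two-column (raw term, DO-slim term) mapping table.

    A raw term mapped to two different slims is a hard error.
    """
    header, rows = _read_tsv_rows(path)
    if len(header) < 2:
        raise PfsSnvError("DO-slim mapping needs two columns (raw, slim)")
    raw_col, slim_col = header[0], header[1]
    mapping: dict[str, str] = {}
    for row in rows:
        raw = row[raw_col].strip()
        slim = row[slim_col].strip()
        if raw in mapping and mapping[raw] != slim:
            raise PfsSnvError(
                f"raw term {raw!r} mapped to both {mapping[raw]!r} and {slim!r}"
            )
        mapping[raw] = slim
    return mapping


def map_cancer_terms(
    records: list[SNVRecord], mapping: Mapping[str, str]
) -> tuple[list[SNVRecord], list[str]]:
    """Fill ``do_slim`` on somatic records from a raw-term mapping.

    Terms absent from the mapping go to the :data:`UNMAPPED` bucket and are
    returned (deduplicated, sorted) as the unmapped-term report. Germline
    records keep ``do_slim`` empty.
    """
    out: list[SNVRecord] = []
    unmapped: set[str] = set()
    for rec in records:
        if rec.origin != "somatic":
            out.append(replace(rec, do_slim=""))
            continue
        slim = mapping.get(rec.cancer_term)
        if slim is None:
            unmapped.add(rec.cancer_term)
            slim = UNMAPPED
        out.append(replace(rec, do_slim=slim))
    return out, sorted(unmapped)


# ---------------------------------------------------------------------------
# Variant collapsing
# ---------------------------------------------------------------------------

def collapse_variants(records: Iterable[SNVRecord]) -> list[CollapsedVariant]:
    """Collapse per-observation records into unique variants.

    Grouping key is (accession, position, ref_aa, alt_aa, consequence,
    origin); sources are unioned and patients accumulated per DO-slim term
    so per-variant patient frequency stays recoverable.
    """
    grouped: dict[tuple, CollapsedVariant] = {}
    for rec in records:
        key = (
            rec.accession,
            rec.position,
            rec.ref_aa,
            rec.alt_aa,
            rec.consequence,
            rec.origin,
        )
        cv = grouped.get(key)
        if cv is None:
            cv = CollapsedVariant(*key)
            grouped[key] = cv
        if rec.source:
            cv.sources.add(rec.source)
        if rec.gene and not cv.gene:
            cv.gene = rec.gene
        cv.gain_phospho = cv.gain_phospho or rec.gain_phospho
        if rec.origin == "somatic" and rec.do_slim:
            patients = cv.patients_by_cancer.setdefault(rec.do_slim, set())
            if rec.patient_id:
                patients.add(rec.patient_id)
    return sorted(grouped.values(), key=lambda cv: cv.key)


def expand_variants(variants: Iterable[CollapsedVariant]) -> list[SNVRecord]:
    """Inverse-ish of :func:`collapse_variants` (one record per patient)."""
    records: list[SNVRecord] = []
    for cv in variants:
        emitted = False
        for cancer in sorted(cv.patients_by_cancer):
            for patient in sorted(cv.patients_by_cancer[cancer]):
                records.append(
                    SNVRecord(
                        accession=cv.accession,
                        position=cv.position,
                        ref_aa=cv.ref_aa,
                        alt_aa=cv.alt_aa,
                        origin=cv.origin,
                        consequence=cv.consequence,
                        cancer_term=cancer,
                        do_slim=cancer,
                        patient_id=patient,
                        source=";".join(sorted(cv.sources)),
                        gene=cv.gene,
                        gain_phospho=cv.gain_phospho,
                    )
                )
                emitted = True
        if not emitted:
            records.append(
                SNVRecord(
                    accession=cv.accession,
                    position=cv.position,
                    ref_aa=cv.ref_aa,
                    alt_aa=cv.alt_aa,
                    origin=cv.origin,
                    consequence=cv.consequence,
                    source=";".join(sorted(cv.sources)),
                    gene=cv.gene,
                    gain_phospho=cv.gain_phospho,
                )
            )
    return records


# ---------------------------------------------------------------------------
# Functional-site table
# ---------------------------------------------------------------------------

SITE_COLUMNS = ["accession", "position", "site_type", "source", "tolerated_residues"]


def read_site_table(
    path: str | Path,
    proteome: ProteinSet,
    default_tolerance=None,
) -> tuple[list[FunctionalSite], RejectionReport]:
    """Read a functional-site TSV, validate against the proteome, dedupe.

    Duplicate (accession, position, site_type) rows are collapsed with
    sources unioned. ``tolerated_residues`` may be given as a comma list;
    when empty it is filled from ``default_tolerance`` (a
    :class:`~pfssnv.site_effects.ToleranceTable`) or falls back to the
    reference residue alone.
    """
    header, rows = _read_tsv_rows(path)
    missing = [c for c in SITE_COLUMNS[:3] if c not in header]
    if missing:
        raise PfsSnvError(f"site table missing columns: {missing}")

    report = RejectionReport()
    merged: dict[tuple[str, int, str], dict] = {}
    for idx, row in enumerate(rows, start=1):
        accession = row["accession"].strip()
        try:
            position = int(row["position"])
            if position < 1:
                raise ValueError
        except (ValueError, TypeError):
            report.add(idx, "BAD_POSITION", repr(row.get("position")))
            continue
        if accession not in proteome:
            report.add(idx, "UNKNOWN_ACCESSION", accession)
            continue
        protein = proteome[accession]
        if position > len(protein):
            report.add(idx, "OUT_OF_RANGE", f"{accession}:{position}")
            continue
        site_type = row["site_type"].strip().lower()
        if site_type not in SITE_TYPES:
            report.add(idx, "UNKNOWN_SITE_TYPE", site_type)
            continue
        ref = protein.residue(position)
        tol_raw = (row.get("tolerated_residues") or "").strip()
        if tol_raw:
            tolerance = frozenset(t.strip().upper() for t in tol_raw.split(","))
        elif default_tolerance is not None:
            tolerance = default_tolerance.tolerated(site_type, ref)
        else:
            tolerance = frozenset({ref})
        if ref not in tolerance:
            report.add(
                idx, "REF_NOT_TOLERATED", f"{accession}:{position} {ref} not in set"
            )
            continue
        key = (accession, position, site_type)
        entry = merged.setdefault(key, {"sources": set(), "tolerance": tolerance})
        src = (row.get("source") or "").strip()
        if src:
            entry["sources"].add(src)
    sites = [
        FunctionalSite(
            accession=acc,
            position=pos,
            site_type=stype,
            sources=frozenset(entry["sources"]),
            tolerated_residues=entry["tolerance"],
        )
        for (acc, pos, stype), entry in sorted(merged.items())
    ]
    return sites, report


def write_site_table(sites: Iterable[FunctionalSite], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(SITE_COLUMNS)
        for s in sites:
            writer.writerow(
                [
                    s.accession,
                    s.position,
                    s.site_type,
                    ";".join(sorted(s.sources)),
                    ",".join(sorted(s.tolerated_residues)),
                ]
            )


def read_gene_list(path: str | Path) -> set[str]:
    """One gene symbol per line; blank lines and ``#`` comments skipped."""
    genes: set[str] = set()
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line and not line.startswith("#"):
                genes.add(line)
    return genes
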