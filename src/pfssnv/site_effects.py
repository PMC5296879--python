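"""Variant-to-site joins, loss/retained/gain effect calls, sequon logic.

The effect of a substitution at a functional site is a pure function of the
site type, the reference/alternate residues and (for N-glycosylation) the
local tripeptide: the alternate residue either still supports the function
(``retained``) or does not (``loss``). Variants landing within +/- window
residues of a site but not on a function-bearing position are ``neighbor``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

from .io_model import (
    AMINO_ACIDS,
    CollapsedVariant,
    FunctionalSite,
    PfsSnvError,
    ProteinSet,
)

WINDOW = 20

EFFECT_LOSS = "loss"
EFFECT_RETAINED = "retained"
EFFECT_GAIN = "gain"
EFFECT_NEIGHBOR = "neighbor"

SEQUON_NONE = "none"
SEQUON_N0 = "N0"
SEQUON_X1 = "X1"
SEQUON_ST2 = "ST2"

#: residues that can carry each function; methylation is resolved per
#: reference residue (K-type vs R-type) in :meth:`ToleranceTable.tolerated`.
DEFAULT_TOLERANCE: dict[str, frozenset[str]] = {
    "phosphorylation": frozenset("STY"),
    "acetylation": frozenset("K"),
    "ubiquitination": frozenset("K"),
    "crotonylation": frozenset("K"),
    "methylation": frozenset("KR"),
    "nitrosylation": frozenset("C"),
    "n_glycosylation": frozenset("N"),
    "o_glycosylation": frozenset("ST"),
}


class ToleranceTable:
    """Per-site-type tolerated residue sets, overridable by the user."""

    def __init__(self, overrides: Mapping[str, Iterable[str]] | None = None):
        self._table: dict[str, frozenset[str]] = dict(DEFAULT_TOLERANCE)
        for site_type, residues in (overrides or {}).items():
            residues = frozenset(str(r).upper() for r in residues)
            if not residues:
                raise PfsSnvError(f"empty tolerance set for {site_type}")
            self._table[site_type] = residues

    def tolerated(self, site_type: str, ref_aa: str) -> frozenset[str]:
        """The tolerance set for a site of this type on residue ``ref_aa``.

        Active/binding sites (and any type without an entry in the table)
        tolerate only the reference residue. Methylation splits into K- and
        R-type by the reference residue.
        """
        if site_type in ("active_site", "binding_site", "other"):
            return frozenset({ref_aa})
        entry = self._table.get(site_type)
        if entry is None:
            raise PfsSnvError(f"no tolerance entry for site type {site_type!r}")
        if site_type == "methylation" and entry == DEFAULT_TOLERANCE["methylation"]:
            if ref_aa in "KR":
                return frozenset({ref_aa})
        return entry

    @classmethod
    def from_file(cls, path: str | Path) -> "ToleranceTable":
        """Two-column text file: site_type <tab> comma-separated residues."""
        overrides: dict[str, set[str]] = {}
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                parts = line.split("\t")
                if len(parts) != 2:
                    raise PfsSnvError(f"bad tolerance line: {line!r}")
                overrides[parts[0].strip().lower()] = {
                    r.strip().upper() for r in parts[1].split(",")
                }
        return cls(overrides)


def classify_site_effect(
    ref_aa: str,
    alt_aa: str,
    consequence: str,
    site: FunctionalSite,
    tolerance: ToleranceTable,
) -> str:
    """Loss/retained call for a variant sitting exactly on a site residue.

    Synonymous variants always come back ``retained`` (they count toward
    occurrence but can never abolish the function). Curated per-site
    tolerance, when present, wins over the type-level default.
    """
    if consequence == "synonymous":
        return EFFECT_RETAINED
    if site.tolerated_residues:
        tolerated = site.tolerated_residues
    else:
        tolerated = tolerance.tolerated(site.site_type, ref_aa)
    return EFFECT_RETAINED if alt_aa in tolerated else EFFECT_LOSS


def is_sequon(triplet: str) -> bool:
    """N-X-S/T with X != P (the N-glycosylation acceptor motif)."""
    return (
        len(triplet) == 3
        and triplet[0] == "N"
        and triplet[1] != "P"
        and triplet[2] in "ST"
    )


def sequon_role(offset: int) -> str:
    return {0: SEQUON_N0, 1: SEQUON_X1, 2: SEQUON_ST2}.get(offset, SEQUON_NONE)


def classify_sequon_effect(
    sequence: str,
    site_position: int,
    variant_position: int,
    alt_aa: str,
    consequence: str,
) -> tuple[str, str]:
    """Effect of a substitution at any of the three sequon positions.

    ``site_position`` is the N (1-based); the variant must lie at offsets
    0, 1 or 2. Returns (effect, sequon_role). A site whose triplet runs off
    the end of the sequence is malformed.
    """
    offset = variant_position - site_position
    role = sequon_role(offset)
    if role == SEQUON_NONE:
        raise PfsSnvError(f"variant offset {offset} outside the sequon")
    if site_position + 2 > len(sequence):
        raise PfsSnvError(
            f"sequon at position {site_position} runs past sequence end"
        )
    if consequence == "synonymous":
        return EFFECT_RETAINED, role
    triplet = list(sequence[site_position - 1 : site_position + 2])
    triplet[offset] = alt_aa
    effect = EFFECT_RETAINED if is_sequon("".join(triplet)) else EFFECT_LOSS
    return effect, role


def scan_sequons(sequence: str) -> set[int]:
    """1-based positions of every N starting an N-X(!=P)-[S/T] triplet."""
    return {
        i + 1
        for i in range(len(sequence) - 2)
        if is_sequon(sequence[i : i + 3])
    }


def detect_gain_nglyc(
    sequence: str, position: int, alt_aa: str
) -> list[int]:
    """Sequon positions created (not present in the reference) by a substitution.

    Scans reference and mutated sequence and returns the gained N
    positions; only triplets overlapping the variant can differ.
    """
    if not 1 <= position <= len(sequence):
        raise PfsSnvError(f"position {position} outside sequence")
    mutated = sequence[: position - 1] + alt_aa + sequence[position:]
    return sorted(scan_sequons(mutated) - scan_sequons(sequence))


# ---------------------------------------------------------------------------
# Neighborhood annotation
# ---------------------------------------------------------------------------

ANNOTATION_COLUMNS = [
    "accession",
    "site_position",
    "site_type",
    "variant_position",
    "offset",
    "ref_aa",
    "alt_aa",
    "origin",
    "consequence",
    "effect",
    "sequon_role",
    "n_patients",
    "cancer_type_count",
    "variant_index",
]


@dataclass(frozen=True)
class PfsSNVAnnotation:
    """One (variant, site) pair within the window, with its effect call."""

    accession: str
    site_position: int
    site_type: str
    variant_position: int
    offset: int
    effect: str
    sequon_role: str = SEQUON_NONE


def annotate_neighborhood(
    variants: list[CollapsedVariant],
    sites: list[FunctionalSite],
    proteome: ProteinSet,
    tolerance: ToleranceTable | None = None,
    window: int = WINDOW,
    include_stop: bool = False,
) -> pd.DataFrame:
    """Join every variant to every same-protein site within ``window``.

    Emits one row per (site, variant) pair with |variant - site| <= window,
    carrying the signed offset (variant minus site) and the effect call:
    loss/retained at offset 0 (or at sequon positions +1/+2 of an
    N-glycosylation site), ``neighbor`` elsewhere. Stop-gain variants are
    excluded unless ``include_stop``.
    """
    tolerance = tolerance or ToleranceTable()
    by_acc: dict[str, list[tuple[int, int]]] = {}
    for idx, v in enumerate(variants):
        if v.consequence == "stop" and not include_stop:
            continue
        by_acc.setdefault(v.accession, []).append((v.position, idx))
    for acc in by_acc:
        by_acc[acc].sort()

    rows: list[tuple] = []
    malformed: list[FunctionalSite] = []
    for site in sites:
        candidates = by_acc.get(site.accession)
        if not candidates:
            continue
        sequence = proteome[site.accession].sequence
        if site.site_type == "n_glycosylation" and site.position + 2 > len(sequence):
            malformed.append(site)
            continue
        lo, hi = site.position - window, site.position + window
        for pos, idx in candidates:
            if pos < lo:
                continue
            if pos > hi:
                break
            v = variants[idx]
            offset = pos - site.position
            role = SEQUON_NONE
            if site.site_type == "n_glycosylation" and offset in (0, 1, 2):
                effect, role = classify_sequon_effect(
                    sequence, site.position, pos, v.alt_aa, v.consequence
                )
            elif offset == 0:
                effect = classify_site_effect(
                    v.ref_aa, v.alt_aa, v.consequence, site, tolerance
                )
            else:
                effect = EFFECT_NEIGHBOR
            rows.append(
                (
                    site.accession,
                    site.position,
                    site.site_type,
                    pos,
                    offset,
                    v.ref_aa,
                    v.alt_aa,
                    v.origin,
                    v.consequence,
                    effect,
                    role,
                    v.n_patients,
                    v.cancer_type_count,
                    idx,
                )
            )
    df = pd.DataFrame(rows, columns=ANNOTATION_COLUMNS)
    df.attrs["malformed_sites"] = malformed
    return df


def site_offset_denominators(
    sites: list[FunctionalSite],
    proteome: ProteinSet,
    window: int = WINDOW,
) -> dict[str, dict[int, int]]:
    """Valid-residue count per (site type, offset) over all site instances.

    Offset positions falling outside the protein do not exist and are not
    counted; a given offset's denominator is therefore <= number of sites.
    """
    denom: dict[str, dict[int, int]] = {}
    for site in sites:
        length = len(proteome[site.accession])
        per_type = denom.setdefault(site.site_type, {})
        lo = max(1, site.position - window)
        hi = min(length, site.position + window)
        for pos in range(lo, hi + 1):
            off = pos - site.position
            per_type[off] = per_type.get(off, 0) + 1
    return denom


def write_annotations(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)
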