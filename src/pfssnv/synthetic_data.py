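"""Seedable generator of proteomes, site tables and SNV/patient tables.

Every pipeline stage gets a no-download test surface: residues are drawn
i.i.d. from a configurable frequency table, sites land on eligible residues
at configurable per-type rates (N-glycosylation only on existing sequons),
and variants are emitted per residue and mutation class at
``class_rate x offset multiplier``, where the multiplier keys on the signed
offset to the nearest site of each type and composes multiplicatively
across types (1.0 everywhere = null). Somatic variants acquire carriers
per cancer cohort; planted variants force carriage at a chosen rate.

Everything is deterministic under the seed: each stage derives its own
``default_rng`` stream from (stage id, seed).
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import yaml

from .io_model import (
    AMINO_ACIDS,
    FunctionalSite,
    PfsSnvError,
    ProteinRecord,
    ProteinSet,
    SNVRecord,
    write_proteome,
    write_site_table,
    write_snv_table,
)
from .occurrence_stats import MutationClass
from .site_effects import DEFAULT_TOLERANCE, ToleranceTable, WINDOW, scan_sequons

MIN_PROTEIN_LENGTH = 45  # must fit a +/-20 window plus a sequon

_STAGE_PROTEOME = 11
_STAGE_SITES = 22
_STAGE_SNVS = 33

#: residues eligible to host each site type
ELIGIBLE_RESIDUES: dict[str, frozenset[str]] = {
    **DEFAULT_TOLERANCE,
    "active_site": frozenset(AMINO_ACIDS),
    "binding_site": frozenset(AMINO_ACIDS),
    "other": frozenset(AMINO_ACIDS),
}


@dataclass
class CancerCohort:
    term: str
    n_patients: int
    rate: float  # per-patient carriage probability of each somatic variant


@dataclass
class PlantedVariant:
    accession: str
    position: int
    alt_aa: str
    cancer: str
    carriage: float


@dataclass
class SimulationConfig:
    seed: int = 0
    n_proteins: int = 20
    length_mean: float = 120.0
    length_sd: float = 20.0
    length_min: int = MIN_PROTEIN_LENGTH
    aa_freqs: dict[str, float] | None = None
    site_type_rates: dict[str, float] = field(
        default_factory=lambda: {"phosphorylation": 0.2, "binding_site": 0.02}
    )
    offset_effects: dict[str, dict[int, float]] = field(default_factory=dict)
    class_rates: dict[str, float] = field(
        default_factory=lambda: {
            "non_SG": 0.02,
            "SG": 0.01,
            "non_SS": 0.02,
            "SS": 0.01,
        }
    )
    cancers: list[CancerCohort] = field(default_factory=list)
    planted_variants: list[PlantedVariant] = field(default_factory=list)
    smg_genes: list[str] = field(default_factory=list)
    cgc_genes: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        for rates in (self.site_type_rates, self.class_rates):
            for key, r in rates.items():
                if not 0.0 <= r <= 1.0:
                    raise PfsSnvError(f"rate {key}={r} outside [0, 1]")
        for effects in self.offset_effects.values():
            for off, mult in effects.items():
                if mult < 0:
                    raise PfsSnvError(f"negative multiplier at offset {off}")

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimulationConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        raw["cancers"] = [CancerCohort(**c) for c in raw.get("cancers", [])]
        raw["planted_variants"] = [
            PlantedVariant(**p) for p in raw.get("planted_variants", [])
        ]
        # yaml round-trips offset keys as ints already; coerce defensively
        raw["offset_effects"] = {
            st: {int(k): float(v) for k, v in eff.items()}
            for st, eff in (raw.get("offset_effects") or {}).items()
        }
        return cls(**raw)


def _rng(stage: int, seed: int) -> np.random.Generator:
    return np.random.default_rng([stage, seed])


def _aa_probabilities(config: SimulationConfig) -> np.ndarray:
    if config.aa_freqs is None:
        return np.full(len(AMINO_ACIDS), 1.0 / len(AMINO_ACIDS))
    probs = np.array([config.aa_freqs.get(aa, 0.0) for aa in AMINO_ACIDS], float)
    total = probs.sum()
    if total <= 0:
        raise PfsSnvError("amino-acid frequency table sums to zero")
    return probs / total


def generate_proteome(config: SimulationConfig, seed: int | None = None) -> ProteinSet:
    """Draw ``n_proteins`` i.i.d.-residue proteins (FASTA-writable)."""
    if config.n_proteins < 1:
        raise PfsSnvError("n_proteins must be >= 1")
    if config.length_min < MIN_PROTEIN_LENGTH:
        raise PfsSnvError(
            f"length_min must be >= {MIN_PROTEIN_LENGTH} to fit a window and sequon"
        )
    rng = _rng(_STAGE_PROTEOME, config.seed if seed is None else seed)
    probs = _aa_probabilities(config)
    letters = np.array(list(AMINO_ACIDS))
    proteome = ProteinSet()
    for i in range(config.n_proteins):
        length = max(
            config.length_min,
            int(round(rng.normal(config.length_mean, config.length_sd))),
        )
        seq = "".join(rng.choice(letters, size=length, p=probs))
        proteome.add(ProteinRecord(f"SP{i:05d}", seq))
    return proteome


def generate_sites(
    proteome: ProteinSet,
    config: SimulationConfig,
    seed: int | None = None,
) -> tuple[list[FunctionalSite], list[str]]:
    """Bernoulli site placement on eligible residues.

    Returns (sites, report of types skipped for lack of eligible residues).
    N-glycosylation sites appear only where the N-X(!=P)-[S/T] sequon
    already holds; tolerated residues come from the default tolerance.
    """
    rng = _rng(_STAGE_SITES, config.seed if seed is None else seed)
    tolerance = ToleranceTable()
    sites: list[FunctionalSite] = []
    eligible_seen: dict[str, int] = {st: 0 for st in config.site_type_rates}
    for rec in proteome:
        seq = rec.sequence
        for site_type, rate in sorted(config.site_type_rates.items()):
            if site_type == "n_glycosylation":
                positions = sorted(
                    p for p in scan_sequons(seq) if p + 2 <= len(seq)
                )
            else:
                eligible = ELIGIBLE_RESIDUES[site_type]
                positions = [i + 1 for i, aa in enumerate(seq) if aa in eligible]
            eligible_seen[site_type] += len(positions)
            if not positions or rate == 0.0:
                continue
            keep = rng.random(len(positions)) < rate
            for pos, k in zip(positions, keep):
                if not k:
                    continue
                sites.append(
                    FunctionalSite(
                        accession=rec.accession,
                        position=pos,
                        site_type=site_type,
                        sources=frozenset({"sim"}),
                        tolerated_residues=tolerance.tolerated(
                            site_type, seq[pos - 1]
                        ),
                    )
                )
    skipped = [st for st, n in eligible_seen.items() if n == 0]
    return sites, skipped


def _nearest_site_multipliers(
    length: int,
    site_positions: Sequence[int],
    effects: Mapping[int, float],
    window: int = WINDOW,
) -> np.ndarray:
    """Per-residue multiplier from the signed offset to the nearest site."""
    mult = np.ones(length)
    if not site_positions:
        return mult
    pos_arr = np.asarray(site_positions)
    residues = np.arange(1, length + 1)
    idx = np.searchsorted(pos_arr, residues)
    left = np.clip(idx - 1, 0, len(pos_arr) - 1)
    right = np.clip(idx, 0, len(pos_arr) - 1)
    d_left = np.abs(residues - pos_arr[left])
    d_right = np.abs(residues - pos_arr[right])
    nearest = np.where(d_right < d_left, pos_arr[right], pos_arr[left])
    offsets = residues - nearest
    for off, m in effects.items():
        mult[offsets == off] = m
    mult[np.abs(offsets) > window] = 1.0
    return mult


def generate_snvs(
    proteome: ProteinSet,
    sites: Sequence[FunctionalSite],
    config: SimulationConfig,
    seed: int | None = None,
) -> list[SNVRecord]:
    """Emit SNV table rows with patient/cancer structure.

    Per residue and mutation class a variant appears with probability
    ``class_rate x`` the product of per-site-type multipliers. Somatic
    variants draw carriers per cohort as Binomial(N_C, cohort rate); a
    somatic variant with no carrier in any cohort is not emitted (at the
    configured rates this conditioning is negligible). Germline variants
    are single rows without patients. Planted variants are added last and
    force carriage at their configured probability.
    """
    rng = _rng(_STAGE_SNVS, config.seed if seed is None else seed)
    letters = np.array(list(AMINO_ACIDS))
    aa_index = {aa: i for i, aa in enumerate(AMINO_ACIDS)}

    sites_by_acc_type: dict[str, dict[str, list[int]]] = {}
    for s in sites:
        sites_by_acc_type.setdefault(s.accession, {}).setdefault(
            s.site_type, []
        ).append(s.position)
    for per_type in sites_by_acc_type.values():
        for positions in per_type.values():
            positions.sort()

    patient_pools = {
        c.term: [f"{c.term}:P{i:04d}" for i in range(c.n_patients)]
        for c in config.cancers
    }

    records: list[SNVRecord] = []

    def assign_patients(rec_template: SNVRecord) -> bool:
        emitted = False
        for cohort in config.cancers:
            k = rng.binomial(cohort.n_patients, cohort.rate)
            if k == 0:
                continue
            chosen = rng.choice(cohort.n_patients, size=k, replace=False)
            for pidx in sorted(chosen):
                records.append(
                    SNVRecord(
                        accession=rec_template.accession,
                        position=rec_template.position,
                        ref_aa=rec_template.ref_aa,
                        alt_aa=rec_template.alt_aa,
                        origin="somatic",
                        consequence=rec_template.consequence,
                        cancer_term=cohort.term,
                        patient_id=patient_pools[cohort.term][pidx],
                        source="sim",
                        gene=rec_template.gene,
                    )
                )
                emitted = True
        return emitted

    for prot_idx, rec in enumerate(proteome):
        seq = rec.sequence
        length = len(seq)
        gene = f"GENE{prot_idx:05d}"
        per_type = sites_by_acc_type.get(rec.accession, {})

        composed = np.ones(length)
        for site_type, effects in config.offset_effects.items():
            composed *= _nearest_site_multipliers(
                length, per_type.get(site_type, []), effects
            )

        seq_idx = np.array([aa_index[a] for a in seq])
        for class_name, base_rate in sorted(config.class_rates.items()):
            mc = MutationClass(class_name)
            rates = base_rate * composed
            if np.any(rates > 1.0):
                raise PfsSnvError(
                    "composed per-residue rate exceeds 1; configuration "
                    "is inconsistent"
                )
            hits = np.flatnonzero(rng.random(length) < rates)
            for pos0 in hits:
                ref = seq[pos0]
                if mc.consequence == "synonymous":
                    alt = ref
                else:
                    others = np.delete(np.arange(20), seq_idx[pos0])
                    alt = letters[rng.choice(others)]
                template = SNVRecord(
                    accession=rec.accession,
                    position=int(pos0) + 1,
                    ref_aa=ref,
                    alt_aa=alt,
                    origin=mc.origin,
                    consequence=mc.consequence,
                    gene=gene,
                )
                if mc.origin == "germline":
                    template.source = "sim_dbsnp"
                    records.append(template)
                else:
                    assign_patients(template)

    gene_by_acc = {
        rec.accession: f"GENE{i:05d}" for i, rec in enumerate(proteome)
    }
    for planted in config.planted_variants:
        if planted.accession not in proteome:
            raise PfsSnvError(f"planted variant on unknown {planted.accession}")
        protein = proteome[planted.accession]
        ref = protein.residue(planted.position)
        if planted.alt_aa == ref:
            raise PfsSnvError("planted variant must be non-synonymous")
        pool = patient_pools.get(planted.cancer)
        if pool is None:
            raise PfsSnvError(f"planted variant in unknown cancer {planted.cancer}")
        k = rng.binomial(len(pool), planted.carriage)
        chosen = rng.choice(len(pool), size=k, replace=False) if k else []
        for pidx in sorted(chosen):
            records.append(
                SNVRecord(
                    accession=planted.accession,
                    position=planted.position,
                    ref_aa=ref,
                    alt_aa=planted.alt_aa,
                    origin="somatic",
                    consequence="non-synonymous",
                    cancer_term=planted.cancer,
                    patient_id=pool[pidx],
                    source="sim_planted",
                    gene=gene_by_acc[planted.accession],
                )
            )
    return records


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def write_fixture_bundle(config: SimulationConfig, out_dir: str | Path) -> dict[str, str]:
    """Write the full fixture set and a digest manifest; returns the digests.

    Files: proteome.fasta, sites.tsv, snvs.tsv, do_slim_map.tsv (identity
    over the configured cohorts), genes_smg.txt, genes_cgc.txt, config.yaml
    and manifest.tsv.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    proteome = generate_proteome(config)
    sites, _ = generate_sites(proteome, config)
    snvs = generate_snvs(proteome, sites, config)

    write_proteome(proteome, out / "proteome.fasta")
    write_site_table(sites, out / "sites.tsv")
    write_snv_table(snvs, out / "snvs.tsv")
    with open(out / "do_slim_map.tsv", "w") as fh:
        fh.write("raw_term\tdo_slim\n")
        for cohort in config.cancers:
            fh.write(f"{cohort.term}\t{cohort.term}\n")
    for name, genes in (
        ("genes_smg.txt", config.smg_genes),
        ("genes_cgc.txt", config.cgc_genes),
    ):
        with open(out / name, "w") as fh:
            for g in genes:
                fh.write(g + "\n")
    config.to_yaml(out / "config.yaml")

    names = [
        "proteome.fasta",
        "sites.tsv",
        "snvs.tsv",
        "do_slim_map.tsv",
        "genes_smg.txt",
        "genes_cgc.txt",
        "config.yaml",
    ]
    digests = {name: _sha256(out / name) for name in names}
    with open(out / "manifest.tsv", "w") as fh:
        fh.write("file\tsha256\n")
        for name in names:
            fh.write(f"{name}\t{digests[name]}\n")
    return digests
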