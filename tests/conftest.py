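import pytest

from pfssnv.io_model import (
    CollapsedVariant,
    FunctionalSite,
    ProteinRecord,
    ProteinSet,
    SNVRecord,
)
from pfssnv.site_effects import ToleranceTable


@pytest.fixture
def tolerance():
    return ToleranceTable()


@pytest.fixture
def toy_proteome():
    """Two small proteins with a phosphosite-rich and a sequon context."""
    return ProteinSet(
        [
            ProteinRecord("P1", "MSTKAYANGSACDEFGHIKLMNPQRSTVWYACDEFGHIKLMNPQR"),
            ProteinRecord("P2", "MKKSSTTYYCANGSA" + "A" * 45),
        ]
    )


def make_variant(
    accession="P1",
    position=2,
    ref_aa="S",
    alt_aa="A",
    consequence="non-synonymous",
    origin="somatic",
    cancers=None,
    gene="",
    gain_phospho=False,
):
    cv = CollapsedVariant(
        accession=accession,
        position=position,
        ref_aa=ref_aa,
        alt_aa=alt_aa,
        consequence=consequence,
        origin=origin,
        sources={"test"},
        gene=gene,
        gain_phospho=gain_phospho,
    )
    for cancer, patients in (cancers or {}).items():
        cv.patients_by_cancer[cancer] = set(patients)
    return cv


def make_site(accession="P1", position=2, site_type="phosphorylation", tolerated=None):
    tol = (
        frozenset(tolerated)
        if tolerated is not None
        else ToleranceTable().tolerated(site_type, "S" if site_type == "phosphorylation" else "K")
    )
    return FunctionalSite(
        accession=accession,
        position=position,
        site_type=site_type,
        sources=frozenset({"test"}),
        tolerated_residues=tol,
    )


@pytest.fixture
def variant_factory():
    return make_variant


@pytest.fixture
def site_factory():
    return make_site
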