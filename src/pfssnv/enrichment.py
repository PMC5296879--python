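"""Binomial enrichment statistics with amino-acid and patient backgrounds.

Two constructions share one exact tail primitive:

* amino-acid background — for residue type A and site type F, the chance
  that a variant with reference A lands on an F site is p_A(F) =
  n_A(F) / L_A; observed on-site counts are tested against
  Binomial(N_A, p_A(F));
* patient level — for variant M in cancer C with N_C patients, the carrier
  count is tested against Binomial(N_C, p_C) where p_C is the expected
  per-patient carriage probability of any functional-site variant in C.

The tail is the directional one: upper when observed exceeds expectation,
lower when below, min of both (capped at 1) at exact equality. Sums are
exact, computed in log space.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.special import gammaln, logsumexp

from .io_model import (
    AMINO_ACIDS,
    CollapsedVariant,
    FunctionalSite,
    PfsSnvError,
    ProteinSet,
)
from .occurrence_stats import MutationClass

DIRECTION_ENRICHED = "enriched"
DIRECTION_DEPLETED = "depleted"


def _log_binom_pmf(k: np.ndarray, n: int, p: float) -> np.ndarray:
    log_choose = gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)
    with np.errstate(divide="ignore"):
        return log_choose + k * np.log(p) + (n - k) * np.log1p(-p)


def binomial_tail(observed: int, n: int, p: float) -> float:
    """Exact directional binomial tail probability.

    P(X >= observed) when observed > n*p, P(X <= observed) when below, and
    min of the two tails (capped at 1) when observed equals n*p exactly.
    """
    if not isinstance(observed, (int, np.integer)) or isinstance(observed, bool):
        raise PfsSnvError("observed must be an integer")
    if not isinstance(n, (int, np.integer)) or isinstance(n, bool):
        raise PfsSnvError("n must be an integer")
    if not 0 <= observed <= n:
        raise PfsSnvError(f"observed {observed} outside [0, {n}]")
    if not 0.0 <= p <= 1.0:
        raise PfsSnvError(f"p {p} outside [0, 1]")
    if p == 0.0:
        # point mass at 0: lower tail always 1; upper tail 1 iff observed 0
        return 1.0 if observed == 0 else 0.0
    if p == 1.0:
        return 1.0 if observed == n else 0.0

    def upper() -> float:
        ks = np.arange(observed, n + 1)
        return float(np.exp(logsumexp(_log_binom_pmf(ks, n, p))))

    def lower() -> float:
        ks = np.arange(0, observed + 1)
        return float(np.exp(logsumexp(_log_binom_pmf(ks, n, p))))

    expected = n * p
    if observed > expected:
        pv = upper()
    elif observed < expected:
        pv = lower()
    else:
        pv = min(upper(), lower())
    return min(pv, 1.0)


def bonferroni_cutoff(n_tests: int, alpha: float = 0.05) -> float:
    """Per-test family-wise threshold alpha / n_tests."""
    if n_tests < 1:
        raise PfsSnvError("n_tests must be >= 1")
    return alpha / n_tests


# ---------------------------------------------------------------------------
# Amino-acid background enrichment
# ---------------------------------------------------------------------------

@dataclass
class AminoAcidBackground:
    amino_acid: str
    L_A: int
    n_A_F: int
    N_A: int

    @property
    def p_A_F(self) -> float:
        return self.n_A_F / self.L_A

    @property
    def n_A_E(self) -> float:
        """Expected on-site variant count N_A * p_A(F)."""
        return self.N_A * self.p_A_F


@dataclass
class EnrichmentResult:
    amino_acid: str
    site_type: str
    n_A_O: int
    background: AminoAcidBackground
    p_value: float

    @property
    def direction(self) -> str:
        return (
            DIRECTION_ENRICHED
            if self.n_A_O > self.background.n_A_E
            else DIRECTION_DEPLETED
        )


def aa_site_enrichment(
    variants: Sequence[CollapsedVariant],
    sites: Sequence[FunctionalSite],
    proteome: ProteinSet,
    site_type: str,
    mutation_class: MutationClass,
) -> tuple[list[EnrichmentResult], list[str]]:
    """Per-amino-acid binomial test of on-site variant occurrence.

    Returns (results, skipped amino acids with no variants of the class).
    """
    residue_counts = proteome.residue_counts()

    site_positions: set[tuple[str, int]] = set()
    n_site_by_aa: dict[str, int] = {aa: 0 for aa in AMINO_ACIDS}
    for s in sites:
        if s.site_type != site_type:
            continue
        site_positions.add((s.accession, s.position))
        ref = proteome[s.accession].residue(s.position)
        if ref in n_site_by_aa:
            n_site_by_aa[ref] += 1

    n_var_by_aa: dict[str, int] = {aa: 0 for aa in AMINO_ACIDS}
    n_obs_by_aa: dict[str, int] = {aa: 0 for aa in AMINO_ACIDS}
    for v in variants:
        if MutationClass.classify(v.origin, v.consequence) is not mutation_class:
            continue
        if v.ref_aa not in n_var_by_aa:
            continue
        n_var_by_aa[v.ref_aa] += 1
        if (v.accession, v.position) in site_positions:
            n_obs_by_aa[v.ref_aa] += 1

    results: list[EnrichmentResult] = []
    skipped: list[str] = []
    for aa in AMINO_ACIDS:
        L_A = residue_counts.get(aa, 0)
        N_A = n_var_by_aa[aa]
        if N_A == 0 or L_A == 0:
            skipped.append(aa)
            continue
        bg = AminoAcidBackground(aa, L_A=L_A, n_A_F=n_site_by_aa[aa], N_A=N_A)
        pv = binomial_tail(n_obs_by_aa[aa], N_A, bg.p_A_F)
        results.append(
            EnrichmentResult(
                amino_acid=aa,
                site_type=site_type,
                n_A_O=n_obs_by_aa[aa],
                background=bg,
                p_value=pv,
            )
        )
    return results, skipped


# ---------------------------------------------------------------------------
# Patient-level enrichment
# ---------------------------------------------------------------------------

@dataclass
class PatientEnrichmentResult:
    variant: CollapsedVariant
    cancer: str
    N_C: int
    n_C_O: int
    p_C: float
    p_value: float
    significant: bool = False

    @property
    def n_C_E(self) -> float:
        return self.N_C * self.p_C


def estimate_p_c(
    variants: Sequence[CollapsedVariant],
    cancer: str,
    cohort_sizes: Mapping[str, int],
    estimator: str = "per_cancer",
) -> float:
    """Expected per-patient carriage probability of a functional-site variant.

    ``per_cancer`` (default): mean per-variant carriage rate over the
    variants observed in this cancer — total carrier count divided by
    (N_C x number of distinct variants observed in C). ``global``: the same
    ratio pooled over every cohort in ``cohort_sizes``.
    """
    if estimator == "per_cancer":
        observed = [v for v in variants if v.patients_in(cancer)]
        if not observed:
            raise PfsSnvError(f"no variants observed in cancer {cancer!r}")
        carriers = sum(len(v.patients_in(cancer)) for v in observed)
        return carriers / (cohort_sizes[cancer] * len(observed))
    if estimator == "global":
        total_carriers = 0
        total_trials = 0
        for c, n_c in cohort_sizes.items():
            observed = [v for v in variants if v.patients_in(c)]
            total_carriers += sum(len(v.patients_in(c)) for v in observed)
            total_trials += n_c * len(observed)
        if total_trials == 0:
            raise PfsSnvError("no variant observations in any cohort")
        return total_carriers / total_trials
    raise PfsSnvError(f"unknown p_C estimator {estimator!r}")


def patient_enrichment(
    variants: Sequence[CollapsedVariant],
    cancer: str,
    cohort_sizes: Mapping[str, int],
    p_c: float | None = None,
    estimator: str = "per_cancer",
) -> list[PatientEnrichmentResult]:
    """Binomial test of per-variant patient counts within one cancer type.

    ``p_c`` may be supplied directly (e.g. a known background rate);
    otherwise it is estimated from the data with ``estimator``. Only
    variants with at least one carrier in the cancer are tested.
    """
    if cancer not in cohort_sizes:
        raise PfsSnvError(f"no cohort size for cancer {cancer!r}")
    N_C = int(cohort_sizes[cancer])
    if N_C <= 0:
        raise PfsSnvError(f"cohort size for {cancer!r} must be positive")
    if p_c is None:
        p_c = estimate_p_c(variants, cancer, cohort_sizes, estimator)
    results: list[PatientEnrichmentResult] = []
    for v in variants:
        n_obs = len(v.patients_in(cancer))
        if n_obs == 0:
            continue
        if n_obs > N_C:
            raise PfsSnvError(
                f"variant {v.key} has {n_obs} carriers but cohort is {N_C}"
            )
        pv = binomial_tail(n_obs, N_C, p_c)
        results.append(
            PatientEnrichmentResult(
                variant=v, cancer=cancer, N_C=N_C, n_C_O=n_obs, p_C=p_c, p_value=pv
            )
        )
    return results


def flag_significant(
    results: Iterable[PatientEnrichmentResult],
    alpha: float = 0.05,
    n_tests: int | None = None,
) -> float:
    """Apply the Bonferroni cutoff in place; returns the threshold used.

    The family defaults to all tests passed in (the run's pfsSNV x cancer
    tests).
    """
    results = list(results)
    if n_tests is None:
        n_tests = len(results)
    cutoff = bonferroni_cutoff(n_tests, alpha)
    for r in results:
        r.significant = r.p_value < cutoff
    return cutoff


def manhattan_frame(results: Iterable[PatientEnrichmentResult]):
    """Scatter-ready table of (protein index, -log10 p) per tested variant."""
    import pandas as pd

    rows = []
    accession_index: dict[str, int] = {}
    for r in results:
        acc = r.variant.accession
        idx = accession_index.setdefault(acc, len(accession_index) + 1)
        rows.append(
            {
                "accession": acc,
                "protein_index": idx,
                "variant": f"{r.variant.ref_aa}{r.variant.position}{r.variant.alt_aa}",
                "cancer": r.cancer,
                "n_C_O": r.n_C_O,
                "N_C": r.N_C,
                "p_value": r.p_value,
                "neg_log10_p": -np.log10(max(r.p_value, 1e-300)),
                "significant": r.significant,
            }
        )
    return pd.DataFrame(rows)
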