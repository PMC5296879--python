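"""Pan-cancer fold-change matrix, hierarchical clustering, key-variant picks.

The matrix cell for (cancer, site type) is observed / expected where the
observed value is the offset-0 occurrence of that cancer's somatic variants
and the expected value is the mean occurrence over the 40 neighbor offsets.
Cells with no variants anywhere in the window stay missing (never 0).
Clustering is deterministic: euclidean distance, complete linkage, ties
broken by lexicographic row label.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .io_model import CollapsedVariant, PfsSnvError
from .enrichment import PatientEnrichmentResult
from .site_effects import EFFECT_GAIN, EFFECT_LOSS, SEQUON_NONE, WINDOW

#: observed > 0 with expected = 0 collapses to this sentinel (and is reported)
FOLD_CAP = 999.0


# ---------------------------------------------------------------------------
# Matrix
# ---------------------------------------------------------------------------

@dataclass
class PanCancerMatrix:
    values: pd.DataFrame  # rows: cancers, columns: site types, NaN = missing
    consequence: str
    capped_cells: list[tuple[str, str]] = field(default_factory=list)

    def write(self, path: str | Path) -> None:
        self.values.to_csv(path, sep="\t", na_rep="NA")


def build_pancancer_matrix(
    annotations: pd.DataFrame,
    variants: Sequence[CollapsedVariant],
    denominators: Mapping[str, Mapping[int, int]],
    consequence: str = "non-synonymous",
    window: int = WINDOW,
    cap: float = FOLD_CAP,
) -> PanCancerMatrix:
    """Observed/expected fold-change matrix over (cancer, site type).

    Somatic annotations of the given consequence are attributed to every
    DO-slim cancer in which the underlying variant has patients. Expected
    is the mean of the per-offset occurrences over offsets +/-1..window.
    """
    som = annotations[
        (annotations["origin"] == "somatic")
        & (annotations["consequence"] == consequence)
    ]
    # per (cancer, site_type, offset) distinct-variant counts
    counts: dict[tuple[str, str], dict[int, int]] = {}
    cancers: set[str] = set()
    for site_type, offset, vidx in zip(
        som["site_type"], som["offset"], som["variant_index"]
    ):
        for cancer, patients in variants[vidx].patients_by_cancer.items():
            if not patients:
                continue
            cancers.add(cancer)
            per = counts.setdefault((cancer, site_type), {})
            per[offset] = per.get(offset, 0) + 1

    site_types = sorted(denominators)
    rows = sorted(cancers)
    values = pd.DataFrame(np.nan, index=rows, columns=site_types)
    capped: list[tuple[str, str]] = []
    for cancer in rows:
        for site_type in site_types:
            denom = denominators[site_type]
            per = counts.get((cancer, site_type))
            if not per:
                continue  # no variants in the window: missing cell
            d0 = denom.get(0, 0)
            if d0 == 0:
                continue
            observed = per.get(0, 0) / d0
            neighbor_occ = [
                per.get(off, 0) / denom[off]
                for off in range(-window, window + 1)
                if off != 0 and denom.get(off, 0)
            ]
            if not neighbor_occ:
                continue
            expected = float(np.mean(neighbor_occ))
            if expected == 0.0:
                if observed > 0.0:
                    values.loc[cancer, site_type] = cap
                    capped.append((cancer, site_type))
                continue
            values.loc[cancer, site_type] = observed / expected
    return PanCancerMatrix(values=values, consequence=consequence, capped_cells=capped)


# ---------------------------------------------------------------------------
# Hierarchical clustering (complete linkage, deterministic)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Merge:
    left: tuple[str, ...]
    right: tuple[str, ...]
    height: float


@dataclass
class ClusterResult:
    order: list[str]
    merges: list[Merge]
    imputed_cells: list[tuple[str, str]]

    def newick(self) -> str:
        """Merge tree in newick form, branch lengths = merge heights."""
        node: dict[tuple[str, ...], str] = {}
        for m in self.merges:
            left = node.get(m.left, m.left[0] if len(m.left) == 1 else None)
            right = node.get(m.right, m.right[0] if len(m.right) == 1 else None)
            rep = f"({left},{right}):{m.height:.6g}"
            node[tuple(sorted(m.left + m.right))] = rep
        if not self.merges:
            return f"({self.order[0]});" if self.order else "();"
        root = node[tuple(sorted(self.order))]
        # root branch length is meaningless; strip it
        return root.rsplit(":", 1)[0] + ";"


def hierarchical_cluster(
    matrix: PanCancerMatrix | pd.DataFrame,
    impute_value: float = 1.0,
) -> ClusterResult:
    """Agglomerative complete-linkage clustering of matrix rows.

    Missing cells are imputed as ``impute_value`` (no change) for distance
    computation only and reported. Ties in the nearest-pair choice are
    broken by the lexicographically smallest (left label, right label)
    pair, so the merge tree is independent of input row order.
    """
    df = matrix.values if isinstance(matrix, PanCancerMatrix) else matrix
    if len(df) == 0:
        raise PfsSnvError("cannot cluster an empty matrix")
    na_rows, na_cols = np.where(df.isna().to_numpy())
    imputed = [
        (str(df.index[r]), str(df.columns[c])) for r, c in zip(na_rows, na_cols)
    ]
    filled = df.fillna(impute_value)
    arr = filled.to_numpy(dtype=float)
    labels = [str(x) for x in filled.index]
    points = {lab: arr[i] for i, lab in enumerate(labels)}

    if len(labels) == 1:
        return ClusterResult(order=list(labels), merges=[], imputed_cells=imputed)

    # cluster state: map from representative (min label) to member tuple
    clusters: dict[str, tuple[str, ...]] = {lab: (lab,) for lab in labels}
    dist: dict[frozenset[str], float] = {}
    for i, a in enumerate(labels):
        for b in labels[i + 1 :]:
            dist[frozenset((a, b))] = float(
                np.linalg.norm(points[a] - points[b])
            )

    merges: list[Merge] = []
    while len(clusters) > 1:
        reps = sorted(clusters)
        best: tuple[float, str, str] | None = None
        for i, a in enumerate(reps):
            for b in reps[i + 1 :]:
                d = dist[frozenset((a, b))]
                cand = (d, a, b)
                if best is None or cand < best:
                    best = cand
        d, a, b = best
        members_a, members_b = clusters.pop(a), clusters.pop(b)
        new_rep = min(a, b)
        merges.append(Merge(left=members_a, right=members_b, height=d))
        # complete linkage: distance to the union is the max of the parts
        for other in clusters:
            dist[frozenset((new_rep, other))] = max(
                dist[frozenset((a, other))], dist[frozenset((b, other))]
            )
        clusters[new_rep] = members_a + members_b

    order = list(next(iter(clusters.values())))
    return ClusterResult(order=order, merges=merges, imputed_cells=imputed)


# ---------------------------------------------------------------------------
# Key pfsSNV selection
# ---------------------------------------------------------------------------

CRITERION_MULTI = "multi_cancer"
CRITERION_ENRICHED = "patient_enriched"
CRITERION_BOTH = "both"


@dataclass
class KeyPfsSNV:
    variant: CollapsedVariant
    site_type: str
    effect: str  # loss or gain
    criterion: str
    cancer_type_count: int
    enriched_cancers: list[tuple[str, float]] = field(default_factory=list)
    smg: bool = False
    cgc: bool = False

    @property
    def variation(self) -> str:
        return f"{self.variant.ref_aa}{self.variant.position}{self.variant.alt_aa}"

    @property
    def effect_tag(self) -> str:
        return "[G]" if self.effect == EFFECT_GAIN else "[L]"


def _pfssnv_effects(
    annotations: pd.DataFrame, variants: Sequence[CollapsedVariant]
) -> dict[int, tuple[str, str]]:
    """variant_index -> (site_type, loss/gain effect) for variants that hit
    a functional site (offset 0 or a sequon position) with a loss call, or
    that carry a gain flag."""
    effects: dict[int, tuple[str, str]] = {}
    on_site = annotations[
        (annotations["effect"] == EFFECT_LOSS)
        & ((annotations["offset"] == 0) | (annotations["sequon_role"] != SEQUON_NONE))
    ]
    for vidx, site_type in zip(on_site["variant_index"], on_site["site_type"]):
        effects.setdefault(int(vidx), (site_type, EFFECT_LOSS))
    for idx, v in enumerate(variants):
        if v.gain_phospho and idx not in effects:
            effects[idx] = ("phosphorylation", EFFECT_GAIN)
    return effects


def select_key_multi_cancer(
    annotations: pd.DataFrame,
    variants: Sequence[CollapsedVariant],
    min_types: int = 5,
) -> list[KeyPfsSNV]:
    """Functional-site variants present in ``min_types`` or more cancers,
    sorted by descending cancer-type count then variant key."""
    effects = _pfssnv_effects(annotations, variants)
    keys: list[KeyPfsSNV] = []
    for vidx, (site_type, effect) in effects.items():
        v = variants[vidx]
        if v.cancer_type_count >= min_types:
            keys.append(
                KeyPfsSNV(
                    variant=v,
                    site_type=site_type,
                    effect=effect,
                    criterion=CRITERION_MULTI,
                    cancer_type_count=v.cancer_type_count,
                )
            )
    keys.sort(key=lambda k: (-k.cancer_type_count, k.variant.key))
    return keys


def select_key_patient_enriched(
    annotations: pd.DataFrame,
    variants: Sequence[CollapsedVariant],
    enrichment_results: Iterable[PatientEnrichmentResult],
) -> list[KeyPfsSNV]:
    """Functional-site variants with >= 1 significant patient-enrichment test."""
    effects = _pfssnv_effects(annotations, variants)
    index_of = {id(v): i for i, v in enumerate(variants)}
    by_variant: dict[int, list[tuple[str, float]]] = {}
    for r in enrichment_results:
        if not r.significant:
            continue
        vidx = index_of.get(id(r.variant))
        if vidx is None or vidx not in effects:
            continue
        by_variant.setdefault(vidx, []).append((r.cancer, r.p_value))
    keys: list[KeyPfsSNV] = []
    for vidx, cancers in by_variant.items():
        v = variants[vidx]
        site_type, effect = effects[vidx]
        keys.append(
            KeyPfsSNV(
                variant=v,
                site_type=site_type,
                effect=effect,
                criterion=CRITERION_ENRICHED,
                cancer_type_count=v.cancer_type_count,
                enriched_cancers=sorted(cancers),
            )
        )
    keys.sort(key=lambda k: (min(p for _, p in k.enriched_cancers), k.variant.key))
    return keys


def combine_key_lists(
    multi: Iterable[KeyPfsSNV], enriched: Iterable[KeyPfsSNV]
) -> list[KeyPfsSNV]:
    """Union of the two criteria; overlapping variants get criterion=both."""
    merged: dict[tuple, KeyPfsSNV] = {}
    for k in multi:
        merged[k.variant.key] = k
    for k in enriched:
        prev = merged.get(k.variant.key)
        if prev is None:
            merged[k.variant.key] = k
        else:
            prev.criterion = CRITERION_BOTH
            prev.enriched_cancers = k.enriched_cancers
    return sorted(
        merged.values(), key=lambda k: (-k.cancer_type_count, k.variant.key)
    )


def intersect_gene_lists(
    keys: list[KeyPfsSNV],
    smg: set[str],
    cgc: set[str],
) -> dict[str, set[str]]:
    """Flag SMG/CGC membership on each key; return intersection summary.

    Summary maps ``smg``/``cgc``/``both`` to the gene symbols of keys found
    in the respective list(s); keys without a gene symbol are reported
    under ``unmatched``.
    """
    genes_in_keys: set[str] = set()
    unmatched: set[str] = set()
    for k in keys:
        gene = k.variant.gene
        if not gene:
            unmatched.add(k.variation)
            continue
        genes_in_keys.add(gene)
        k.smg = gene in smg
        k.cgc = gene in cgc
    return {
        "smg": genes_in_keys & smg,
        "cgc": genes_in_keys & cgc,
        "both": genes_in_keys & smg & cgc,
        "unmatched": unmatched,
    }


def keys_frame(keys: Iterable[KeyPfsSNV]) -> pd.DataFrame:
    rows = []
    for k in keys:
        rows.append(
            {
                "gene": k.variant.gene,
                "accession": k.variant.accession,
                "variation": k.variation,
                "functional_site": f"{k.effect_tag}{k.site_type}",
                "criterion": k.criterion,
                "cancer_type_count": k.cancer_type_count,
                "min_enrichment_p": (
                    min(p for _, p in k.enriched_cancers)
                    if k.enriched_cancers
                    else math.nan
                ),
                "smg": k.smg,
                "cgc": k.cgc,
            }
        )
    return pd.DataFrame(rows)
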