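"""Global SNV rates, per-site-type impact percentages and +/-20 profiles.

Analyzed variants split into four mutation classes — (non-)synonymous x
germline/somatic — abbreviated non_SG, SG, non_SS, SS; stop-gain records
are excluded from the partition. Fold change at an offset is the occurrence
(distinct collapsed variants per valid residue) divided by the global
per-residue rate of the class, so 1.0 reads as background.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd
from scipy import stats

from .io_model import CollapsedVariant, FunctionalSite, PfsSnvError, ProteinSet
from .site_effects import WINDOW


class MutationClass(str, Enum):
    non_SG = "non_SG"
    SG = "SG"
    non_SS = "non_SS"
    SS = "SS"

    @property
    def origin(self) -> str:
        return "germline" if self.name.endswith("SG") else "somatic"

    @property
    def consequence(self) -> str:
        return "non-synonymous" if self.name.startswith("non") else "synonymous"

    @classmethod
    def classify(cls, origin: str, consequence: str) -> "MutationClass | None":
        """Class of a variant, or None for stop-gain records."""
        if consequence == "stop":
            return None
        for mc in cls:
            if mc.origin == origin and mc.consequence == consequence:
                return mc
        raise PfsSnvError(f"unclassifiable variant ({origin}, {consequence})")


def global_snv_rate(
    variants: Iterable[CollapsedVariant],
    proteome: ProteinSet,
    mutation_class: MutationClass,
) -> float:
    """Distinct collapsed variants of the class per proteome residue."""
    total = proteome.total_length
    if total == 0:
        raise PfsSnvError("empty proteome")
    n = sum(
        1
        for v in variants
        if MutationClass.classify(v.origin, v.consequence) is mutation_class
    )
    return n / total


def _class_mask(annotations: pd.DataFrame, mutation_class: MutationClass) -> pd.Series:
    return (annotations["origin"] == mutation_class.origin) & (
        annotations["consequence"] == mutation_class.consequence
    )


def percent_sites_impacted(
    sites: list[FunctionalSite],
    annotations: pd.DataFrame,
    mutation_class: MutationClass,
) -> tuple[dict[str, float], list[str]]:
    """Percent of each site type's positions hit at offset 0 by the class.

    Returns (site_type -> percentage, report of types with zero sites).
    """
    totals: dict[str, int] = {}
    for s in sites:
        totals[s.site_type] = totals.get(s.site_type, 0) + 1

    hits = annotations[(annotations["offset"] == 0) & _class_mask(annotations, mutation_class)]
    hit_counts = (
        hits.groupby("site_type")[["accession", "site_position"]]
        .apply(lambda g: len(g.drop_duplicates()))
        .to_dict()
    )
    out: dict[str, float] = {}
    skipped: list[str] = []
    for site_type, total in totals.items():
        if total == 0:
            skipped.append(site_type)
            continue
        out[site_type] = 100.0 * hit_counts.get(site_type, 0) / total
    return out, skipped


@dataclass
class TTestResult:
    t: float
    p: float
    n_neighbors: int
    degenerate: bool = False


@dataclass
class NeighborhoodProfile:
    """Per-offset counts, denominators and fold changes for one
    (site type, mutation class) pair, plus the site-vs-neighbors test."""

    site_type: str
    mutation_class: MutationClass
    counts: dict[int, int]
    denominators: dict[int, int]
    fold_change: dict[int, float]
    global_rate: float
    t_statistic: float | None = None
    p_value: float | None = None
    degenerate: bool = False

    @property
    def offsets(self) -> list[int]:
        return sorted(self.fold_change)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "site_type": self.site_type,
                "class": self.mutation_class.value,
                "offset": self.offsets,
                "count": [self.counts[o] for o in self.offsets],
                "denominator": [self.denominators[o] for o in self.offsets],
                "fold_change": [self.fold_change[o] for o in self.offsets],
            }
        )


def neighborhood_profile(
    annotations: pd.DataFrame,
    denominators: dict[str, dict[int, int]],
    mutation_class: MutationClass,
    site_type: str,
    global_rate: float,
    window: int = WINDOW,
) -> NeighborhoodProfile:
    """Fold-change profile over offsets -window..window for one site type.

    occurrence(o) = class annotation count at o / valid residues at o;
    fold_change(o) = occurrence(o) / global class rate. Offsets with zero
    denominator are omitted.
    """
    if global_rate <= 0:
        raise PfsSnvError("profile undefined for zero global rate")
    denom = denominators.get(site_type, {})
    sel = annotations[
        (annotations["site_type"] == site_type)
        & _class_mask(annotations, mutation_class)
    ]
    raw_counts = sel.groupby("offset").size().to_dict()
    counts: dict[int, int] = {}
    fold: dict[int, float] = {}
    denoms: dict[int, int] = {}
    for off in range(-window, window + 1):
        d = denom.get(off, 0)
        if d == 0:
            continue
        c = int(raw_counts.get(off, 0))
        counts[off] = c
        denoms[off] = d
        fold[off] = (c / d) / global_rate
    return NeighborhoodProfile(
        site_type=site_type,
        mutation_class=mutation_class,
        counts=counts,
        denominators=denoms,
        fold_change=fold,
        global_rate=global_rate,
    )


def site_vs_neighbors_ttest(profile: NeighborhoodProfile) -> TTestResult:
    """One-sample t-test of neighbor fold changes against the site value.

    The 2*window neighbor fold changes form the sample; the offset-0 fold
    change is the hypothesized mean. Two-sided p on n_neighbors - 1 df.
    Sign convention: t > 0 when the neighbor mean exceeds the site value.
    Zero variance among neighbors is degenerate: p = 1 if the neighbor
    mean equals the site value, else p = 0.
    """
    if 0 not in profile.fold_change:
        raise PfsSnvError("profile has no offset-0 value")
    site_value = profile.fold_change[0]
    neighbors = np.array(
        [fc for off, fc in profile.fold_change.items() if off != 0], dtype=float
    )
    n = neighbors.size
    if n < 2:
        raise PfsSnvError("need at least 2 neighbor offsets for the t-test")
    mean = neighbors.mean()
    sd = neighbors.std(ddof=1)
    if sd == 0:
        p = 1.0 if mean == site_value else 0.0
        t = 0.0 if mean == site_value else np.inf * np.sign(mean - site_value)
        result = TTestResult(t=float(t), p=p, n_neighbors=n, degenerate=True)
    else:
        t = (mean - site_value) / (sd / np.sqrt(n))
        p = 2.0 * stats.t.sf(abs(t), df=n - 1)
        result = TTestResult(t=float(t), p=float(p), n_neighbors=n)
    profile.t_statistic = result.t
    profile.p_value = result.p
    profile.degenerate = result.degenerate
    return result


def profiles_summary(profiles: Iterable[NeighborhoodProfile]) -> pd.DataFrame:
    rows = []
    for pr in profiles:
        rows.append(
            {
                "site_type": pr.site_type,
                "class": pr.mutation_class.value,
                "t": pr.t_statistic,
                "p": pr.p_value,
                "degenerate": pr.degenerate,
            }
        )
    return pd.DataFrame(rows)


def write_profiles(
    profiles: Iterable[NeighborhoodProfile], out_dir: str | Path
) -> None:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    profiles = list(profiles)
    frames = [pr.to_frame() for pr in profiles]
    if frames:
        pd.concat(frames, ignore_index=True).to_csv(
            out_dir / "neighborhood_profiles.tsv", sep="\t", index=False
        )
    profiles_summary(profiles).to_csv(
        out_dir / "neighborhood_ttests.tsv", sep="\t", index=False
    )


def plot_profile(profile: NeighborhoodProfile, path: str | Path) -> None:
    """Simple line plot of a fold-change profile (optional output)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 3))
    offs = profile.offsets
    ax.plot(offs, [profile.fold_change[o] for o in offs], marker="o", ms=2)
    ax.axhline(1.0, color="grey", lw=0.5)
    ax.set_xlabel("offset from site")
    ax.set_ylabel("fold change")
    ax.set_title(f"{profile.site_type} / {profile.mutation_class.value}")
    fig.tight_layout()
    fig.savefig(path, dpi=100)
    plt.close(fig)
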