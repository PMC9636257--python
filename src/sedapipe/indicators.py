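"""Ecological-indicator grading and derived per-sample series.

A trnL P6-loop barcode often matches several species (haplotype-sharing
species).  A barcode is usable as an ecological indicator for a dimension
(elevational belt, pastoral activity, arable activity) only under the
*unanimity rule*: every haplotype-sharing species must carry the same value
for that dimension.  Any conflict, missing species or missing value makes
the barcode unsuitable *for that dimension* — the dimensions are graded
independently, so a barcode can be a pastoral indicator while being
belt-unsuitable.

Downstream series (belt profiles, pastoral/arable activity, functional
groups) sum RAI over the optimal indicators of each class.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .abundance import RAIMatrix
from .io_formats import BELT_VOCABULARY, GROWTH_FORMS, ReplicateCountTable

__all__ = [
    "IndicatorAssignment",
    "grade_indicators",
    "belt_profile",
    "activity_series",
    "richness",
    "functional_groups",
]

DIMENSIONS = ("belt", "pastoral", "arable")


@dataclass
class IndicatorAssignment:
    """Per-dimension grading outcome for one barcode."""

    barcode_id: str
    species: list
    grade: dict = field(default_factory=dict)  # dimension -> "optimal" | "unsuitable"
    value: dict = field(default_factory=dict)  # dimension -> unanimous value (if optimal)
    log: list = field(default_factory=list)

    def is_optimal(self, dimension: str) -> bool:
        return self.grade.get(dimension) == "optimal"


def _normalize(name: str) -> str:
    return " ".join(str(name).split()).casefold()


def grade_indicators(
    barcode_to_species: dict, traits: pd.DataFrame
) -> dict[str, IndicatorAssignment]:
    """Grade each barcode per ecological dimension by the unanimity rule.

    ``barcode_to_species`` maps barcode ids to their haplotype-sharing
    species lists; ``traits`` is the species trait table (index = species).
    Species names are matched after whitespace/case normalization — no
    fuzzy matching.  Intermediate agreement levels (e.g. majority) are
    recorded in the log but graded unsuitable: only unanimous barcodes feed
    the indicator series.
    """
    lookup = {_normalize(sp): sp for sp in traits.index}
    out: dict[str, IndicatorAssignment] = {}
    for bid, species in barcode_to_species.items():
        asg = IndicatorAssignment(barcode_id=bid, species=list(species))
        if not species:
            for dim in DIMENSIONS:
                asg.grade[dim] = "unsuitable"
            asg.log.append("empty species list")
            out[bid] = asg
            continue
        resolved, missing = [], []
        for sp in species:
            key = _normalize(sp)
            (resolved if key in lookup else missing).append(lookup.get(key, sp))
        if missing:
            asg.log.append(f"species missing from trait table: {missing}")
        for dim, col, empty_ok in (
            ("belt", "belt", True),
            ("pastoral", "pastoral_flag", False),
            ("arable", "arable_flag", False),
        ):
            if missing or not resolved:
                asg.grade[dim] = "unsuitable"
                continue
            values = [traits.at[sp, col] for sp in resolved]
            distinct = set(values)
            if len(distinct) == 1 and (values[0] != "" or not empty_ok):
                v = values[0]
                if dim == "belt" and v == "":
                    asg.grade[dim] = "unsuitable"
                    asg.log.append("belt: unanimous but no belt value")
                elif dim in ("pastoral", "arable") and not v:
                    # unanimously non-indicator: suitable grading, class "none"
                    asg.grade[dim] = "unsuitable"
                else:
                    asg.grade[dim] = "optimal"
                    asg.value[dim] = bool(v) if dim != "belt" else v
            else:
                asg.grade[dim] = "unsuitable"
                agree = max(values.count(v) for v in distinct)
                asg.log.append(
                    f"{dim}: conflicting values {sorted(map(str, distinct))} "
                    f"(majority {agree}/{len(values)})"
                )
        out[bid] = asg
    return out


def _rai_frame(rai: RAIMatrix | pd.DataFrame) -> pd.DataFrame:
    return rai.value if isinstance(rai, RAIMatrix) else rai


def belt_profile(
    rai, assignments: dict[str, IndicatorAssignment], mode: str = "rai"
) -> pd.DataFrame:
    """Per-sample elevational-belt composition from optimal belt indicators.

    ``mode='rai'`` (default) sums RAI per belt and renormalizes over
    belt-indicator taxa; ``mode='count'`` uses the share of *detected*
    indicator taxa instead.  Samples where no belt indicator occurs are
    all-NaN rows (flagged empty rather than fabricating a composition).
    """
    if mode not in ("rai", "count"):
        raise ValueError("mode must be 'rai' or 'count'")
    values = _rai_frame(rai)
    belt_of = {
        bid: a.value["belt"]
        for bid, a in assignments.items()
        if a.is_optimal("belt") and bid in values.columns
    }
    if not belt_of:
        raise ValueError("no optimal belt indicator present in the matrix")
    out = pd.DataFrame(0.0, index=values.index, columns=list(BELT_VOCABULARY))
    for bid, belt in belt_of.items():
        contrib = values[bid] if mode == "rai" else (values[bid] > 0).astype(float)
        out[belt] = out[belt] + contrib
    totals = out.sum(axis=1)
    out = out.div(totals.where(totals > 0, np.nan), axis=0)
    return out


def activity_series(
    rai, assignments: dict[str, IndicatorAssignment]
) -> pd.DataFrame:
    """Summed RAI of pastoral and of arable indicator taxa, per sample."""
    values = _rai_frame(rai)
    out = pd.DataFrame(0.0, index=values.index, columns=["pastoral", "arable"])
    for dim in ("pastoral", "arable"):
        ids = [
            bid
            for bid, a in assignments.items()
            if a.is_optimal(dim) and a.value.get(dim) is True and bid in values.columns
        ]
        if ids:
            out[dim] = values[ids].sum(axis=1)
    return out


def richness(
    retained_table: ReplicateCountTable | pd.DataFrame, smooth: bool = False, span: float = 0.1
):
    """Per-sample taxon richness: the count of taxa recorded in each sample.

    Accepts a retained count table or any sample x taxon abundance frame.
    With ``smooth=True`` also returns a loess-smoothed curve (span 0.1,
    matching the presentation convention for richness series).
    """
    if isinstance(retained_table, ReplicateCountTable):
        per_sample = retained_table.reads_per_sample().T  # unit x taxon
        per_sample = per_sample.loc[
            [s for s in retained_table.sample_units if s in per_sample.index]
        ]
    else:
        per_sample = retained_table
    counts = (per_sample > 0).sum(axis=1).astype(int)
    if not smooth:
        return counts
    from .drivers import loess_smooth

    smoothed = pd.Series(
        loess_smooth(counts.to_numpy(dtype=float), span=span), index=counts.index
    )
    return counts, smoothed


def functional_groups(rai, traits_by_barcode: dict) -> pd.DataFrame:
    """Per-sample RAI proportions of growth forms (tree/shrub/forb/...).

    ``traits_by_barcode`` maps barcode id -> growth form (the unanimous
    growth form of its haplotype-sharing species; barcodes without one are
    left out).  Rows renormalize to 1; samples with nothing assigned are NaN.
    """
    values = _rai_frame(rai)
    out = pd.DataFrame(0.0, index=values.index, columns=list(GROWTH_FORMS))
    seen = False
    for bid, form in traits_by_barcode.items():
        if bid in values.columns and form in GROWTH_FORMS:
            out[form] = out[form] + values[bid]
            seen = True
    if not seen:
        raise ValueError("no barcode carries a growth form")
    totals = out.sum(axis=1)
    return out.div(totals.where(totals > 0, np.nan), axis=0)
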