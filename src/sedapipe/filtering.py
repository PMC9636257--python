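"""Retention cascade and curation rules for metabarcoding count tables.

The cascade mirrors standard replicate-aware sedaDNA curation:

1. length / singleton pre-filter,
2. reference-identity filter (perfect match in at least one database),
3. merging of homopolymer-length artifact variants into their source,
4. detection and total-read thresholds (a cell is a *detection* only when it
   holds at least ``min_reads_per_replicate_detection`` reads; sub-threshold
   cells are zeroed so they cannot leak into downstream abundance indices),
5. removal of barcodes that are better represented in negative controls
   than in sediment samples (with an ecological whitelist),
6. marker-specific taxonomic curation (mammal 16S: discard off-target taxa,
   collapse by taxon, flag sporadic single-replicate detections).

Merging runs *before* the detection/total thresholds so that true variants
rescue their source sequence's totals.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io_formats import ReplicateCountTable, ValidationError

__all__ = [
    "FilterParams",
    "FilterReport",
    "prefilter_barcodes",
    "apply_detection_thresholds",
    "filter_barcodes",
    "merge_artifacts",
    "remove_contaminants",
    "curate_mammals",
    "run_cascade",
    "homopolymer_runs",
    "is_homopolymer_variant",
]


@dataclass
class FilterParams:
    """Thresholds of the retention cascade (defaults are the study rules)."""

    min_identity: float = 1.0
    min_reads_per_replicate_detection: int = 3
    min_total_reads: int = 10
    min_total_replicates: int = 3
    min_barcode_length: int = 10
    drop_singletons: bool = True
    #: "dataset" counts detections across every unit and replicate;
    #: "sample" requires min_total_replicates within some single sample.
    replicate_scope: str = "dataset"
    whitelist: frozenset = frozenset()
    blacklist: frozenset = frozenset()

    def __post_init__(self) -> None:
        if not (0.0 <= self.min_identity <= 1.0):
            raise ValueError("min_identity must lie in [0, 1]")
        for name in (
            "min_reads_per_replicate_detection",
            "min_total_reads",
            "min_total_replicates",
            "min_barcode_length",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.replicate_scope not in ("dataset", "sample"):
            raise ValueError("replicate_scope must be 'dataset' or 'sample'")
        self.whitelist = frozenset(self.whitelist)
        self.blacklist = frozenset(self.blacklist)


@dataclass
class FilterReport:
    """Provenance of every barcode through one cascade stage (or the whole)."""

    input_barcodes: int = 0
    retained: list = field(default_factory=list)
    removed: dict = field(default_factory=dict)   # rule -> [barcode ids]
    merged: dict = field(default_factory=dict)    # variant id -> source id
    zeroed_reads: int = 0
    input_reads: int = 0
    retained_reads: int = 0
    removed_reads: int = 0
    control_detected_taxa: list = field(default_factory=list)
    notes: list = field(default_factory=list)

    @property
    def rule_counts(self) -> dict:
        return {rule: len(ids) for rule, ids in self.removed.items()}

    def n_removed(self) -> int:
        return sum(len(v) for v in self.removed.values())

    def check_conservation(self) -> None:
        if self.input_barcodes != len(self.retained) + self.n_removed() + len(self.merged):
            raise ValidationError("barcode accounting does not balance")
        if self.input_reads != self.retained_reads + self.removed_reads + self.zeroed_reads:
            raise ValidationError("read accounting does not balance")

    def to_dict(self) -> dict:
        return {
            "input_barcodes": self.input_barcodes,
            "n_retained": len(self.retained),
            "removed_per_rule": self.rule_counts,
            "n_merged": len(self.merged),
            "merged": dict(self.merged),
            "input_reads": int(self.input_reads),
            "retained_reads": int(self.retained_reads),
            "removed_reads": int(self.removed_reads),
            "zeroed_reads": int(self.zeroed_reads),
            "control_detected_taxa": list(self.control_detected_taxa),
            "notes": list(self.notes),
        }


def _base_report(table: ReplicateCountTable) -> FilterReport:
    rep = FilterReport()
    rep.input_barcodes = len(table.meta)
    rep.input_reads = int(table.total_reads().sum())
    return rep


def _finalize(table: ReplicateCountTable, keep, rep: FilterReport) -> ReplicateCountTable:
    out = table.subset_barcodes(keep)
    rep.retained = list(keep)
    rep.retained_reads = int(out.total_reads().sum())
    rep.removed_reads = rep.input_reads - rep.retained_reads - rep.zeroed_reads
    rep.check_conservation()
    return out


# ---------------------------------------------------------------------------
# Stages
# ---------------------------------------------------------------------------

def prefilter_barcodes(
    table: ReplicateCountTable, params: FilterParams
) -> tuple[ReplicateCountTable, FilterReport]:
    """Length, singleton and reference-identity rules."""
    rep = _base_report(table)
    totals = table.total_reads()
    identity = table.best_identity.fillna(0.0)
    seq_len = table.meta["sequence"].str.len()

    keep = []
    for bid in table.meta.index:
        if seq_len[bid] < params.min_barcode_length:
            rep.removed.setdefault("short_sequence", []).append(bid)
        elif params.drop_singletons and totals[bid] <= 1:
            rep.removed.setdefault("singleton", []).append(bid)
        elif identity[bid] < params.min_identity:
            rep.removed.setdefault("low_identity", []).append(bid)
        else:
            keep.append(bid)
    return _finalize(table, keep, rep), rep


def _detections(counts: pd.DataFrame, min_reads: int) -> pd.DataFrame:
    return counts >= min_reads


def apply_detection_thresholds(
    table: ReplicateCountTable, params: FilterParams
) -> tuple[ReplicateCountTable, FilterReport]:
    """Total-read / replicate-detection thresholds; zero sub-threshold cells.

    A barcode survives when its raw total reads reach ``min_total_reads`` and
    it is detected (>= ``min_reads_per_replicate_detection`` reads in a cell)
    in at least ``min_total_replicates`` replicates — across the whole data
    set by default, within one sample under ``replicate_scope='sample'``.
    """
    rep = _base_report(table)
    det = _detections(table.counts, params.min_reads_per_replicate_detection)
    totals = table.total_reads()

    if params.replicate_scope == "dataset":
        n_det = det.sum(axis=1)
        enough_reps = n_det >= params.min_total_replicates
    else:
        per_sample = det.T.groupby(level=0).sum().T
        enough_reps = (per_sample >= params.min_total_replicates).any(axis=1)

    keep = []
    for bid in table.meta.index:
        if totals[bid] < params.min_total_reads:
            rep.removed.setdefault("low_total_reads", []).append(bid)
        elif not enough_reps[bid]:
            rep.removed.setdefault("too_few_replicates", []).append(bid)
        else:
            keep.append(bid)

    out = table.subset_barcodes(keep)
    sub = out.counts.where(
        _detections(out.counts, params.min_reads_per_replicate_detection), 0
    )
    rep.zeroed_reads = int((out.counts - sub).to_numpy().sum())
    out = ReplicateCountTable(out.meta, sub.astype(np.int64), out.samples)
    rep.retained = list(keep)
    rep.retained_reads = int(out.total_reads().sum())
    rep.removed_reads = rep.input_reads - rep.retained_reads - rep.zeroed_reads
    rep.check_conservation()
    return out, rep


def filter_barcodes(
    table: ReplicateCountTable, params: FilterParams | None = None
) -> tuple[ReplicateCountTable, FilterReport]:
    """Length/singleton/identity rules plus detection and total thresholds."""
    params = params or FilterParams()
    pre, rep1 = prefilter_barcodes(table, params)
    out, rep2 = apply_detection_thresholds(pre, params)
    rep = _base_report(table)
    rep.removed = {**rep1.removed, **rep2.removed}
    rep.zeroed_reads = rep2.zeroed_reads
    rep.retained = rep2.retained
    rep.retained_reads = rep2.retained_reads
    rep.removed_reads = rep.input_reads - rep.retained_reads - rep.zeroed_reads
    rep.check_conservation()
    return out, rep


# ---------------------------------------------------------------------------
# Homopolymer artifact merging
# ---------------------------------------------------------------------------

def homopolymer_runs(seq: str) -> list[tuple[str, int]]:
    """Run-length encoding of a sequence, e.g. 'AAATG' -> [(A,3),(T,1),(G,1)]."""
    runs: list[tuple[str, int]] = []
    for ch in seq:
        if runs and runs[-1][0] == ch:
            runs[-1] = (ch, runs[-1][1] + 1)
        else:
            runs.append((ch, 1))
    return runs


def is_homopolymer_variant(a: str, b: str) -> bool:
    """True when *a* and *b* differ only in the length of one homopolymer run."""
    if a == b:
        return False
    ra, rb = homopolymer_runs(a), homopolymer_runs(b)
    if len(ra) != len(rb):
        return False
    diffs = 0
    for (ca, la), (cb, lb) in zip(ra, rb):
        if ca != cb:
            return False
        if la != lb:
            diffs += 1
    return diffs == 1


def merge_artifacts(
    table: ReplicateCountTable,
) -> tuple[ReplicateCountTable, FilterReport]:
    """Merge homopolymer-length variants into their more abundant source.

    Each barcode that is a homopolymer variant of a strictly more abundant
    barcode is summed into the most abundant such candidate (sequence
    lexicographic order breaks abundance ties); chains resolve transitively
    to the final unmerged source.  Totals are those of the input table, so
    the outcome does not depend on merge order.
    """
    rep = _base_report(table)
    totals = table.total_reads()
    seqs = table.meta["sequence"]
    ids = list(table.meta.index)

    target: dict = {}
    for bid in ids:
        cands = [
            other
            for other in ids
            if totals[other] > totals[bid]
            and is_homopolymer_variant(seqs[bid], seqs[other])
        ]
        if cands:
            best = max(cands, key=lambda o: (totals[o], _neg_lex(seqs[o])))
            target[bid] = best

    def root(bid):
        seen = set()
        while bid in target:
            if bid in seen:  # pragma: no cover - cannot happen, totals decrease
                break
            seen.add(bid)
            bid = target[bid]
        return bid

    counts = table.counts.copy()
    merged: dict = {}
    for bid in ids:
        if bid in target:
            src = root(bid)
            counts.loc[src] = counts.loc[src] + counts.loc[bid]
            merged[bid] = src

    keep = [bid for bid in ids if bid not in merged]
    out = ReplicateCountTable(
        table.meta.loc[keep].copy(), counts.loc[keep], table.samples.copy()
    )
    rep.merged = merged
    rep.retained = keep
    rep.retained_reads = int(out.total_reads().sum())
    rep.removed_reads = 0
    rep.check_conservation()
    return out, rep


class _neg_lex(str):
    """Inverts lexicographic order so max() prefers the *smallest* sequence."""

    def __lt__(self, other):  # noqa: D105
        return str.__gt__(self, other)


# ---------------------------------------------------------------------------
# Contaminant removal
# ---------------------------------------------------------------------------

def remove_contaminants(
    table: ReplicateCountTable, params: FilterParams | None = None
) -> tuple[ReplicateCountTable, FilterReport]:
    """Drop barcodes more abundant in negative controls than in samples.

    The comparison is between per-unit mean read counts (replicates summed
    within a unit).  Whitelisted taxa survive the comparison (but stay
    logged); blacklisted taxa are removed unconditionally.
    """
    params = params or FilterParams()
    controls = table.control_units
    if not controls:
        raise ValidationError("contaminant removal needs at least one control unit")
    samples = table.sample_units

    per_sample = table.reads_per_sample().reindex(
        columns=table.samples.index, fill_value=0
    )
    control_mean = per_sample[controls].mean(axis=1)
    sample_mean = (
        per_sample[samples].mean(axis=1) if samples else pd.Series(0.0, index=per_sample.index)
    )

    rep = _base_report(table)
    rep.control_detected_taxa = sorted(
        set(table.meta.loc[per_sample[controls].sum(axis=1) > 0, "taxon"])
    )
    keep = []
    for bid in table.meta.index:
        taxon = table.meta.at[bid, "taxon"]
        if taxon in params.blacklist:
            rep.removed.setdefault("blacklisted", []).append(bid)
        elif control_mean[bid] > sample_mean[bid]:
            if taxon in params.whitelist:
                keep.append(bid)
                rep.notes.append(
                    f"whitelisted taxon {taxon!r} ({bid}) retained despite "
                    f"control mean {control_mean[bid]:.2f} > sample mean "
                    f"{sample_mean[bid]:.2f}"
                )
            else:
                rep.removed.setdefault("contaminant", []).append(bid)
        else:
            keep.append(bid)
    return _finalize(table, keep, rep), rep


# ---------------------------------------------------------------------------
# Mammal curation
# ---------------------------------------------------------------------------

DEFAULT_MAMMAL_DISCARDS = frozenset({"Homo sapiens", "Sus scrofa"})


def curate_mammals(
    table: ReplicateCountTable,
    discard_taxa=DEFAULT_MAMMAL_DISCARDS,
    min_reads_per_replicate_detection: int = 3,
    adjacency_window: int = 1,
) -> tuple[ReplicateCountTable, FilterReport, pd.DataFrame]:
    """Curate a mammal 16S table: discard, collapse by taxon, flag sporadics.

    Off-target taxa in ``discard_taxa`` (human and pig by default — the
    former a ubiquitous laboratory contaminant, the latter indistinguishable
    from domestic pig at this locus) are removed; remaining barcodes are
    collapsed by assigned taxon (counts summed).  A (taxon, sample)
    occurrence is flagged *sporadic* — likely contamination — when the taxon
    is detected in exactly one replicate of that sample and in no
    stratigraphically adjacent sample (within ``adjacency_window`` retained
    samples on each side).
    """
    if not (table.meta["category"] == "mammal_16S").all():
        raise ValidationError("curate_mammals expects a mammal_16S table")
    discard_taxa = frozenset(discard_taxa)
    rep = _base_report(table)

    keep = []
    for bid in table.meta.index:
        if table.meta.at[bid, "taxon"] in discard_taxa:
            rep.removed.setdefault("discarded_taxon", []).append(bid)
        else:
            keep.append(bid)
    sub = table.subset_barcodes(keep)

    # collapse by taxon: counts summed, metadata from the most abundant barcode
    totals = sub.total_reads()
    groups: dict[str, list] = {}
    for bid in sub.meta.index:
        groups.setdefault(sub.meta.at[bid, "taxon"], []).append(bid)

    rows, metas = [], []
    for taxon in sorted(groups):
        bids = groups[taxon]
        lead = max(bids, key=lambda b: (totals[b], b))
        metas.append(sub.meta.loc[lead])
        rows.append(sub.counts.loc[bids].sum(axis=0))
        for bid in bids:
            if bid != lead:
                rep.merged[bid] = lead
    if rows:
        meta = pd.DataFrame(metas)
        meta.index = pd.Index([f"taxon:{t}" for t in sorted(groups)], name="id")
        counts = pd.DataFrame(rows, index=meta.index).astype(np.int64)
    else:
        meta = sub.meta.iloc[:0]
        counts = sub.counts.iloc[:0]
    collapsed = ReplicateCountTable(meta, counts, sub.samples.copy())

    # sporadic-occurrence flags on stratigraphically ordered sample units
    order = collapsed.samples.loc[collapsed.sample_units].sort_values("depth_cm")
    ordered_samples = list(order.index)
    det = _detections(collapsed.counts, min_reads_per_replicate_detection)
    det_per_sample = det.T.groupby(level=0).sum().T  # taxon-row x sample

    flags = []
    for i, sid in enumerate(ordered_samples):
        lo = max(0, i - adjacency_window)
        neighbours = [
            s for s in ordered_samples[lo : i + adjacency_window + 1] if s != sid
        ]
        for rid in collapsed.meta.index:
            n_det = int(det_per_sample.at[rid, sid]) if sid in det_per_sample else 0
            if n_det != 1:
                continue
            adjacent = any(
                s in det_per_sample and det_per_sample.at[rid, s] > 0
                for s in neighbours
            )
            if not adjacent:
                flags.append(
                    {
                        "taxon": collapsed.meta.at[rid, "taxon"],
                        "sample_id": sid,
                        "reads": int(collapsed.reads_per_sample().at[rid, sid]),
                    }
                )
    sporadic = pd.DataFrame(flags, columns=["taxon", "sample_id", "reads"])

    rep.retained = list(collapsed.meta.index)
    rep.input_barcodes = len(table.meta)
    rep.retained_reads = int(collapsed.total_reads().sum())
    rep.removed_reads = rep.input_reads - rep.retained_reads
    return collapsed, rep, sporadic


# ---------------------------------------------------------------------------
# Whole cascade
# ---------------------------------------------------------------------------

def run_cascade(
    table: ReplicateCountTable, params: FilterParams | None = None
) -> tuple[ReplicateCountTable, list[FilterReport]]:
    """length/singleton -> identity -> artifact merge -> thresholds -> controls."""
    params = params or FilterParams()
    reports = []
    out, rep = prefilter_barcodes(table, params)
    reports.append(rep)
    out, rep = merge_artifacts(out)
    reports.append(rep)
    out, rep = apply_detection_thresholds(out, params)
    reports.append(rep)
    if out.control_units:
        out, rep = remove_contaminants(out, params)
        reports.append(rep)
    return out, reports
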