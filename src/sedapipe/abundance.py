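"""Weighted PCR-replicate proportions and the Relative Abundance Index.

The Relative Abundance Index (RAI) is a per-sample, per-taxon proportional
index combining two scale-free signals::

    RAI(s, t) = prop_reads(s, t) * wtRep(s, t)

``prop_reads`` is the taxon's share of the sample's retained reads.
``wtRep`` is a detectability measure: in each PCR replicate the taxon's
reads are weighted against the best-represented retained taxon of that
replicate, and the weights are averaged over every replicate the sample
ran.  A taxon that dominates all replicates scores 1; a taxon that appears
weakly or sporadically across replicates scores near 0.  Both factors live
in [0, 1], so does RAI, and per sample the RAI values sum to at most 1.

The tables fed in here must be post-filtering: sub-detection-threshold
cells are already zeroed, so "detected" and "non-zero" coincide.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_formats import ReplicateCountTable

__all__ = ["RAIMatrix", "weighted_replicates", "rai"]


@dataclass
class RAIMatrix:
    """RAI values with the two factors they are built from.

    All three frames are unit x taxon (rows = every unit in the table,
    columns = retained barcode/taxon ids).
    """

    value: pd.DataFrame
    prop_reads: pd.DataFrame
    wtrep: pd.DataFrame
    empty_samples: list

    def for_samples(self, sample_ids) -> pd.DataFrame:
        return self.value.loc[list(sample_ids)]


def weighted_replicates(
    table: ReplicateCountTable, norm: str = "max"
) -> pd.DataFrame:
    """Per-(unit, taxon) weighted replicate proportion.

    Per replicate r the weight is ``reads(t, r) / max_t' reads(t', r)``
    (``norm='sum'`` divides by the replicate's total instead); an empty
    replicate contributes weight 0.  wtRep is the mean weight over the
    replicates the unit actually ran — a failed PCR still counts in the
    denominator, as evidence of low detectability, but a replicate column
    absent from the table (never run) does not.
    """
    if norm not in ("max", "sum"):
        raise ValueError("norm must be 'max' or 'sum'")
    units = list(table.samples.index)
    out = pd.DataFrame(0.0, index=pd.Index(units, name="sample_id"), columns=table.counts.index)
    for unit in units:
        cols = [c for c in table.counts.columns if c[0] == unit]
        if not cols:
            continue
        block = table.counts[cols].to_numpy(dtype=float)  # taxa x replicates
        denom = block.max(axis=0) if norm == "max" else block.sum(axis=0)
        weights = np.divide(
            block, denom, out=np.zeros_like(block), where=denom > 0
        )
        out.loc[unit] = weights.mean(axis=1)
    return out


def rai(table: ReplicateCountTable, norm: str = "max") -> RAIMatrix:
    """Relative Abundance Index: proportion of reads x weighted replicates."""
    wt = weighted_replicates(table, norm=norm)
    per_sample = table.reads_per_sample().T  # unit x taxon
    per_sample = per_sample.reindex(index=wt.index, columns=wt.columns, fill_value=0)
    totals = per_sample.sum(axis=1)
    prop = per_sample.div(totals.where(totals > 0, np.nan), axis=0).fillna(0.0)
    value = prop * wt
    empty = list(totals.index[totals == 0])
    return RAIMatrix(value=value, prop_reads=prop, wtrep=wt, empty_samples=empty)
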