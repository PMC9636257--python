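"""Per-sample metabarcoding quality scores, gating, and diagnostics.

Two summary scores gate samples:

* **MTQ** (technical quality): the fraction of a sample's raw reads sitting
  on barcodes with a perfect reference match in at least one database —
  how much of the signal is technically interpretable.
* **MAQ** (analytical quality): the fraction of raw reads on barcodes that
  survive the full analytical cascade — how much of the signal feeds the
  downstream analyses.

Retained barcodes are a subset of the perfect-match barcodes, so
``MAQ <= MTQ`` always.  The exact score definitions are a reconstruction
(bounded read-fractions) and are centralized here so they can be swapped
out; the gate thresholds themselves (relaxed 0.45/0.175, strict 0.9/0.9)
are the study rules, the relaxed pair having been set at the maximum scores
observed in negative controls.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .abundance import weighted_replicates
from .io_formats import ReplicateCountTable

__all__ = ["QualityGate", "compute_quality", "gate_samples", "quality_diagnostics"]


@dataclass
class QualityGate:
    relaxed_mtq: float = 0.45
    relaxed_maq: float = 0.175
    strict_mtq: float = 0.9
    strict_maq: float = 0.9

    def __post_init__(self) -> None:
        if self.strict_mtq < self.relaxed_mtq or self.strict_maq < self.relaxed_maq:
            raise ValueError("strict thresholds must dominate relaxed thresholds")


def compute_quality(
    raw_table: ReplicateCountTable,
    retained_table: ReplicateCountTable,
    terrestrial_taxa=None,
) -> pd.DataFrame:
    """Quality metrics per sample unit.

    ``terrestrial_taxa`` restricts the 'proportion terrestrial' metric to a
    taxon set; by default every retained taxon counts as terrestrial (the
    retained community of an alpine lake catchment is terrestrial plants).
    Samples with zero raw reads get MTQ = MAQ = 0 and ``flagged_empty``.
    """
    missing = set(retained_table.samples.index) - set(raw_table.samples.index)
    if missing:
        raise ValueError(f"samples absent from raw table: {sorted(missing)}")

    raw_per_sample = raw_table.reads_per_sample()  # barcode x unit
    perfect = raw_table.best_identity.fillna(0.0) >= 1.0
    retained_ids = [b for b in retained_table.meta.index if b in raw_per_sample.index]
    if terrestrial_taxa is None:
        terrestrial_ids = list(retained_table.meta.index)
    else:
        terrestrial_taxa = set(terrestrial_taxa)
        terrestrial_ids = [
            b
            for b in retained_table.meta.index
            if retained_table.meta.at[b, "taxon"] in terrestrial_taxa
        ]

    seq_len = raw_table.meta["sequence"].str.len().to_numpy(dtype=float)
    wt = weighted_replicates(retained_table)
    retained_per_sample = retained_table.reads_per_sample()

    rows = []
    for sid in raw_table.sample_units:
        raw_reads = raw_per_sample[sid] if sid in raw_per_sample else pd.Series(
            0, index=raw_per_sample.index
        )
        total = int(raw_reads.sum())
        if total > 0:
            mtq = float(raw_reads[perfect].sum()) / total
            maq = float(raw_reads.loc[retained_ids].sum()) / total
            mean_len = float(np.average(seq_len, weights=raw_reads.to_numpy()))
        else:
            mtq = maq = mean_len = 0.0
        if sid in retained_per_sample.columns:
            detected = retained_per_sample.index[retained_per_sample[sid] > 0]
        else:
            detected = []
        mean_wtrep = float(wt.loc[sid, detected].mean()) if len(detected) else 0.0
        terr_reads = (
            float(retained_per_sample.loc[terrestrial_ids, sid].sum())
            if sid in retained_per_sample.columns
            else 0.0
        )
        ret_total = (
            float(retained_per_sample[sid].sum())
            if sid in retained_per_sample.columns
            else 0.0
        )
        prop_terr = terr_reads / ret_total if ret_total > 0 else 0.0
        rows.append(
            {
                "sample_id": sid,
                "total_raw_reads": total,
                "mean_barcode_length": mean_len,
                "mean_wtRep": mean_wtrep,
                "prop_terrestrial": prop_terr,
                "MTQ": mtq,
                "MAQ": maq,
                "flagged_empty": total == 0,
            }
        )
    out = pd.DataFrame(rows).set_index("sample_id")
    if ((out["MAQ"] - out["MTQ"]) > 1e-12).any():
        raise AssertionError("MAQ exceeded MTQ: retained set not a subset of perfect matches")
    return out


def gate_samples(metrics: pd.DataFrame, gate: QualityGate | None = None) -> dict:
    """Partition samples by the relaxed and strict quality gates."""
    gate = gate or QualityGate()
    relaxed = set(
        metrics.index[(metrics["MTQ"] >= gate.relaxed_mtq) & (metrics["MAQ"] >= gate.relaxed_maq)]
    )
    strict = set(
        metrics.index[(metrics["MTQ"] >= gate.strict_mtq) & (metrics["MAQ"] >= gate.strict_maq)]
    )
    assert strict <= relaxed
    return {
        "relaxed_set": relaxed,
        "strict_set": strict,
        "removed_set": set(metrics.index) - relaxed,
    }


def quality_diagnostics(
    metrics: pd.DataFrame, ages: pd.Series, richness: pd.Series, alpha: float = 0.05
) -> pd.DataFrame:
    """Correlate each quality metric with sample age and plant richness.

    Pearson and Spearman coefficients with two-sided p-values, flagged at
    ``alpha`` (diagnostics only — no multiplicity correction).  Constant
    metrics yield NaN coefficients and are marked degenerate.
    """
    targets = {"age": ages, "richness": richness}
    metric_cols = [
        "total_raw_reads",
        "mean_barcode_length",
        "mean_wtRep",
        "prop_terrestrial",
        "MTQ",
        "MAQ",
    ]
    rows = []
    for mcol in metric_cols:
        x = metrics[mcol]
        for tname, t in targets.items():
            common = x.index.intersection(t.index)
            xv = x.loc[common].to_numpy(dtype=float)
            tv = t.loc[common].to_numpy(dtype=float)
            degenerate = len(common) < 3 or np.ptp(xv) == 0 or np.ptp(tv) == 0
            if degenerate:
                pr = pp = sr = sp = np.nan
            else:
                pr, pp = stats.pearsonr(xv, tv)
                sr, sp = stats.spearmanr(xv, tv)
            rows.append(
                {
                    "metric": mcol,
                    "against": tname,
                    "pearson_r": pr,
                    "pearson_p": pp,
                    "spearman_r": sr,
                    "spearman_p": sp,
                    "significant": (not degenerate) and min(pp, sp) < alpha,
                    "degenerate": degenerate,
                }
            )
    return pd.DataFrame(rows)
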