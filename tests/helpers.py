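"""Construction helpers and independent brute-force oracles for the tests.

The oracles deliberately re-evaluate rules with naive, loop-based code that
shares nothing with the package implementations.
"""

from __future__ import annotations

import itertools

import numpy as np
import pandas as pd

from sedapipe.io_formats import ReplicateCountTable


def make_table(barcodes, units, category="plant_trnL"):
    """Build a ReplicateCountTable from plain dicts.

    barcodes: list of dicts with keys ``id``, ``sequence``, optional
    ``taxon`` / ``identity`` (float), and ``counts`` = {unit_id: [reads per
    replicate]}.  units: {unit_id: unit_type} or {unit_id: (unit_type,
    depth_cm, age_calBP)}.
    """
    unit_rows = {}
    for uid, spec in units.items():
        if isinstance(spec, str):
            unit_rows[uid] = (spec, np.nan, np.nan)
        else:
            unit_rows[uid] = tuple(spec)
    samples = pd.DataFrame(
        [(t, d, a) for (t, d, a) in unit_rows.values()],
        index=pd.Index(list(unit_rows), name="sample_id"),
        columns=["unit_type", "depth_cm", "age_calBP"],
    )

    columns = []
    for b in barcodes:
        for uid, reps in b.get("counts", {}).items():
            for r in range(1, len(reps) + 1):
                if (uid, r) not in columns:
                    columns.append((uid, r))
    columns.sort(key=lambda c: (list(unit_rows).index(c[0]), c[1]))
    col_index = pd.MultiIndex.from_tuples(columns, names=["sample_id", "replicate"])

    meta_rows, count_rows, ids = [], [], []
    for b in barcodes:
        ids.append(b["id"])
        meta_rows.append(
            {
                "sequence": b["sequence"],
                "category": category,
                "taxon": b.get("taxon", b["id"]),
                "rank": b.get("rank", "species"),
                "best_identity:refdb": float(b.get("identity", 1.0)),
            }
        )
        row = np.zeros(len(columns), dtype=np.int64)
        for uid, reps in b.get("counts", {}).items():
            for r, v in enumerate(reps, start=1):
                row[columns.index((uid, r))] = int(v)
        count_rows.append(row)
    meta = pd.DataFrame(meta_rows, index=pd.Index(ids, name="id"))
    counts = pd.DataFrame(np.vstack(count_rows), index=meta.index, columns=col_index)
    return ReplicateCountTable(meta=meta, counts=counts, samples=samples)


_BASES = "ACGT"


def random_filter_table(rng: np.random.Generator, max_barcodes=50):
    """Random table exercising every retention rule (for oracle tests)."""
    n_b = int(rng.integers(3, max_barcodes + 1))
    n_s = int(rng.integers(2, 5))
    n_c = int(rng.integers(1, 3))
    R = int(rng.integers(2, 5))
    units = {f"S{i}": ("sample", 10.0 * (i + 1), 160.0 * (i + 1)) for i in range(n_s)}
    units.update({f"N{i}": "extraction_control" for i in range(n_c)})
    barcodes = []
    for b in range(n_b):
        length = int(rng.integers(5, 25))
        seq = "".join(rng.choice(list(_BASES), length))
        identity = float(rng.choice([1.0, 1.0, 0.98, 0.9]))
        counts = {}
        for uid in units:
            if rng.random() < 0.25 and uid.startswith("S"):
                continue  # unit never amplified for this barcode
            lam = float(rng.choice([0.2, 1.0, 4.0, 40.0]))
            if uid.startswith("N"):
                lam = float(rng.choice([0.0, 0.3, 30.0]))
            counts[uid] = list(rng.poisson(lam, R))
        barcodes.append(
            {
                "id": f"b{b:03d}",
                "sequence": seq,
                "taxon": f"Taxon{b % max(2, n_b // 2)}",
                "identity": identity,
                "counts": counts,
            }
        )
    return make_table(barcodes, units)


# ---------------------------------------------------------------------------
# Independent brute-force rule evaluators
# ---------------------------------------------------------------------------

def brute_filter(table, params):
    """Naive per-barcode re-evaluation of length/singleton/identity/threshold
    rules; returns (retained ids, zeroed counts frame)."""
    retained = []
    for bid in table.meta.index:
        seq = table.meta.at[bid, "sequence"]
        ident = max(
            table.meta.at[bid, c]
            for c in table.meta.columns
            if c.startswith("best_identity:")
        )
        total = 0
        detections = 0
        for col in table.counts.columns:
            v = int(table.counts.at[bid, col])
            total += v
            if v >= params.min_reads_per_replicate_detection:
                detections += 1
        ok = len(seq) >= params.min_barcode_length
        ok = ok and not (params.drop_singletons and total <= 1)
        ok = ok and ident >= params.min_identity
        ok = ok and total >= params.min_total_reads
        ok = ok and detections >= params.min_total_replicates
        if ok:
            retained.append(bid)
    zeroed = table.counts.loc[retained].copy()
    for bid in retained:
        for col in zeroed.columns:
            if zeroed.at[bid, col] < params.min_reads_per_replicate_detection:
                zeroed.at[bid, col] = 0
    return retained, zeroed


def brute_runs(seq):
    return [(ch, len(list(g))) for ch, g in itertools.groupby(seq)]


def brute_is_variant(a, b):
    ra, rb = brute_runs(a), brute_runs(b)
    if a == b or len(ra) != len(rb):
        return False
    if any(x[0] != y[0] for x, y in zip(ra, rb)):
        return False
    return sum(x[1] != y[1] for x, y in zip(ra, rb)) == 1


def brute_merge(table):
    """Independent homopolymer merge: returns {variant id: final source id}."""
    totals = {bid: int(table.counts.loc[bid].sum()) for bid in table.meta.index}
    seq = {bid: table.meta.at[bid, "sequence"] for bid in table.meta.index}
    direct = {}
    for bid in table.meta.index:
        cands = [
            o
            for o in table.meta.index
            if totals[o] > totals[bid] and brute_is_variant(seq[bid], seq[o])
        ]
        if cands:
            best_total = max(totals[o] for o in cands)
            tied = sorted([o for o in cands if totals[o] == best_total], key=lambda o: seq[o])
            direct[bid] = tied[0]
    final = {}
    for bid, tgt in direct.items():
        while tgt in direct:
            tgt = direct[tgt]
        final[bid] = tgt
    return final


def brute_contaminants(table, whitelist=frozenset(), blacklist=frozenset()):
    """Independent control-vs-sample mean comparison; returns removed ids."""
    controls = [
        u
        for u in table.samples.index
        if table.samples.at[u, "unit_type"] in ("extraction_control", "pcr_control")
    ]
    samples = [u for u in table.samples.index if table.samples.at[u, "unit_type"] == "sample"]
    removed = []
    for bid in table.meta.index:
        taxon = table.meta.at[bid, "taxon"]
        if taxon in blacklist:
            removed.append(bid)
            continue
        cm = np.mean(
            [sum(int(table.counts.at[bid, c]) for c in table.counts.columns if c[0] == u) for u in controls]
        )
        sm = (
            np.mean(
                [sum(int(table.counts.at[bid, c]) for c in table.counts.columns if c[0] == u) for u in samples]
            )
            if samples
            else 0.0
        )
        if cm > sm and taxon not in whitelist:
            removed.append(bid)
    return removed
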