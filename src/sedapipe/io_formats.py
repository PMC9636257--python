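"""Tables, file dialects, and proxy-series alignment.

Everything the pipeline reads or writes is plain TSV (UTF-8, '.' decimal).
The central object is :class:`ReplicateCountTable`: one row per metabarcode
(amplicon sequence variant), one count column per (sample, PCR replicate)
pair.  Replicate structure is explicit because replicate-level detection
patterns carry the abundance signal the downstream index exploits.

Dialect
-------
Barcode table columns: ``id``, ``sequence``, ``category``, ``taxon``,
``rank``, one ``best_identity:<db>`` column per reference database, then one
``sample:<sample_id>:<replicate>`` column per PCR replicate.  A sample that
ran fewer PCRs simply has fewer columns; absent replicates are *absent*, not
zero.  Unit types (sample vs negative control) live in a sidecar
sample-metadata TSV with columns ``sample_id``, ``unit_type``, ``depth_cm``,
``age_calBP``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "FormatError",
    "ValidationError",
    "UNIT_TYPES",
    "BELT_VOCABULARY",
    "GROWTH_FORMS",
    "ReplicateCountTable",
    "ProxySeries",
    "read_metabarcoding_table",
    "write_metabarcoding_table",
    "read_sample_metadata",
    "write_sample_metadata",
    "read_trait_table",
    "write_trait_table",
    "compute_influx",
    "align_nearest",
    "align_drivers",
]


class FormatError(ValueError):
    """A file does not conform to the declared dialect."""


class ValidationError(ValueError):
    """An in-memory table violates its invariants."""


UNIT_TYPES = ("sample", "extraction_control", "pcr_control")
CONTROL_UNIT_TYPES = ("extraction_control", "pcr_control")

#: Elevational vegetation belts, ordered from high to low elevation.
BELT_VOCABULARY = (
    "Alpine",
    "Subalpine-Alpine",
    "Subalpine",
    "Montane-Subalpine",
    "Montane",
    "Colline-Montane",
    "Colline",
)

GROWTH_FORMS = ("tree", "shrub", "dwarf_shrub", "forb", "graminoid", "other")

_META_COLUMNS = ("sequence", "category", "taxon", "rank")
_IDENTITY_PREFIX = "best_identity:"
_SAMPLE_PREFIX = "sample:"


@dataclass
class ReplicateCountTable:
    """Barcode x (sample, replicate) read counts with assignment metadata.

    Attributes
    ----------
    meta:
        One row per barcode (index = barcode id) with columns ``sequence``,
        ``category``, ``taxon``, ``rank`` and one ``best_identity:<db>``
        column per reference database (fractions in [0, 1]; NaN = no hit).
    counts:
        Integer reads, index = barcode id, columns = MultiIndex
        ``(sample_id, replicate)`` with replicate indices starting at 1.
    samples:
        Index = sample_id; columns ``unit_type``, ``depth_cm``, ``age_calBP``.
    """

    meta: pd.DataFrame
    counts: pd.DataFrame
    samples: pd.DataFrame

    def __post_init__(self) -> None:
        self.validate()

    # -- invariants -------------------------------------------------------
    def validate(self) -> None:
        if not self.meta.index.equals(self.counts.index):
            raise ValidationError("meta and counts must index the same barcodes")
        if self.meta.index.has_duplicates:
            raise ValidationError("duplicate barcode ids")
        for col in _META_COLUMNS:
            if col not in self.meta.columns:
                raise ValidationError(f"meta is missing column {col!r}")
        if not self.identity_columns:
            raise ValidationError("meta needs at least one best_identity:<db> column")
        if (self.meta["sequence"].astype(str).str.len() == 0).any():
            raise ValidationError("empty barcode sequence")
        if self.counts.columns.nlevels != 2:
            raise ValidationError("counts columns must be (sample_id, replicate)")
        vals = self.counts.to_numpy()
        if vals.size and (not np.issubdtype(vals.dtype, np.integer)):
            if not np.all(np.equal(np.mod(vals, 1), 0)):
                raise ValidationError("counts must be integral")
        if vals.size and (vals < 0).any():
            raise ValidationError("counts must be non-negative")
        if self.samples.index.has_duplicates:
            raise ValidationError("duplicate sample ids")
        unknown = set(self.counts.columns.get_level_values(0)) - set(self.samples.index)
        if unknown:
            raise ValidationError(f"count columns for unknown samples: {sorted(unknown)}")
        bad_unit = set(self.samples["unit_type"]) - set(UNIT_TYPES)
        if bad_unit:
            raise ValidationError(f"unknown unit_type values: {sorted(bad_unit)}")

    # -- derived views ----------------------------------------------------
    @property
    def identity_columns(self) -> list[str]:
        return [c for c in self.meta.columns if c.startswith(_IDENTITY_PREFIX)]

    @property
    def best_identity(self) -> pd.Series:
        """Maximum best-match identity across reference databases."""
        return self.meta[self.identity_columns].max(axis=1)

    @property
    def sample_units(self) -> list[str]:
        return list(self.samples.index[self.samples["unit_type"] == "sample"])

    @property
    def control_units(self) -> list[str]:
        return list(
            self.samples.index[self.samples["unit_type"].isin(CONTROL_UNIT_TYPES)]
        )

    def counts_for_units(self, units) -> pd.DataFrame:
        cols = [c for c in self.counts.columns if c[0] in set(units)]
        return self.counts[cols]

    def reads_per_sample(self) -> pd.DataFrame:
        """Barcode x sample totals, replicates summed."""
        return self.counts.T.groupby(level=0).sum().T

    def total_reads(self) -> pd.Series:
        """Total reads per barcode across every unit and replicate."""
        return self.counts.sum(axis=1)

    def replicates_of(self, sample_id: str) -> list[int]:
        return sorted(
            r for (s, r) in self.counts.columns if s == sample_id
        )

    def copy(self) -> "ReplicateCountTable":
        return ReplicateCountTable(
            self.meta.copy(), self.counts.copy(), self.samples.copy()
        )

    def subset_barcodes(self, ids) -> "ReplicateCountTable":
        ids = list(ids)
        return ReplicateCountTable(
            self.meta.loc[ids].copy(), self.counts.loc[ids].copy(), self.samples.copy()
        )


@dataclass
class ProxySeries:
    """A depth/age-indexed environmental series (one proxy)."""

    proxy_name: str
    units: str
    depth_cm: np.ndarray
    age_calBP: np.ndarray
    value: np.ndarray

    def __post_init__(self) -> None:
        self.depth_cm = np.asarray(self.depth_cm, dtype=float)
        self.age_calBP = np.asarray(self.age_calBP, dtype=float)
        self.value = np.asarray(self.value, dtype=float)
        n = len(self.value)
        if len(self.depth_cm) != n or len(self.age_calBP) != n:
            raise ValidationError("depth, age and value must have equal length")
        if np.isnan(self.value).any() or np.isnan(self.age_calBP).any():
            raise ValidationError("proxy series may not contain NaN")
        order = np.argsort(self.depth_cm, kind="stable")
        if np.any(np.diff(self.age_calBP[order]) < 0):
            raise ValidationError("ages must be monotone non-decreasing with depth")

    def __len__(self) -> int:
        return len(self.value)


# ---------------------------------------------------------------------------
# Metabarcoding TSV dialect
# ---------------------------------------------------------------------------

def _parse_sample_column(name: str, lineinfo: str) -> tuple[str, int]:
    parts = name.split(":")
    if len(parts) != 3 or parts[0] != "sample":
        raise FormatError(f"{lineinfo}: malformed sample column {name!r}")
    try:
        rep = int(parts[2])
    except ValueError as exc:
        raise FormatError(f"{lineinfo}: non-integer replicate in {name!r}") from exc
    if rep < 1:
        raise FormatError(f"{lineinfo}: replicate index must be >= 1 in {name!r}")
    return parts[1], rep


def read_sample_metadata(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    for col in ("sample_id", "unit_type"):
        if col not in df.columns:
            raise FormatError(f"sample metadata missing mandatory column {col!r}")
    for col in ("depth_cm", "age_calBP"):
        if col not in df.columns:
            df[col] = np.nan
    df = df.set_index("sample_id")
    bad = set(df["unit_type"]) - set(UNIT_TYPES)
    if bad:
        raise FormatError(f"unknown unit_type values: {sorted(bad)}")
    return df[["unit_type", "depth_cm", "age_calBP"]]


def write_sample_metadata(samples: pd.DataFrame, path) -> None:
    out = samples.reset_index()
    out.columns = ["sample_id", "unit_type", "depth_cm", "age_calBP"]
    out.to_csv(path, sep="\t", index=False)


def read_metabarcoding_table(path, sample_metadata) -> ReplicateCountTable:
    """Read an OBITools-style barcode count TSV plus its sample sidecar.

    ``sample_metadata`` may be a path to the sidecar TSV or a pre-loaded
    DataFrame indexed by sample_id.  Malformed cells are reported with the
    1-based data line number.
    """
    if not isinstance(sample_metadata, pd.DataFrame):
        sample_metadata = read_sample_metadata(sample_metadata)
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    for col in ("id", "sequence", "taxon", "rank"):
        if col not in df.columns:
            raise FormatError(f"missing mandatory column {col!r}")
    if "category" not in df.columns:
        df["category"] = ""
    id_cols = [c for c in df.columns if c.startswith(_IDENTITY_PREFIX)]
    if not id_cols:
        raise FormatError("no best_identity:<db> column found")
    sample_cols = [c for c in df.columns if c.startswith(_SAMPLE_PREFIX)]
    if not sample_cols:
        raise FormatError("no sample:<sid>:<rep> count columns found")

    parsed = [_parse_sample_column(c, "header") for c in sample_cols]
    counts = np.zeros((len(df), len(sample_cols)), dtype=np.int64)
    for j, col in enumerate(sample_cols):
        for i, raw in enumerate(df[col]):
            line = i + 2  # header is line 1
            try:
                v = int(raw)
            except ValueError as exc:
                raise FormatError(
                    f"line {line}, column {col!r}: non-integer count {raw!r}"
                ) from exc
            if v < 0:
                raise FormatError(
                    f"line {line}, column {col!r}: negative count {v}"
                )
            counts[i, j] = v

    meta = df[["sequence", "category", "taxon", "rank"]].copy()
    for c in id_cols:
        meta[c] = pd.to_numeric(df[c].replace("", np.nan))
        bad = meta[c].dropna()
        if ((bad < 0) | (bad > 1)).any():
            raise FormatError(f"column {c!r}: identity outside [0, 1]")
    meta.index = pd.Index(df["id"], name="id")
    if meta.index.has_duplicates:
        dup = meta.index[meta.index.duplicated()][0]
        raise FormatError(f"duplicate barcode id {dup!r}")

    columns = pd.MultiIndex.from_tuples(parsed, names=["sample_id", "replicate"])
    count_df = pd.DataFrame(counts, index=meta.index, columns=columns)
    return ReplicateCountTable(meta=meta, counts=count_df, samples=sample_metadata)


def write_metabarcoding_table(table: ReplicateCountTable, path) -> None:
    """Write the barcode TSV (sidecar written separately).

    ``read_metabarcoding_table`` on the result reproduces the table
    bit-exactly (integers verbatim, identities via shortest round-trip
    ``repr``).
    """
    id_cols = table.identity_columns
    data = {"id": table.meta.index.to_numpy()}
    for c in ("sequence", "category", "taxon", "rank"):
        data[c] = table.meta[c].to_numpy()
    for c in id_cols:
        data[c] = [
            "" if (isinstance(v, float) and math.isnan(v)) else repr(float(v))
            for v in table.meta[c]
        ]
    for (sid, rep) in table.counts.columns:
        data[f"sample:{sid}:{rep}"] = table.counts[(sid, rep)].to_numpy()
    pd.DataFrame(data).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Trait tables
# ---------------------------------------------------------------------------

def read_trait_table(path, belt_vocabulary=BELT_VOCABULARY) -> pd.DataFrame:
    """Read a species trait table (indicator source values).

    Columns ``species``, ``belt``, ``pastoral_flag``, ``arable_flag``,
    ``growth_form`` are mandatory; ``belt`` may be empty (species without a
    narrow elevational preference) but any non-empty label must come from the
    controlled vocabulary.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    required = ("species", "belt", "pastoral_flag", "arable_flag", "growth_form")
    for col in required:
        if col not in df.columns:
            raise FormatError(f"trait table missing column {col!r}")
    if df["species"].duplicated().any():
        dup = df["species"][df["species"].duplicated()].iloc[0]
        raise FormatError(f"duplicate species {dup!r}")
    bad = set(df["belt"]) - set(belt_vocabulary) - {""}
    if bad:
        raise FormatError(f"unknown belt label(s): {sorted(bad)}")
    bad_gf = set(df["growth_form"]) - set(GROWTH_FORMS) - {""}
    if bad_gf:
        raise FormatError(f"unknown growth_form value(s): {sorted(bad_gf)}")

    def to_bool(s: pd.Series) -> pd.Series:
        mapping = {"true": True, "false": False, "1": True, "0": False, "": False}
        out = s.str.strip().str.lower().map(mapping)
        if out.isna().any():
            raw = s[out.isna()].iloc[0]
            raise FormatError(f"non-boolean flag value {raw!r}")
        return out

    df = df.set_index("species")
    df["pastoral_flag"] = to_bool(df["pastoral_flag"])
    df["arable_flag"] = to_bool(df["arable_flag"])
    return df[["belt", "pastoral_flag", "arable_flag", "growth_form"]]


def write_trait_table(traits: pd.DataFrame, path) -> None:
    out = traits.reset_index().rename(columns={traits.index.name or "index": "species"})
    out.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Influx conversion and proxy alignment
# ---------------------------------------------------------------------------

def compute_influx(
    count: float,
    spike_added: float,
    spike_counted: float,
    sample_volume_cm3: float,
    deposition_time_yr_per_cm: float,
    slice_thickness_cm: float = 1.0,
) -> float:
    """Convert a microscopy particle count to influx (particles cm^-2 yr^-1).

    The exotic-spike (Lycopodium tablet) calibration gives the concentration
    ``count * spike_added / spike_counted / sample_volume_cm3`` in particles
    per cm^3; dividing by the deposition time of one cm of sediment and
    multiplying by the counted slice thickness yields the influx::

        influx = (count * spike_added / spike_counted) / sample_volume_cm3
                 / deposition_time_yr_per_cm * slice_thickness_cm
    """
    if spike_counted <= 0:
        raise ValueError("spike_counted must be > 0 (concentration undefined)")
    if sample_volume_cm3 <= 0 or deposition_time_yr_per_cm <= 0:
        raise ValueError("sample volume and deposition time must be > 0")
    concentration = count * spike_added / spike_counted / sample_volume_cm3
    return concentration / deposition_time_yr_per_cm * slice_thickness_cm


def align_nearest(proxy: ProxySeries, target_ages) -> np.ndarray:
    """Nearest-neighbour value lookup on the age axis.

    Each target age receives the value of the proxy point with the smallest
    absolute age difference; an exact tie goes to the *younger* (smaller age)
    point, so the rule is deterministic.
    """
    if len(proxy) == 0:
        raise ValueError("empty proxy series")
    targets = np.asarray(target_ages, dtype=float)
    if not np.isfinite(targets).all():
        raise ValueError("target ages must be finite")
    order = np.argsort(proxy.age_calBP, kind="stable")
    ages = proxy.age_calBP[order]
    values = proxy.value[order]
    # among duplicate ages keep the first in depth order (identical distance)
    idx = np.searchsorted(ages, targets)
    idx = np.clip(idx, 0, len(ages) - 1)
    left = np.clip(idx - 1, 0, len(ages) - 1)
    d_right = np.abs(ages[idx] - targets)
    d_left = np.abs(targets - ages[left])
    # tie (d_left == d_right) -> younger point = smaller age = left neighbour
    use_left = (idx > 0) & (d_left <= d_right)
    chosen = np.where(use_left, left, idx)
    return values[chosen]


def align_drivers(
    proxies: dict[str, ProxySeries],
    sample_ids,
    sample_ages,
) -> pd.DataFrame:
    """Build the per-sample covariate table by nearest-age interpolation."""
    ages = np.asarray(sample_ages, dtype=float)
    data = {"age_calBP": ages}
    for name, proxy in proxies.items():
        data[name] = align_nearest(proxy, ages)
    return pd.DataFrame(data, index=pd.Index(sample_ids, name="sample_id"))
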