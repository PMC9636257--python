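"""End-to-end orchestration: filter -> quality -> RAI -> indicators ->
zonation -> temperature reconstruction -> driver analysis.

Every stage reads and writes plain files under the run's output directory,
so no stage can mutate another's in-memory state; a JSON manifest records
versions, seeds, per-stage row counts and the configuration hash.  The
orchestrator runs equally from generated synthetic inputs (the default,
with ground truth written alongside) or from user-supplied TSVs.
"""

from __future__ import annotations

import hashlib
import json
import sys
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .abundance import rai
from .drivers import (
    forward_select,
    gam_poisson,
    piecewise_sem,
    pillai_test,
    rda,
    transform_fourth_root,
)
from .filtering import FilterParams, run_cascade
from .indicators import (
    activity_series,
    belt_profile,
    functional_groups,
    grade_indicators,
    richness,
)
from .io_formats import (
    align_drivers,
    read_metabarcoding_table,
    read_trait_table,
    write_metabarcoding_table,
    write_sample_metadata,
)
from .sample_quality import QualityGate, compute_quality, gate_samples
from .synthetic_data import (
    SimulationConfig,
    barcode_species_map,
    simulate_calibration,
    simulate_community,
    simulate_drivers,
)
from .transfer_function import bootstrap_validate, wapls_fit, wapls_predict
from .sample_quality import quality_diagnostics
from .zonation import zonate

__all__ = ["RunConfig", "run_pipeline", "DEFAULT_SEM_DAG"]

#: Default path diagram for the driver analysis: climate and fire shape
#: richness directly and indirectly through grazers.
DEFAULT_SEM_DAG = [
    ("precipitation_kg_m2_month", "richness"),
    ("charcoal_influx", "richness"),
    ("precipitation_kg_m2_month", "spore_influx"),
    ("charcoal_influx", "spore_influx"),
    ("spore_influx", "richness"),
    ("temperature_C", "richness"),
]


@dataclass
class RunConfig:
    """Validated configuration of a full pipeline run."""

    seed: int
    output_dir: str = "run_output"
    # input paths; None means "simulate"
    barcode_table: str | None = None
    sample_metadata: str | None = None
    trait_table: str | None = None
    barcode_species: str | None = None  # TSV: barcode_id, species (;-separated)
    simulation: dict = field(default_factory=dict)
    filter_params: dict = field(default_factory=dict)
    gate: dict = field(default_factory=dict)
    wtrep_norm: str = "max"
    belt_mode: str = "rai"
    zonation_transform: str = "fourth_root"
    wapls_components: int = 2
    n_boot: int = 9999
    n_perm: int = 999
    sem_dag: list = field(default_factory=lambda: list(DEFAULT_SEM_DAG))

    _KNOWN = None

    def __post_init__(self) -> None:
        if self.wtrep_norm not in ("max", "sum"):
            raise ValueError("wtrep_norm must be 'max' or 'sum'")
        if self.belt_mode not in ("rai", "count"):
            raise ValueError("belt_mode must be 'rai' or 'count'")
        if self.n_boot < 1 or self.n_perm < 1:
            raise ValueError("n_boot and n_perm must be >= 1")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = set(cls.__dataclass_fields__)
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown configuration keys: {sorted(unknown)}")
        return cls(**raw)

    def config_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _write(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t")


def run_pipeline(config: RunConfig, log=sys.stderr) -> dict:
    """Execute every stage; returns the manifest (also written to disk).

    Any stage failure is re-raised annotated with the stage name so the
    cause surfaces verbatim.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "seed": config.seed,
        "config_hash": config.config_hash(),
        "stages": {},
    }

    def stage(name):
        print(f"[sedapipe] stage: {name}", file=log)
        return name

    try:
        name = stage("inputs")
        sim_cfg = SimulationConfig(seed=config.seed, **config.simulation)
        if config.barcode_table is None:
            proxies = simulate_drivers(sim_cfg)
            sample_ids = [f"S{i:03d}" for i in range(sim_cfg.n_samples)]
            ages = [(i + 1) * sim_cfg.depth_step_cm * sim_cfg.years_per_cm for i in range(sim_cfg.n_samples)]
            driver_vals = align_drivers(proxies, sample_ids, ages).drop(columns="age_calBP")
            raw, traits, truth = simulate_community(sim_cfg, driver_values=driver_vals)
            write_metabarcoding_table(raw, out / "raw_barcodes.tsv")
            write_sample_metadata(raw.samples, out / "samples.tsv")
            b2s = barcode_species_map(traits)
        else:
            raw = read_metabarcoding_table(config.barcode_table, config.sample_metadata)
            traits = read_trait_table(config.trait_table) if config.trait_table else None
            truth = None
            proxies = simulate_drivers(sim_cfg)  # driver series must be supplied upstream
            b2s = {}
            if config.barcode_species:
                m = pd.read_csv(config.barcode_species, sep="\t", dtype=str)
                b2s = {
                    r.barcode_id: [s for s in str(r.species).split(";") if s]
                    for r in m.itertuples()
                }
        manifest["stages"][name] = {"barcodes": len(raw.meta), "units": len(raw.samples)}

        name = stage("filter")
        params = FilterParams(**config.filter_params)
        retained, reports = run_cascade(raw, params)
        write_metabarcoding_table(retained, out / "retained_barcodes.tsv")
        with open(out / "filter_report.json", "w") as fh:
            json.dump([r.to_dict() for r in reports], fh, indent=1)
        manifest["stages"][name] = {"retained_barcodes": len(retained.meta)}

        name = stage("quality")
        metrics = compute_quality(raw, retained)
        gates = gate_samples(metrics, QualityGate(**config.gate))
        _write(metrics, out / "quality_metrics.tsv")
        with open(out / "quality_gate.json", "w") as fh:
            json.dump({k: sorted(v) for k, v in gates.items()}, fh, indent=1)
        manifest["stages"][name] = {k: len(v) for k, v in gates.items()}

        name = stage("rai")
        rai_res = rai(retained, norm=config.wtrep_norm)
        relaxed = sorted(gates["relaxed_set"])
        strict = sorted(gates["strict_set"])
        rai_relaxed = rai_res.value.loc[relaxed]
        _write(rai_res.value, out / "rai.tsv")
        _write(rai_res.wtrep, out / "wtrep.tsv")
        _write(rai_res.prop_reads, out / "prop_reads.tsv")
        manifest["stages"][name] = {"samples": len(relaxed), "taxa": rai_res.value.shape[1]}

        name = stage("indicators")
        rich = richness(retained).reindex(relaxed).fillna(0).astype(int)
        results_ind = {}
        if traits is not None and b2s:
            assignments = grade_indicators(
                {bid: b2s.get(bid, []) for bid in retained.meta.index}, traits
            )
            belts = belt_profile(rai_relaxed, assignments, mode=config.belt_mode)
            acts = activity_series(rai_relaxed, assignments)
            _write(belts, out / "belt_profile.tsv")
            _write(acts, out / "activity.tsv")
            results_ind = {
                "optimal_belt": sum(a.is_optimal("belt") for a in assignments.values()),
                "optimal_pastoral": sum(
                    a.is_optimal("pastoral") and a.value.get("pastoral") for a in assignments.values()
                ),
            }
        rich.to_frame("richness").to_csv(out / "richness.tsv", sep="\t")
        manifest["stages"][name] = {**results_ind, "richness_samples": len(rich)}

        name = stage("zones")
        zres = zonate(
            rai_relaxed.to_numpy(),
            ages=retained.samples.loc[relaxed, "age_calBP"].to_numpy(),
            transform=config.zonation_transform,
        )
        with open(out / "zones.json", "w") as fh:
            json.dump(
                {
                    "n_significant_zones": zres.n_significant_zones,
                    "boundaries": zres.boundaries,
                    "boundary_ages": zres.boundary_ages,
                    "total_dispersion": zres.total_dispersion,
                },
                fh,
                indent=1,
            )
        manifest["stages"][name] = {"n_zones": zres.n_significant_zones}

        name = stage("reconstruct")
        cal_df, T_cal, fos_df, T_fos = simulate_calibration(sim_cfg)
        model = wapls_fit(cal_df, T_cal, n_components=config.wapls_components)
        recon = wapls_predict(model, fos_df)
        boot = bootstrap_validate(
            cal_df,
            T_cal,
            fossil=fos_df,
            n_components=config.wapls_components,
            n_boot=config.n_boot,
            seed=config.seed,
        )
        pd.DataFrame(
            {"predicted_T": recon, "eSEP": boot.get("eSEP", np.nan)}, index=fos_df.index
        ).to_csv(out / "reconstruction.tsv", sep="\t")
        manifest["stages"][name] = {
            "RMSEP": boot["RMSEP"],
            "r2": boot["r2"],
            "apparent_r2": model.apparent_r2,
        }

        name = stage("drivers")
        ages_rel = retained.samples.loc[relaxed, "age_calBP"]
        X = align_drivers(proxies, relaxed, ages_rel.to_numpy()).drop(columns="age_calBP")
        Y = transform_fourth_root(rai_relaxed)
        sel = forward_select(Y, X, n_perm=config.n_perm, seed=config.seed)
        drv = {"selected": sel["selected"]}
        if sel["selected"]:
            r = rda(Y, X[sel["selected"]])
            drv.update(
                constrained_pct=r.proportion_explained,
                axis1_pct=float(r.axis_proportions[0]) if len(r.axis_proportions) else 0.0,
                model_p=pillai_test(Y, X[sel["selected"]], n_perm=config.n_perm, seed=config.seed)["p_value"],
            )
        # richness models run on the strict set (outlier-sensitive analyses);
        # if too few samples pass the strict gate, fall back to relaxed
        richness_set = strict if len(strict) >= 10 else relaxed
        rich_strict = richness(retained).reindex(richness_set).fillna(0).astype(int)
        Xs = align_drivers(
            proxies,
            richness_set,
            retained.samples.loc[richness_set, "age_calBP"].to_numpy(),
        ).drop(columns="age_calBP")
        gam = gam_poisson(
            rich_strict.to_numpy(),
            Xs[["temperature_C", "precipitation_kg_m2_month", "spore_influx"]],
            ages=retained.samples.loc[richness_set, "age_calBP"].to_numpy(),
        )
        diag = quality_diagnostics(
            metrics.loc[relaxed], ages_rel, rich.astype(float)
        )
        diag.to_csv(out / "quality_diagnostics.tsv", sep="\t", index=False)
        sem_data = Xs.copy()
        sem_data["richness"] = rich_strict
        sem = piecewise_sem(
            [tuple(e) for e in config.sem_dag if set(e) <= set(sem_data.columns)], sem_data
        )
        with open(out / "drivers.json", "w") as fh:
            json.dump(
                {
                    **drv,
                    "gam_dw": gam.dw_statistic,
                    "gam_edf": gam.edf,
                    "gam_outliers": gam.outliers,
                    "sem_fisher_c": sem.fisher_c,
                    "sem_df": sem.df,
                    "sem_p": sem.p_value,
                    "sem_r2": sem.marginal_r2,
                },
                fh,
                indent=1,
                default=float,
            )
        manifest["stages"][name] = {
            "selected": sel["selected"],
            "sem_df": sem.df,
            "gam_dw": gam.dw_statistic,
        }
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, default=str)
    return manifest
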