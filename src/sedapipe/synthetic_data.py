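"""Synthetic inputs with recorded ground truth for every pipeline stage.

The generator emulates the structure of a replicated lake-sediment
metabarcoding study: ~80 sediment samples and 8+8 negative controls, 8 PCR
replicates per unit (plant marker; 4 for the mammal marker), per-replicate
read totals with overdispersion, abundance-dependent replicate dropout
(detection probability logistic in log true abundance — the coupling the
relative abundance index exploits), contaminant taxa enriched in the
negative controls, homopolymer-length artifact variants copied off genuine
sequences, taxa labelled with elevational belts and land-use flags, and
driver series with known effects on composition and richness.

Everything is reproducible from one integer seed; per-stage child seeds are
spawned deterministically.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .io_formats import (
    BELT_VOCABULARY,
    GROWTH_FORMS,
    ProxySeries,
    ReplicateCountTable,
)

__all__ = [
    "SimulationConfig",
    "CalibrationParams",
    "DriverParams",
    "SyntheticTruth",
    "simulate_community",
    "simulate_calibration",
    "simulate_drivers",
    "simulate_richness",
]

_DNA = np.array(list("ACGT"))


@dataclass
class CalibrationParams:
    """Gaussian-response model for the assemblage-temperature training set."""

    n_sites: int = 274
    n_taxa: int = 30
    n_fossil: int = 73
    temp_min: float = 4.0
    temp_max: float = 18.0
    tolerance: float = 2.0
    count_size: int = 120
    noise_sd: float = 0.0  # lognormal sd on expected abundances
    fossil_temp_range: tuple = (6.0, 12.0)


@dataclass
class DriverParams:
    age_min: float = 0.0
    age_max: float = 12700.0
    step: float = 100.0
    noise_sd: float = 0.05  # relative noise on each trajectory


@dataclass
class SimulationConfig:
    """Study-scale defaults: 80 samples, 8+8 negatives, 8 PCR replicates."""

    seed: int
    n_samples: int = 80
    n_extraction_controls: int = 8
    n_pcr_controls: int = 8
    n_taxa: int = 40
    replicates: int = 8
    category: str = "plant_trnL"
    reads_mean: float = 1000.0
    reads_dispersion: float = 5.0  # negative-binomial shape; larger = tighter
    detection_slope: float = 1.5
    detection_midpoint: float = -2.3  # log10 abundance with 50% replicate detection
    detection_max: float = 1.0
    n_contaminant_taxa: int = 2
    contaminant_control_reads: float = 400.0
    contaminant_sample_reads: float = 5.0
    cross_talk_rate: float = 0.0  # genuine reads leaking into controls
    n_low_identity_taxa: int = 3
    low_identity_scale: float = 0.2  # abundance multiplier for imperfect-match taxa
    quality_decay: float = 3.0  # log-abundance boost of imperfect-match taxa with age
    homopolymer_artifact_rate: float = 0.1
    artifact_fraction: float = 0.05
    n_conflict_taxa: int = 4  # planted non-unanimous haplotype-sharing sets
    abundance_sigma: float = 1.0  # lognormal spread of base abundances
    driver_effect_size: float = 0.0  # per-sd log-abundance shift on responsive taxa
    n_responsive_taxa: int = 0
    depth_step_cm: float = 10.0
    years_per_cm: float = 16.0
    calibration: CalibrationParams = field(default_factory=CalibrationParams)
    drivers: DriverParams = field(default_factory=DriverParams)

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("seed is mandatory")
        for name in (
            "homopolymer_artifact_rate",
            "artifact_fraction",
            "cross_talk_rate",
            "detection_max",
        ):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        if isinstance(self.calibration, dict):
            self.calibration = CalibrationParams(**self.calibration)
        if isinstance(self.drivers, dict):
            self.drivers = DriverParams(**self.drivers)

    def child_rng(self, stage: str) -> np.random.Generator:
        """Deterministic per-stage RNG derived from the global seed."""
        digest = sum(ord(c) * (31**i) for i, c in enumerate(stage)) % (2**31)
        return np.random.default_rng(np.random.SeedSequence((self.seed, digest)))

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class SyntheticTruth:
    """Ground truth recorded alongside the generated tables."""

    true_abundance: pd.DataFrame  # sample x taxon, rows sum to 1
    taxon_labels: pd.DataFrame  # belt/pastoral/arable/growth_form + optimality
    contaminant_ids: list
    low_identity_ids: list
    artifact_sources: dict  # variant barcode id -> source barcode id
    driver_values: pd.DataFrame | None = None
    driver_effects: pd.DataFrame | None = None
    calibration_temperatures: np.ndarray | None = None
    fossil_temperatures: np.ndarray | None = None

    def validate(self) -> None:
        sums = self.true_abundance.sum(axis=1)
        if not np.allclose(sums, 1.0):
            raise AssertionError("true abundances must sum to 1 per sample")


# ---------------------------------------------------------------------------
# Sequence helpers
# ---------------------------------------------------------------------------

def _random_sequence(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(_DNA, size=length))


def _runs(seq: str):
    out = []
    for ch in seq:
        if out and out[-1][0] == ch:
            out[-1][1] += 1
        else:
            out.append([ch, 1])
    return out


def _signature(seq: str) -> tuple:
    return tuple(ch for ch, _ in _runs(seq))


def _make_sequences(rng: np.random.Generator, n: int, lo=20, hi=60) -> list[str]:
    """Distinct sequences, pairwise *not* homopolymer variants of each other."""
    seqs: list[str] = []
    sigs: set = set()
    while len(seqs) < n:
        s = _random_sequence(rng, int(rng.integers(lo, hi + 1)))
        if _signature(s) in sigs:  # same run signature could collide under merging
            continue
        seqs.append(s)
        sigs.add(_signature(s))
    return seqs


def _homopolymer_variant(rng: np.random.Generator, seq: str) -> str:
    runs = _runs(seq)
    i = int(rng.integers(0, len(runs)))
    ch, ln = runs[i]
    delta = 1 if ln == 1 else int(rng.choice([-1, 1]))
    runs[i][1] = ln + delta
    return "".join(c * k for c, k in runs)


# ---------------------------------------------------------------------------
# Community simulation
# ---------------------------------------------------------------------------

def _negbin_total(rng, mean, dispersion):
    if dispersion <= 0:
        return int(rng.poisson(mean))
    lam = rng.gamma(dispersion, mean / dispersion)
    return int(rng.poisson(lam))


def simulate_community(
    config: SimulationConfig, driver_values: pd.DataFrame | None = None
):
    """Generate a raw replicate count table, trait table and ground truth.

    Per replicate, each taxon is *included* with a probability logistic in
    its log10 true relative abundance; the replicate's reads are multinomial
    over the included taxa.  Negative controls carry only contaminant reads
    (plus optional cross-talk), so contaminant-removal truth is unambiguous.
    Homopolymer variants are literal copies of their source with one run
    length +/-1 and a fixed fraction of the source's reads.
    """
    cfg = config
    rng = cfg.child_rng("community")

    taxa = [f"t{k:03d}" for k in range(cfg.n_taxa)]
    cont = [f"c{k:02d}" for k in range(cfg.n_contaminant_taxa)]
    seqs = _make_sequences(rng, cfg.n_taxa + cfg.n_contaminant_taxa)

    # base abundances and optional driver forcing of log-abundance
    base = rng.lognormal(0.0, cfg.abundance_sigma, cfg.n_taxa)
    samples = [f"S{i:03d}" for i in range(cfg.n_samples)]
    # imperfect-reference-match taxa: rare in young samples, rising with age
    # (emulates reduced assignability of degraded DNA down-core)
    low_ids = sorted(
        rng.choice(cfg.n_taxa, min(cfg.n_low_identity_taxa, cfg.n_taxa), replace=False)
    )
    base[low_ids] = base[low_ids] * cfg.low_identity_scale
    log_ab = np.tile(np.log(base), (cfg.n_samples, 1))
    if low_ids and cfg.quality_decay > 0 and cfg.n_samples > 1:
        age_frac = np.arange(cfg.n_samples) / (cfg.n_samples - 1)
        for t in low_ids:
            log_ab[:, t] += cfg.quality_decay * age_frac
    effects = None
    if driver_values is not None and cfg.n_responsive_taxa > 0:
        drivers = (driver_values - driver_values.mean()) / driver_values.std(ddof=0)
        responsive = rng.choice(cfg.n_taxa, cfg.n_responsive_taxa, replace=False)
        eff = np.zeros((cfg.n_taxa, drivers.shape[1]))
        for j, t in enumerate(responsive):
            col = j % drivers.shape[1]
            sign = 1 if j % 2 == 0 else -1
            eff[t, col] = sign * cfg.driver_effect_size
        log_ab = log_ab + drivers.to_numpy() @ eff.T
        effects = pd.DataFrame(eff, index=taxa, columns=drivers.columns)
    p_true = np.exp(log_ab)
    p_true /= p_true.sum(axis=1, keepdims=True)
    truth_ab = pd.DataFrame(p_true, index=samples, columns=taxa)

    # unit roster
    units = [(s, "sample") for s in samples]
    units += [(f"EC{i:02d}", "extraction_control") for i in range(cfg.n_extraction_controls)]
    units += [(f"PC{i:02d}", "pcr_control") for i in range(cfg.n_pcr_controls)]

    # detection probability logistic in log10 true abundance (per-decade slope)
    det_p = cfg.detection_max / (
        1.0 + np.exp(-cfg.detection_slope * (np.log10(p_true) - cfg.detection_midpoint))
    )

    all_ids = taxa + cont
    n_rows = len(all_ids)
    columns = []
    blocks = []
    for uid, utype in units:
        for r in range(1, cfg.replicates + 1):
            columns.append((uid, r))
            col = np.zeros(n_rows, dtype=np.int64)
            if utype == "sample":
                i = samples.index(uid)
                total = _negbin_total(rng, cfg.reads_mean, cfg.reads_dispersion)
                include = rng.random(cfg.n_taxa) < det_p[i]
                if include.any() and total > 0:
                    pr = p_true[i] * include
                    pr = pr / pr.sum()
                    col[: cfg.n_taxa] = rng.multinomial(total, pr)
                # contaminants at a low level in samples
                for k in range(cfg.n_contaminant_taxa):
                    col[cfg.n_taxa + k] = rng.poisson(cfg.contaminant_sample_reads)
            else:
                for k in range(cfg.n_contaminant_taxa):
                    col[cfg.n_taxa + k] = rng.poisson(cfg.contaminant_control_reads)
                if cfg.cross_talk_rate > 0:
                    leak = rng.random(cfg.n_taxa) < cfg.cross_talk_rate
                    col[: cfg.n_taxa][leak] = rng.poisson(2.0, leak.sum())
            blocks.append(col)
    counts = np.column_stack(blocks)

    # metadata: identities; the low_ids taxa carry an imperfect best match
    identity = np.ones(n_rows)
    for t in low_ids:
        identity[t] = 0.97
    meta = pd.DataFrame(
        {
            "sequence": seqs,
            "category": cfg.category,
            "taxon": [f"Taxon {tid}" for tid in taxa] + [f"Contaminant {cid}" for cid in cont],
            "rank": "species",
            "best_identity:refdb": identity,
        },
        index=pd.Index(all_ids, name="id"),
    )
    col_index = pd.MultiIndex.from_tuples(columns, names=["sample_id", "replicate"])
    count_df = pd.DataFrame(counts, index=meta.index, columns=col_index)

    # homopolymer artifact variants
    artifact_sources: dict[str, str] = {}
    n_art = int(round(cfg.homopolymer_artifact_rate * cfg.n_taxa))
    perfect = [t for t in range(cfg.n_taxa) if t not in low_ids]
    n_art = min(n_art, len(perfect))
    if n_art:
        # artifacts ride on the most abundant templates (PCR error copies)
        chosen = sorted(perfect, key=lambda t: -base[t])[:n_art]
        art_rows, art_meta = [], []
        existing = set(meta["sequence"])
        for idx, t in enumerate(chosen):
            for _ in range(20):
                var_seq = _homopolymer_variant(rng, seqs[t])
                if var_seq not in existing:
                    break
            else:  # pragma: no cover - exhausted retries
                continue
            existing.add(var_seq)
            vid = f"a{idx:02d}"
            artifact_sources[vid] = taxa[t]
            art_meta.append(
                {
                    "sequence": var_seq,
                    "category": cfg.category,
                    "taxon": meta.at[taxa[t], "taxon"],
                    "rank": "species",
                    "best_identity:refdb": identity[t],
                }
            )
            art_rows.append((count_df.loc[taxa[t]].to_numpy() * cfg.artifact_fraction).astype(np.int64))
        if art_rows:
            art_index = pd.Index(list(artifact_sources.keys()), name="id")
            meta = pd.concat([meta, pd.DataFrame(art_meta, index=art_index)])
            count_df = pd.concat(
                [count_df, pd.DataFrame(np.vstack(art_rows), index=art_index, columns=col_index)]
            )

    depth = {
        uid: (samples.index(uid) + 1) * cfg.depth_step_cm if utype == "sample" else np.nan
        for uid, utype in units
    }
    sample_meta = pd.DataFrame(
        {
            "unit_type": [utype for _, utype in units],
            "depth_cm": [depth[uid] for uid, _ in units],
            "age_calBP": [
                depth[uid] * cfg.years_per_cm if not np.isnan(depth[uid]) else np.nan
                for uid, _ in units
            ],
        },
        index=pd.Index([uid for uid, _ in units], name="sample_id"),
    )
    table = ReplicateCountTable(meta=meta, counts=count_df, samples=sample_meta)

    traits, labels = _make_traits(cfg, rng, taxa, low_ids)
    truth = SyntheticTruth(
        true_abundance=truth_ab,
        taxon_labels=labels,
        contaminant_ids=cont,
        low_identity_ids=[taxa[t] for t in low_ids],
        artifact_sources=artifact_sources,
        driver_values=driver_values,
        driver_effects=effects,
    )
    truth.validate()
    return table, traits, truth


def _make_traits(cfg, rng, taxa, low_ids):
    """Haplotype-sharing species sets: mostly unanimous, some planted conflicts."""
    belts = list(BELT_VOCABULARY)
    forms = list(GROWTH_FORMS)
    conflict = set(
        rng.choice(cfg.n_taxa, min(cfg.n_conflict_taxa, cfg.n_taxa), replace=False)
    )
    rows, labels = [], []
    for t, tid in enumerate(taxa):
        n_sp = int(rng.integers(1, 5))
        belt = belts[t % len(belts)]
        pastoral = t % 7 == 0
        arable = t % 19 == 3
        form = forms[t % len(forms)]
        is_conflict = t in conflict and n_sp >= 2
        for s in range(max(n_sp, 2) if is_conflict else n_sp):
            sp_belt = belt
            sp_pastoral = pastoral
            if is_conflict and s == 0:
                sp_belt = belts[(t + 3) % len(belts)]
                sp_pastoral = not pastoral
            rows.append(
                {
                    "species": f"Species {tid}-{s}",
                    "belt": sp_belt,
                    "pastoral_flag": sp_pastoral,
                    "arable_flag": arable,
                    "growth_form": form,
                }
            )
        labels.append(
            {
                "taxon_id": tid,
                "n_species": max(n_sp, 2) if is_conflict else n_sp,
                "belt": belt,
                "pastoral": pastoral,
                "arable": arable,
                "growth_form": form,
                "belt_optimal": not is_conflict,
                "pastoral_optimal": (not is_conflict) and pastoral,
                "arable_optimal": arable,
            }
        )
    traits = pd.DataFrame(rows).set_index("species")
    labels = pd.DataFrame(labels).set_index("taxon_id")
    return traits, labels


def barcode_species_map(traits: pd.DataFrame, taxa=None) -> dict:
    """Recover the barcode -> haplotype-sharing-species map from trait names."""
    out: dict[str, list] = {}
    for sp in traits.index:
        tid = sp.split()[1].rsplit("-", 1)[0]
        out.setdefault(tid, []).append(sp)
    if taxa is not None:
        out = {t: out.get(t, []) for t in taxa}
    return out


# ---------------------------------------------------------------------------
# Calibration (transfer-function) simulation
# ---------------------------------------------------------------------------

def simulate_calibration(config: SimulationConfig):
    """Gaussian unimodal species responses along a temperature gradient.

    Returns ``(calibration_df, true_temperatures, fossil_df,
    fossil_true_temperatures)``.  Site counts are multinomial draws from
    expected abundances ``exp(-(T - opt)^2 / (2 tol^2))`` with species
    optima spread over the temperature range; the fossil set follows a
    smooth trajectory between the configured bounds.
    """
    cal = config.calibration
    rng = config.child_rng("calibration")
    if cal.n_taxa < 2:
        raise ValueError("need at least 2 taxa")
    optima = np.linspace(cal.temp_min, cal.temp_max, cal.n_taxa)
    tol = np.full(cal.n_taxa, cal.tolerance)

    def expected(T):
        return np.exp(-((T[:, None] - optima[None, :]) ** 2) / (2 * tol[None, :] ** 2))

    def draw(T):
        mu = expected(T)
        if cal.noise_sd > 0:
            mu = mu * rng.lognormal(0.0, cal.noise_sd, mu.shape)
        counts = np.zeros_like(mu, dtype=np.int64)
        for i in range(len(T)):
            p = mu[i] / mu[i].sum()
            counts[i] = rng.multinomial(cal.count_size, p)
        return counts

    T_cal = rng.uniform(cal.temp_min, cal.temp_max, cal.n_sites)
    T_cal.sort()
    Y_cal = draw(T_cal)
    # smooth fossil trajectory: cold start, ramp, plateau (deglaciation-like)
    u = np.linspace(0, 1, cal.n_fossil)
    lo, hi = cal.fossil_temp_range
    T_fos = lo + (hi - lo) / (1.0 + np.exp(-10 * (u - 0.35)))
    Y_fos = draw(T_fos)
    taxa = [f"chir{k:02d}" for k in range(cal.n_taxa)]
    cal_df = pd.DataFrame(Y_cal, columns=taxa, index=[f"site{i:03d}" for i in range(cal.n_sites)])
    fos_df = pd.DataFrame(Y_fos, columns=taxa, index=[f"fossil{i:03d}" for i in range(cal.n_fossil)])
    return cal_df, T_cal, fos_df, T_fos


# ---------------------------------------------------------------------------
# Driver simulation
# ---------------------------------------------------------------------------

def simulate_drivers(config: SimulationConfig) -> dict[str, ProxySeries]:
    """Smooth environmental/human-impact trajectories plus noise.

    Emulates Holocene-scale series: July temperature (deglacial ramp plus a
    mid-Holocene optimum), precipitation, organic-matter content (LOI),
    microcharcoal influx (late-Holocene rise = human fire activity) and
    coprophilous-spore influx (grazing).  Noise is relative Gaussian with
    sd ``drivers.noise_sd``; a zero value returns the mean functions
    exactly.
    """
    d = config.drivers
    rng = config.child_rng("drivers")
    ages = np.arange(d.age_min, d.age_max + d.step / 2, d.step)
    u = (ages - d.age_min) / max(d.age_max - d.age_min, 1.0)  # 0 young .. 1 old

    means = {
        "temperature_C": 11.0 - 4.0 / (1.0 + np.exp(-12 * (u - 0.9))) + 1.0 * np.sin(np.pi * u),
        "precipitation_kg_m2_month": 110.0 + 25.0 * np.sin(2 * np.pi * u) + 10.0 * u,
        "LOI_percent": 18.0 + 10.0 * np.exp(-(((u - 0.55) / 0.2) ** 2)),
        "charcoal_influx": 5.0 + 60.0 * np.exp(-((u / 0.18) ** 2)),
        "spore_influx": 2.0 + 25.0 * np.exp(-(((u - 0.12) / 0.1) ** 2)),
    }
    units = {
        "temperature_C": "degC",
        "precipitation_kg_m2_month": "kg m-2 month-1",
        "LOI_percent": "%",
        "charcoal_influx": "particles cm-2 yr-1",
        "spore_influx": "particles cm-2 yr-1",
    }
    out = {}
    for name, mean in means.items():
        noise = rng.normal(0.0, d.noise_sd, len(ages)) * np.abs(mean) if d.noise_sd > 0 else 0.0
        out[name] = ProxySeries(
            proxy_name=name,
            units=units[name],
            depth_cm=ages / config.years_per_cm,
            age_calBP=ages,
            value=mean + noise,
        )
    return out


def simulate_richness(
    drivers: pd.DataFrame, coefficients: dict, intercept: float = 3.5, seed: int = 0
) -> pd.Series:
    """Poisson richness with log-mean linear/smooth in standardized drivers.

    ``coefficients`` maps a driver column to either a scalar (linear effect
    on the log mean) or a callable applied to the standardized values.
    """
    rng = np.random.default_rng(seed)
    eta = np.full(len(drivers), float(intercept))
    for name, coef in coefficients.items():
        z = (drivers[name] - drivers[name].mean()) / drivers[name].std(ddof=0)
        eta = eta + (coef(z.to_numpy()) if callable(coef) else coef * z.to_numpy())
    return pd.Series(rng.poisson(np.exp(eta)), index=drivers.index)
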