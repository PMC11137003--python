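"""Synthetic experiments with known ground truth.

Every pipeline stage is exercised on data generated here: a two-group
cohort (fed vs fasted, five animals per group) with per-metabolite pool
sizes and group-effect multipliers, tracer label cascades propagated
through precursor->product transfer fractions, forward natural-abundance
convolution onto the true isotopologue fractions, isotope-dilution peak
areas, enzyme-assay products, and mono-exponential glucose-bolus decay
curves sampled at 5-90 min.

Noise is multiplicative log-normal (MS peak areas are positive with
roughly constant CV); an additive-Gaussian alternative is available by
flag. All randomness flows from one master seed through spawned child
streams, so adding a table never perturbs the others and regenerating
with the same seed is byte-identical.

Default effect multipliers are illustrative, set once in the direction of
the study's reported contrasts (portal propionate sharply down on
fasting, ketones up, propionylcarnitine down) so the pipeline's
qualitative readout matches the biology it emulates; they are not fitted
values.
"""

from __future__ import annotations

import functools
from dataclasses import dataclass, field
from graphlib import CycleError, TopologicalSorter

import numpy as np
import pandas as pd

from .mid import (
    MIDVector,
    build_correction_matrix,
    fragment_context,
    forward_convolve,
    load_fragment_registry,
)
from .turnover import STANDARD_TIME_POINTS, BolusDose, EnrichmentTimeCourse

__all__ = [
    "CohortConfig",
    "TracerExperimentConfig",
    "SyntheticDataset",
    "DEFAULT_POOLS",
    "DEFAULT_CASCADES",
    "simulate_tracer_cascade",
    "simulate_measured_mids",
    "simulate_glucose_bolus",
    "generate_cohort",
]

# (tissue, baseline pool nmol/mg or uM, fasted/fed multiplier)
DEFAULT_POOLS: dict[str, tuple[str, float, float]] = {
    "acetylcarnitine": ("plasma", 0.020, 1.60),
    "propionylcarnitine": ("plasma", 0.020, 0.38),
    "BHB": ("plasma", 100.0, 2.20),
    "propionate": ("portal_vein", 20.0, 0.25),
    "acetate": ("portal_vein", 200.0, 0.50),
    "butyrate": ("portal_vein", 15.0, 0.50),
    "hexanoate": ("portal_vein", 5.0, 1.50),
    "citrate": ("liver", 0.30, 1.00),
    "methylcitrate": ("liver", 0.15, 0.50),
}

# (assay, baseline activity nmol/min/mg, fasted/fed multiplier)
DEFAULT_ACTIVITIES: dict[str, tuple[float, float]] = {
    "PCC": (0.05, 1.0),
    "SDS": (0.40, 2.0),
    "BCAT": (1.50, 1.5),
}


@dataclass(frozen=True)
class CohortConfig:
    """Design of a synthetic two-group experiment."""

    groups: tuple[str, str] = ("fed", "fasted")
    n_per_group: int = 5
    pools: dict = field(default_factory=lambda: dict(DEFAULT_POOLS))
    activities: dict = field(default_factory=lambda: dict(DEFAULT_ACTIVITIES))
    cv: float = 0.10
    noise: str = "lognormal"
    seed: int = 0
    # bolus experiment ground truth (umol/kg and umol/kg/min)
    true_pool_umol_kg: float = 1800.0
    true_ra_umol_kg_min: float = 150.0
    ra_multiplier: float = 0.60

    def __post_init__(self) -> None:
        if self.n_per_group < 2:
            raise ValueError("need n >= 2 per group")
        if self.cv < 0:
            raise ValueError("CV must be >= 0")
        if any(v[2] <= 0 for v in self.pools.values()):
            raise ValueError("effect multipliers must be positive")
        if self.noise not in ("lognormal", "gaussian"):
            raise ValueError(f"unknown noise model {self.noise!r}")


@dataclass(frozen=True)
class TracerExperimentConfig:
    """A labeled-tracer experiment: the administered precursor, its plasma
    enrichment, the precursor->product cascade with transfer fractions,
    and the mass shift carried by each metabolite in the chain."""

    tracer: str
    dose_mg_per_kg: float
    precursor: str
    precursor_enrichment: float
    edges: tuple[tuple[str, str, float], ...]
    shifts: dict[str, int] = field(default_factory=dict)
    sampling_time_min: float = 20.0
    time_points: tuple[float, ...] = STANDARD_TIME_POINTS

    def __post_init__(self) -> None:
        for src, dst, frac in self.edges:
            if not 0.0 <= frac <= 1.0:
                raise ValueError(f"transfer fraction {frac} for {src}->{dst}")


#: Label cascades of the three tracer experiments. Mass shifts follow the
#: pathway bookkeeping: M6 valine -> M5 ketoisovalerate -> M4
#: 3-hydroxyisobutyrate -> M3 propionylcarnitine; M4 threonine -> M4
#: 2-ketobutyrate -> M3 propionylcarnitine; M3 propionate -> M3
#: propionylcarnitine -> TCA -> glucose. Transfer fractions are free
#: parameters chosen so terminal labeling stays below 30%.
DEFAULT_CASCADES: dict[str, TracerExperimentConfig] = {
    "valine": TracerExperimentConfig(
        tracer="[15N,13C5]valine", dose_mg_per_kg=100.0,
        precursor="valine", precursor_enrichment=0.40,
        edges=(("valine", "KIV", 0.5), ("KIV", "3HIB", 0.5),
               ("3HIB", "propionylcarnitine", 0.5)),
        shifts={"valine": 6, "KIV": 5, "3HIB": 4, "propionylcarnitine": 3},
    ),
    "threonine": TracerExperimentConfig(
        tracer="[13C4]threonine", dose_mg_per_kg=100.0,
        precursor="threonine", precursor_enrichment=0.40,
        edges=(("threonine", "2KB", 0.4),
               ("2KB", "propionylcarnitine", 0.5)),
        shifts={"threonine": 4, "2KB": 4, "propionylcarnitine": 3},
    ),
    "propionate": TracerExperimentConfig(
        tracer="[13C3]propionate", dose_mg_per_kg=500.0,
        precursor="propionate", precursor_enrichment=0.30,
        edges=(("propionate", "propionylcarnitine", 0.5),
               ("propionylcarnitine", "citrate", 0.3),
               ("citrate", "glucose_13C", 0.2)),
        shifts={"propionate": 3, "propionylcarnitine": 3, "citrate": 3,
                "glucose_13C": 3},
    ),
}


def simulate_tracer_cascade(cfg: TracerExperimentConfig) -> pd.DataFrame:
    """Propagate precursor enrichment through the cascade.

    Product enrichment is the sum over incoming edges of precursor
    enrichment times transfer fraction, evaluated in topological order;
    a cyclic cascade raises ``ValueError``. Returns a tidy frame with
    metabolite, mass_shift, enrichment.
    """
    graph: dict[str, set[str]] = {}
    for src, dst, _ in cfg.edges:
        graph.setdefault(dst, set()).add(src)
        graph.setdefault(src, set())
    try:
        order = list(TopologicalSorter(graph).static_order())
    except CycleError as exc:
        raise ValueError(f"tracer cascade contains a cycle: {exc}") from exc
    enrich = {m: 0.0 for m in order}
    enrich[cfg.precursor] = cfg.precursor_enrichment
    for m in order:
        for src, dst, frac in cfg.edges:
            if dst == m:
                enrich[m] += enrich[src] * frac
    rows = [
        {
            "metabolite": m,
            "mass_shift": cfg.shifts.get(m, 0),
            "enrichment": e,
        }
        for m, e in enrich.items()
    ]
    return pd.DataFrame(rows)


@functools.lru_cache(maxsize=None)
def _cached_matrix(metabolite: str):
    """Fragment context + correction matrix for a default-registry
    metabolite (matrices depend only on the registry, so cache them)."""
    ctx = fragment_context(metabolite)
    return ctx, build_correction_matrix(ctx)


def _noise(rng: np.random.Generator, shape, cv: float, model: str) -> np.ndarray:
    """Unit-mean multiplicative factors at the requested CV."""
    if cv == 0:
        return np.ones(shape)
    if model == "lognormal":
        sigma = np.sqrt(np.log1p(cv**2))
        return rng.lognormal(mean=-sigma**2 / 2.0, sigma=sigma, size=shape)
    return np.clip(1.0 + cv * rng.standard_normal(shape), 1e-6, None)


def simulate_measured_mids(
    true_enrichments: pd.DataFrame,
    registry: pd.DataFrame | None = None,
    cv: float = 0.0,
    seed: int | np.random.SeedSequence = 0,
    noise: str = "lognormal",
) -> pd.DataFrame:
    """Forward-convolve true tracer MIDs into observable mol-percent MIDs.

    Each metabolite's true MID (all mass at shift 0 and at its cascade
    shift) is pushed through the fragment's correction matrix, multiplied
    by unit-mean noise at the given CV, and renormalized. Output is the
    long-form schema the correction stage consumes: metabolite,
    mass_shift, value, value_type.
    """
    use_cache = registry is None
    if registry is None:
        registry = load_fragment_registry()
    rng = np.random.default_rng(seed)
    rows = []
    for rec in true_enrichments.itertuples(index=False):
        if use_cache:
            ctx, M = _cached_matrix(rec.metabolite)
        else:
            ctx = fragment_context(rec.metabolite, registry)
            M = build_correction_matrix(ctx)
        n = ctx.n_tracer_positions
        if rec.mass_shift > n:
            raise ValueError(
                f"{rec.metabolite}: cascade shift {rec.mass_shift} exceeds "
                f"{n} tracer positions"
            )
        true = np.zeros(n + 1)
        true[0] = 1.0 - rec.enrichment
        true[rec.mass_shift] += rec.enrichment
        measured = forward_convolve(MIDVector(true, "corrected", n), M)
        noisy = measured.fractions * _noise(rng, n + 5, cv, noise)
        noisy = noisy / noisy.sum()
        for shift, val in enumerate(noisy):
            rows.append(
                {
                    "metabolite": rec.metabolite,
                    "mass_shift": shift,
                    "value": val * 100.0,
                    "value_type": "mol_percent",
                }
            )
    return pd.DataFrame(rows)


def simulate_glucose_bolus(
    true_ra: float,
    true_q: float,
    dose: BolusDose,
    time_points=STANDARD_TIME_POINTS,
    cv: float = 0.0,
    seed: int | np.random.SeedSequence = 0,
    noise: str = "lognormal",
) -> EnrichmentTimeCourse:
    """Sample a bolus decay course from the single-pool model.

    k = Ra/Q and E0 = D/(D+Q); enrichment at each time point is perturbed
    by unit-mean multiplicative noise and clipped into (0, 1).
    """
    if true_ra <= 0 or true_q <= 0:
        raise ValueError("Ra and Q must be positive")
    rng = np.random.default_rng(seed)
    t = np.asarray(time_points, dtype=float)
    k = true_ra / true_q
    e0 = dose.dose_umol_per_kg / (dose.dose_umol_per_kg + true_q)
    e = e0 * np.exp(-k * t) * _noise(rng, len(t), cv, noise)
    e = np.clip(e, 1e-9, 1.0 - 1e-9)
    return EnrichmentTimeCourse(t, e)


@dataclass
class SyntheticDataset:
    """Observed tables plus the ground truth that generated them."""

    observed: dict[str, pd.DataFrame]
    ground_truth: dict[str, pd.DataFrame]
    config: CohortConfig

    def table_hash(self) -> str:
        """Deterministic digest of every observed table (CSV bytes)."""
        import hashlib

        h = hashlib.sha256()
        for name in sorted(self.observed):
            h.update(name.encode())
            h.update(self.observed[name].to_csv(index=False).encode())
        return h.hexdigest()


def generate_cohort(cfg: CohortConfig | None = None) -> SyntheticDataset:
    """Generate a full synthetic experiment for a two-group cohort.

    Produces observed tables in the schemas the downstream stages consume:

    - ``peak_areas``: isotope-dilution areas per sample x metabolite
      (sample_id, group, tissue, assay, analyte, area, is_name, is_area)
    - ``mids``: measured mol-percent MIDs per sample for the propionate
      tracer cascade (sample_id, group, tissue, metabolite, fragment_id,
      mass_shift, value, value_type)
    - ``bolus``: glucose-bolus enrichment courses (sample_id, group,
      time_min, enrichment)
    - ``enzyme``: enzyme-assay product areas (sample_id, group, assay,
      analyte, area, is_name, is_area)

    plus ground-truth pools, activities, and turnover parameters.
    """
    if cfg is None:
        cfg = CohortConfig()
    root = np.random.SeedSequence(cfg.seed)
    ss_pool, ss_mid, ss_bolus, ss_enzyme = root.spawn(4)

    samples = [
        (f"{g}_{i + 1:02d}", g)
        for g in cfg.groups
        for i in range(cfg.n_per_group)
    ]

    # --- pools and peak areas ---------------------------------------------
    rng = np.random.default_rng(ss_pool)
    area_rows, truth_rows = [], []
    is_base_area = 1.0e5
    for met, (tissue, baseline, mult) in cfg.pools.items():
        for group_idx, (sid, g) in enumerate(samples):
            mean = baseline * (mult if g == cfg.groups[1] else 1.0)
            conc = mean * _noise(rng, (), cfg.cv, cfg.noise)
            is_area = is_base_area * _noise(rng, (), cfg.cv, cfg.noise)
            # isotope-dilution geometry: 0.4 nmol IS into 20 units of sample
            area = conc * 20.0 / 0.4 * is_area
            area_rows.append(
                {
                    "sample_id": sid, "group": g, "tissue": tissue,
                    "assay": "profiling", "analyte": met,
                    "area": float(area), "is_name": f"IS_{met}",
                    "is_area": float(is_area),
                }
            )
        truth_rows.append(
            {
                "metabolite": met, "tissue": tissue,
                "mean_fed": baseline, "mean_fasted": baseline * mult,
                "multiplier": mult,
            }
        )
    peak_areas = pd.DataFrame(area_rows)
    truth_pools = pd.DataFrame(truth_rows)

    # --- measured MIDs (propionate tracer, per sample) --------------------
    cascade = simulate_tracer_cascade(DEFAULT_CASCADES["propionate"])
    mid_rows = []
    for child, (sid, g) in zip(ss_mid.spawn(len(samples)), samples):
        # fasted animals route more propionyl-CoA to the TCA/gluconeogenesis
        scale = 1.25 if g == cfg.groups[1] else 1.0
        tc = cascade.copy()
        tc["enrichment"] = np.clip(tc["enrichment"] * scale, 0.0, 0.95)
        obs = simulate_measured_mids(tc, cv=cfg.cv / 2, seed=child, noise=cfg.noise)
        obs.insert(0, "sample_id", sid)
        obs.insert(1, "group", g)
        obs.insert(2, "tissue", "plasma")
        obs.insert(4, "fragment_id", obs["metabolite"])
        mid_rows.append(obs)
    mids = pd.concat(mid_rows, ignore_index=True)
    truth_mids = cascade.copy()

    # --- glucose bolus ----------------------------------------------------
    dose = BolusDose()
    bolus_rows, truth_bolus_rows = [], []
    for child, (sid, g) in zip(ss_bolus.spawn(len(samples)), samples):
        child_rng = np.random.default_rng(child)
        mult = cfg.ra_multiplier if g == cfg.groups[1] else 1.0
        ra = cfg.true_ra_umol_kg_min * mult * _noise(child_rng, (), cfg.cv, cfg.noise)
        q = cfg.true_pool_umol_kg * _noise(child_rng, (), cfg.cv, cfg.noise)
        course = simulate_glucose_bolus(
            ra, q, dose, cv=cfg.cv / 2, seed=child_rng.integers(2**31), noise=cfg.noise
        )
        for t, e in zip(course.times_min, course.enrichments):
            bolus_rows.append(
                {"sample_id": sid, "group": g, "time_min": t, "enrichment": e}
            )
        truth_bolus_rows.append(
            {"sample_id": sid, "group": g, "true_ra": ra, "true_q": q}
        )
    bolus = pd.DataFrame(bolus_rows)
    truth_bolus = pd.DataFrame(truth_bolus_rows)

    # --- enzyme assays ----------------------------------------------------
    from .quant import BCAT_ASSAY, PCC_ASSAY, SDS_ASSAY

    assay_cfgs = {"PCC": PCC_ASSAY, "SDS": SDS_ASSAY, "BCAT": BCAT_ASSAY}
    rng = np.random.default_rng(ss_enzyme)
    enzyme_rows, truth_enzyme_rows = [], []
    for assay, (baseline, mult) in cfg.activities.items():
        acfg = assay_cfgs[assay]
        for sid, g in samples:
            act = baseline * (mult if g == cfg.groups[1] else 1.0)
            act *= _noise(rng, (), cfg.cv, cfg.noise)
            product = act * acfg.reaction_time_min * acfg.tissue_mg
            is_area = is_base_area * _noise(rng, (), cfg.cv, cfg.noise)
            area = product / acfg.is_spec.amount_nmol * is_area
            enzyme_rows.append(
                {
                    "sample_id": sid, "group": g, "assay": assay,
                    "analyte": acfg.product_analyte, "area": float(area),
                    "is_name": acfg.is_spec.name, "is_area": float(is_area),
                }
            )
            truth_enzyme_rows.append(
                {"sample_id": sid, "group": g, "assay": assay, "true_activity": act}
            )
    enzyme = pd.DataFrame(enzyme_rows)
    truth_enzyme = pd.DataFrame(truth_enzyme_rows)

    return SyntheticDataset(
        observed={
            "peak_areas": peak_areas,
            "mids": mids,
            "bolus": bolus,
            "enzyme": enzyme,
        },
        ground_truth={
            "pools": truth_pools,
            "mids": truth_mids,
            "bolus": truth_bolus,
            "enzyme": truth_enzyme,
        },
        config=cfg,
    )
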