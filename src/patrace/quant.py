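"""Internal-standard quantification and enzyme-activity computation.

All absolute quantification in the pipeline is isotope-dilution style: a
known amount of a stable-isotope-labeled internal standard (IS) is spiked
into the sample, and the analyte amount follows from the analyte/IS
peak-area ratio (response factor 1 for a co-eluting labeled IS unless
overridden):

    conc = (area_analyte / area_IS) * RF * amount_IS / sample_amount

Enzyme activities (propionyl-CoA carboxylase, serine-threonine
dehydratase, branched-chain aminotransferase) convert the product amount
found in the reaction into nmol product / min / mg tissue.

The module also carries the MRM transition registry and a consistency
check that recomputes each precursor (Q1) m/z from the registered formula,
derivatization, and adduct, and each product (Q3) as Q1 minus the
registered neutral loss. One registry entry (D5-propionate) is a known
discrepancy whose printed Q1 exceeds the computed acylhydrazide mass by 3;
the check reports it as a failure with that delta.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd

from . import chem

__all__ = [
    "PeakAreaRecord",
    "InternalStandardSpec",
    "EnzymeAssayConfig",
    "EnzymeActivityResult",
    "TransitionReport",
    "concentration_by_is",
    "enzyme_activity",
    "ammonia_from_is",
    "load_mrm_registry",
    "mrm_transition_check",
    "check_all_transitions",
    "PCC_ASSAY",
    "SDS_ASSAY",
    "BCAT_ASSAY",
]


@dataclass(frozen=True)
class PeakAreaRecord:
    sample_id: str
    analyte: str
    area: float
    is_name: str
    is_area: float

    def __post_init__(self) -> None:
        if self.area < 0 or self.is_area < 0:
            raise ValueError("peak areas must be non-negative")


@dataclass(frozen=True)
class InternalStandardSpec:
    """Spiked IS: amount (nmol), response factor vs analyte, and the
    sample amount (mg tissue or ul plasma) it normalizes to."""

    name: str
    amount_nmol: float
    response_factor: float = 1.0
    sample_amount: float = 1.0

    def __post_init__(self) -> None:
        if self.amount_nmol <= 0 or self.response_factor <= 0 or self.sample_amount <= 0:
            raise ValueError("IS spec fields must be positive")


def concentration_by_is(rec: PeakAreaRecord, spec: InternalStandardSpec) -> float:
    """Analyte concentration (nmol per mg or per ul) by isotope dilution."""
    if rec.is_area <= 0:
        raise ValueError("internal-standard peak area must be positive")
    ratio = rec.area / rec.is_area
    return ratio * spec.response_factor * spec.amount_nmol / spec.sample_amount


def ammonia_from_is(
    rec: PeakAreaRecord,
    is_amount_nmol: float = 0.5,
    plasma_volume_ul: float = 20.0,
) -> float:
    """Plasma ammonia (uM) from the 14N/15N derivative area ratio.

    The default spike is 10 ul of 0.05 mM 15N-ammonium chloride (0.5 nmol)
    into 20 ul plasma, so an area ratio of 1 reads 25 uM.
    """
    if rec.is_area <= 0:
        raise ValueError("internal-standard peak area must be positive")
    if plasma_volume_ul <= 0:
        raise ValueError("plasma volume must be positive")
    ratio = rec.area / rec.is_area
    return ratio * is_amount_nmol / plasma_volume_ul * 1000.0


# ---------------------------------------------------------------------------
# Enzyme activities
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class EnzymeAssayConfig:
    """Reaction geometry of a tissue enzyme assay."""

    name: str
    reaction_time_min: float
    reaction_volume_ul: float
    homogenate_volume_ul: float
    homogenate_conc_mg_per_ml: float = 20.0  # 20 mg tissue in 1 ml buffer
    product_analyte: str = ""
    is_spec: InternalStandardSpec | None = None

    def __post_init__(self) -> None:
        if min(
            self.reaction_time_min,
            self.reaction_volume_ul,
            self.homogenate_volume_ul,
            self.homogenate_conc_mg_per_ml,
        ) <= 0:
            raise ValueError("assay config fields must be positive")

    @property
    def tissue_mg(self) -> float:
        return self.homogenate_volume_ul * self.homogenate_conc_mg_per_ml / 1000.0


@dataclass(frozen=True)
class EnzymeActivityResult:
    activity_nmol_min_mg: float
    product_nmol: float
    assay: str

    def __post_init__(self) -> None:
        if self.activity_nmol_min_mg < 0:
            raise ValueError("activity must be >= 0")


# Assay geometries: PCC (carboxylation of propionyl-CoA to
# methylmalonyl-CoA, 30 min, 10 ul homogenate), SDS (threonine -> 2KB,
# 2 h, 100 ul), BCAT (valine + 2KG -> KIV, 30 min, 100 ul).
PCC_ASSAY = EnzymeAssayConfig(
    "PCC", reaction_time_min=30.0, reaction_volume_ul=120.0,
    homogenate_volume_ul=10.0, product_analyte="methylmalonyl-CoA",
    is_spec=InternalStandardSpec("D9_pentanoyl-CoA", amount_nmol=1e-4),
)
SDS_ASSAY = EnzymeAssayConfig(
    "SDS", reaction_time_min=120.0, reaction_volume_ul=290.0,
    homogenate_volume_ul=100.0, product_analyte="2KB",
    is_spec=InternalStandardSpec("M5_KIV", amount_nmol=4e-4),
)
BCAT_ASSAY = EnzymeAssayConfig(
    "BCAT", reaction_time_min=30.0, reaction_volume_ul=320.0,
    homogenate_volume_ul=100.0, product_analyte="KIV",
    is_spec=InternalStandardSpec("M5_KIV", amount_nmol=4e-4),
)


def enzyme_activity(product_nmol: float, cfg: EnzymeAssayConfig) -> EnzymeActivityResult:
    """Specific activity from the product amount formed in the reaction:
    product / (reaction time * tissue mass in the reaction)."""
    if product_nmol < 0:
        raise ValueError("product amount must be >= 0")
    tissue = cfg.tissue_mg
    if tissue <= 0 or cfg.reaction_time_min <= 0:
        raise ValueError("zero reaction time or tissue mass")
    return EnzymeActivityResult(
        activity_nmol_min_mg=product_nmol / (cfg.reaction_time_min * tissue),
        product_nmol=product_nmol,
        assay=cfg.name,
    )


# ---------------------------------------------------------------------------
# MRM transition registry and consistency check
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TransitionReport:
    analyte: str
    q1_registered: int
    q1_computed: int
    q3_registered: int
    q3_computed: int
    delta_q1: int
    passed: bool
    known_discrepancy: bool
    note: str = ""


def load_mrm_registry(path=None) -> pd.DataFrame:
    """Registry of analytes with formulas, derivatives, adducts and the
    printed MRM transitions (packaged CSV unless a path is given)."""
    if path is None:
        ref = resources.files("patrace").joinpath("data/mrm_registry.csv")
        with resources.as_file(ref) as p:
            df = pd.read_csv(p, keep_default_na=False)
    else:
        df = pd.read_csv(path, keep_default_na=False)
    return df.set_index("analyte", drop=False)


def mrm_transition_check(analyte: str, registry: pd.DataFrame | None = None) -> TransitionReport:
    """Recompute an analyte's Q1 from formula + derivative + adduct and
    compare against the registered transition.

    Q1 is the nominal adduct m/z of the derivatized formula; Q3 is checked
    as registered Q1 minus the registered neutral loss. ``delta_q1`` is
    registered minus computed; any nonzero delta or Q3 mismatch fails.
    """
    if registry is None:
        registry = load_mrm_registry()
    if analyte not in registry.index:
        raise KeyError(f"analyte {analyte!r} not in MRM registry")
    row = registry.loc[analyte]
    f = chem.parse_formula(row["backbone_formula"])
    if row["derivative"]:
        f = chem.apply_derivative(f, row["derivative"])
    q1_computed = int(chem.ion_mz(f, row["adduct"], mode="nominal"))
    q1_registered = int(row["q1"])
    q3_registered = int(row["q3"])
    q3_computed = q1_registered - int(row["neutral_loss"])
    delta = q1_registered - q1_computed
    passed = delta == 0 and q3_computed == q3_registered
    return TransitionReport(
        analyte=analyte,
        q1_registered=q1_registered,
        q1_computed=q1_computed,
        q3_registered=q3_registered,
        q3_computed=q3_computed,
        delta_q1=delta,
        passed=passed,
        known_discrepancy=bool(int(row["known_discrepancy"])),
        note=str(row["note"]),
    )


def check_all_transitions(registry: pd.DataFrame | None = None) -> pd.DataFrame:
    """Run the transition check over the whole registry; one row each."""
    if registry is None:
        registry = load_mrm_registry()
    reports = [mrm_transition_check(a, registry) for a in registry.index]
    return pd.DataFrame([r.__dict__ for r in reports])


def quantify_table(
    areas: pd.DataFrame,
    is_specs: dict[str, InternalStandardSpec],
) -> pd.DataFrame:
    """Vectorized isotope-dilution quantification of a tidy peak-area table.

    ``areas`` needs columns sample_id, analyte, area, is_name, is_area;
    ``is_specs`` maps analyte -> spec. Returns the table with a
    ``concentration`` column (nmol per sample-amount unit of the spec).
    """
    required = {"sample_id", "analyte", "area", "is_name", "is_area"}
    missing = required - set(areas.columns)
    if missing:
        raise ValueError(f"peak-area table missing columns {sorted(missing)}")
    out = areas.copy()
    conc = np.empty(len(out))
    for i, row in enumerate(out.itertuples(index=False)):
        spec = is_specs[row.analyte]
        rec = PeakAreaRecord(row.sample_id, row.analyte, row.area, row.is_name, row.is_area)
        conc[i] = concentration_by_is(rec, spec)
    out["concentration"] = conc
    return out
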