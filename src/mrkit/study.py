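"""The emulated study grid: exposures, outcome data sets, and their magnitudes.

These constants describe the study design the synthetic generator emulates:
twelve modifiable risk factors instrumented by genome-wide significant,
LD-pruned variants, tested against an Alzheimer disease case-control outcome
(clinically diagnosed cases), a variant of it excluding one biobank, and a
GWAS-by-proxy variant (parental-dementia report). Instrument counts, LD
thresholds, and variance explained mirror the published summary table; all
summary statistics built from them here are synthetic.
"""

from __future__ import annotations

from dataclasses import dataclass

#: outcome sample sizes (clinically diagnosed cases vs controls)
N_CASE_DIAGNOSED = 39_106
N_CONTROL = 401_577
N_PROXY_CASE = 46_828


@dataclass(frozen=True)
class ExposureDesign:
    name: str
    unit: str
    n_snv: int
    ld_r2_threshold: float
    variance_explained: float  # proportion, not percent
    unit_multiplier: float = 1.0  # reporting scale (e.g. 10 for per-10-mm-Hg)
    trait_type: str = "continuous"
    gwas_n: int = 400_000


#: the twelve-exposure grid (variance for educational attainment is reported
#: as a 12-16% range; its lower bound is carried here)
EXPOSURES: tuple[ExposureDesign, ...] = (
    ExposureDesign("ldl_cholesterol", "SD in mmol/L", 220, 0.001, 0.077, gwas_n=440_546),
    ExposureDesign("triglycerides", "SD in mmol/L", 440, 0.001, 0.103, gwas_n=441_016),
    ExposureDesign("apolipoprotein_b", "SD in g/L", 255, 0.001, 0.092, gwas_n=439_214),
    ExposureDesign("hdl_cholesterol", "SD in mmol/L", 534, 0.001, 0.119, gwas_n=403_943),
    ExposureDesign("apolipoprotein_a1", "SD in g/L", 440, 0.001, 0.101, gwas_n=393_193),
    ExposureDesign("educational_attainment", "years", 3952, 0.1, 0.12, gwas_n=3_037_499),
    ExposureDesign("bmi", "SD per 1 unit", 507, 0.001, 0.06, gwas_n=681_275),
    ExposureDesign("smoking_initiation", "ever vs never smoked regularly", 378, 0.1,
                   0.023, trait_type="binary", gwas_n=1_232_091),
    ExposureDesign("alcohol_consumption", "SD in drinks per week", 99, 0.1, 0.007,
                   gwas_n=941_280),
    ExposureDesign("systolic_bp", "10 mm Hg", 266, 0.1, 0.057, unit_multiplier=10.0,
                   gwas_n=757_601),
    ExposureDesign("diastolic_bp", "10 mm Hg", 346, 0.1, 0.053, unit_multiplier=10.0,
                   gwas_n=757_601),
    ExposureDesign("type_2_diabetes", "log odds", 425, 0.05, 0.19, trait_type="binary",
                   gwas_n=1_114_458),
)

#: multivariable MR adjustment sets chosen to avoid lipid multicollinearity:
#: HDL and TG adjusted for LDL and apoB; HDL and LDL for TG; LDL and TG for
#: HDL and apoA1 (plus SBP/DBP mutually adjusted)
MVMR_GROUPS: dict[str, list[str]] = {
    "hdl_tg_adj_ldl_apob": ["hdl_cholesterol", "triglycerides",
                            "ldl_cholesterol", "apolipoprotein_b"],
    "hdl_ldl_adj_tg": ["hdl_cholesterol", "ldl_cholesterol", "triglycerides"],
    "ldl_tg_adj_hdl_apoa1": ["ldl_cholesterol", "triglycerides",
                             "hdl_cholesterol", "apolipoprotein_a1"],
    "sbp_adj_dbp": ["systolic_bp", "diastolic_bp"],
}

#: behavioral exposures examined in the reverse direction (AD -> risk factor)
REVERSE_TRAITS = ("educational_attainment", "smoking_initiation",
                  "alcohol_consumption", "bmi")


def r2_by_exposure() -> dict[str, float]:
    return {e.name: e.variance_explained for e in EXPOSURES}


#: true odds ratios (per reporting unit) used by the synthetic study grid.
#: These are scenario magnitudes chosen to be directionally plausible for the
#: emulated study; they are generator inputs, not reproduction targets.
SYNTHETIC_TRUE_OR: dict[str, float] = {
    "ldl_cholesterol": 1.00,
    "triglycerides": 0.99,
    "apolipoprotein_b": 1.00,
    "hdl_cholesterol": 1.07,
    "apolipoprotein_a1": 1.04,
    "educational_attainment": 0.83,
    "bmi": 0.95,
    "smoking_initiation": 0.95,
    "alcohol_consumption": 1.00,
    "systolic_bp": 1.02,
    "diastolic_bp": 0.93,
    "type_2_diabetes": 1.00,
}
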