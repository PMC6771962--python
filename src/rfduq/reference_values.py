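"""Published inputs for the TCDD reference-dose derivation chain.

These constants are the printed inputs of the 2012 US EPA IRIS derivation
and of the Seveso cohort studies behind it (Mocarelli sperm quartiles,
Baccarelli maternal-TCDD / neonatal-TSH series).  They parameterize the
worked examples and the default analysis scenarios; everything derived from
them is computed at run time.
"""

from __future__ import annotations

from .rfd_core import (
    Classification,
    DoseUnit,
    IntakeRate,
    Metric,
    SerumConcentration,
    SerumIntakeAnchor,
    UncertaintyFactorSpec,
)
from .teq_accounting import TeqBreakdown

# --- RfD derivation chain (EPA IRIS, 2012) ---------------------------------

#: LOAEL-to-NOAEL extrapolation factor
UF_L = UncertaintyFactorSpec("UF_L", 10.0)
#: human interindividual variability factor
UF_H = UncertaintyFactorSpec("UF_H", 3.0)

#: peak intake at exposure and average intake over the 10-year critical
#: window (sperm endpoint), ng/kg/day; their mean is the POD intake
PEAK_INTAKE = IntakeRate(0.032, DoseUnit.NG_PER_KG_DAY)
WINDOW_INTAKE = IntakeRate(0.0080, DoseUnit.NG_PER_KG_DAY)
POD_INTAKE = IntakeRate(0.020, DoseUnit.NG_PER_KG_DAY)

#: current reference dose, pg/kg/day
CURRENT_RFD = 0.7

# --- serum concentrations (ppt, lipid-adjusted) ----------------------------

#: maternal serum TCDD at which the TSH curve crosses 5 uU/mL (TSH endpoint POD)
TSH_POD_SERUM = SerumConcentration(235.0, Metric.TCDD)
#: sperm-endpoint quartile medians (Q1, Q3, Q4) and exposed-cohort median
Q1_MEDIAN = SerumConcentration(68.0, Metric.TCDD)
Q3_MEDIAN = SerumConcentration(345.0, Metric.TCDD)
Q4_MEDIAN = SerumConcentration(733.0, Metric.TCDD)
COHORT_MEDIAN = SerumConcentration(210.0, Metric.TCDD)

#: anchor pairing the TSH-endpoint serum POD with its kinetic-model intake;
#: used for proportional serum-to-intake scaling throughout
ANCHOR = SerumIntakeAnchor(serum=TSH_POD_SERUM, intake=POD_INTAKE)

# --- TEQ breakdowns (modeled totals; components need not sum) --------------

#: total TEQ associated with the sperm-endpoint median TCDD of 68 ppt
SPERM_TEQ = TeqBreakdown(tcdd=68.0, non_tcdd_teq=72.5, total_teq=140.1)
#: total TEQ associated with the TSH-endpoint serum POD of 235 ppt
TSH_TEQ = TeqBreakdown(tcdd=235.0, non_tcdd_teq=250.0, total_teq=485.0)
#: TSH-cohort mean maternal levels: TCDD-only vs total TEQ
TSH_COHORT_MEAN_TCDD = 18.9
TSH_COHORT_MEAN_TEQ = 41.8

# --- inverse-prediction results at the clinical recall threshold ------------

#: serum TCDD at which the TSH regression reaches 10 uU/mL, with its 95%
#: interval (lower bound; the upper bound exceeds the 1e7 ppt cap)
TSH10_POINT_PPT = 1513.56
TSH10_LOWER_PPT = 151.36
UPPER_CAP_PPT = 1.0e7

# --- sperm-endpoint group summaries (means, million sperm/mL) ---------------

CONTROL_MEAN_SPERM = 72.5
EXPOSED_MEAN_SPERM = 53.6

# --- kinetic-variant TEQ PODs (sensitivity-tree inputs, ng/kg/day) ----------

TEQ_POD_LOW = IntakeRate(0.0180, DoseUnit.NG_PER_KG_DAY)
TEQ_POD_HIGH = IntakeRate(0.0593, DoseUnit.NG_PER_KG_DAY)

#: default UF sets by POD classification
DEFAULT_UF_TABLE = {
    Classification.NOAEL: (UF_H,),
    Classification.LOAEL: (UF_L, UF_H),
}
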