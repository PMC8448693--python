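"""Tidy-table schemas shared by the generators, readers and reducers.

All tables are plain pandas DataFrames in UTF-8 comma-separated CSV with a
header row and period decimal separator.  Column names carry their units
(``_mg_l``, ``_ul``, ``_h``) because unit mix-ups are the dominant failure
mode in transwell bookkeeping.
"""

from __future__ import annotations

# dose-response table
COMPOUND = "compound_id"
CONC = "concentration_mg_l"
VIABILITY = "viability_pct"
BIO_REP = "biological_rep"
TECH_REP = "technical_rep"

# transport table (one row per sampling event)
ANALYTE = "analyte_id"
DIRECTION = "direction"  # AP_to_BL | BL_to_AP
REPLICATE = "replicate"
TIME_H = "time_h"
C_RECEIVER = "conc_receiver_mg_l"
DONOR_C0 = "donor_c0_mg_l"
V_DONOR = "v_donor_ul"
V_RECEIVER = "v_receiver_ul"
V_SAMPLE = "v_sample_ul"

# anisotropy table
SAMPLE_ID = "sample_id"
TREATMENT = "treatment"
I_VV = "i_vv"
I_VH = "i_vh"
I_HV = "i_hv"
I_HH = "i_hh"

# ATPase plate table
CONDITION = "condition"
TEST_ARTICLE = "test_article"
RLU = "rlu"

# generic endpoint table for the stats layer
VALUE = "value"

DIRECTIONS = ("AP_to_BL", "BL_to_AP")
ATPASE_CONDITIONS = ("navo4", "verapamil", "untreated", "test_verapamil", "test_alone")

DOSE_RESPONSE_COLUMNS = (COMPOUND, CONC, VIABILITY, BIO_REP, TECH_REP)
TRANSPORT_COLUMNS = (
    ANALYTE, DIRECTION, REPLICATE, TIME_H, C_RECEIVER,
    DONOR_C0, V_DONOR, V_RECEIVER, V_SAMPLE,
)
ANISOTROPY_COLUMNS = (SAMPLE_ID, TREATMENT, REPLICATE, I_VV, I_VH, I_HV, I_HH)
ATPASE_COLUMNS = (CONDITION, TEST_ARTICLE, CONC, REPLICATE, RLU)
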