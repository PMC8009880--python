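"""Shared vocabulary for the nutrition-stratification pipeline."""

#: The six daily binary nutrition components, in fixed column order:
#: maternal milk, human donor milk, breast-milk fortifier, formula milk,
#: parenteral nutrition, glucose-electrolyte solution.
COMPONENTS = ["MM", "HDM", "BMF", "FM", "PN", "GE"]

#: Enteral components (milk-based feeds given by mouth or tube).
ENTERAL = ["MM", "HDM", "BMF", "FM"]

#: Parenteral components (intravenous nutrition or fluids).
PARENTERAL = ["PN", "GE"]

#: Opaque care-region categories (four-way split of the service geography).
REGIONS = ["North", "Midlands", "London", "South"]

#: Admission covariates derived by curation.
ADMISSION_VARS = [
    "birth_year",
    "ga_weeks",
    "bw_zscore",
    "resuscitation",
    "antenatal_steroids",
    "sex",
    "apgar1",
    "apgar5",
    "apgar10",
    "imd_decile",
    "smoking",
]

#: Outcome variables derived by curation.
OUTCOME_VARS = [
    "mortality",
    "severe_nec",
    "bpd",
    "mm_at_discharge",
    "los",
    "w36_zscore",
    "w36dz",
]
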