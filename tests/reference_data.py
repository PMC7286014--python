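"""Published 6 MV TrueBeam commissioning benchmark values used as fixtures.

These are printed values from a reference small-field commissioning
dataset (jaw-defined fields, 100 cm SSD, 10 cm measurement depth):
dosimetric field widths, per-detector output factors before and after
TRS-483-style correction, intermediate-field-method results, MLC/jaw
ratios and monitor-unit summaries.  They serve as regression inputs: the
package must reproduce each derived column (S_clin, %SD, ratios) from the
raw printed numbers.
"""

# (collimator side at 100 cm, side at 110 cm, cross-plane FWHM,
#  in-plane FWHM, equivalent square side) -- all cm, widths at the
#  110 cm measurement plane
EQUIVALENT_SQUARE_TABLE = [
    (6.0, 6.6, 6.45, 6.63, 6.54),
    (4.0, 4.4, 4.23, 4.43, 4.33),
    (3.0, 3.3, 3.12, 3.32, 3.22),
    (2.0, 2.2, 2.01, 2.20, 2.10),
    (1.0, 1.1, 0.90, 1.11, 1.00),
]

# uncorrected field output factors; %SD pooled over CC01/PFD/EFD only
UNCORRECTED_FOF = {
    6.0: {"CC01": 0.916, "PFD": 0.928, "EFD": 0.908, "EDGE": 0.918, "CC13": 0.922},
    4.0: {"CC01": 0.859, "PFD": 0.875, "EFD": 0.845, "EDGE": 0.863, "CC13": 0.865},
    3.0: {"CC01": 0.824, "PFD": 0.844, "EFD": 0.811, "EDGE": 0.830, "CC13": 0.833},
    2.0: {"CC01": 0.783, "PFD": 0.811, "EFD": 0.771, "EDGE": 0.794, "CC13": 0.790},
    1.0: {"CC01": 0.674, "PFD": 0.736, "EFD": 0.668, "EDGE": 0.720, "CC13": 0.615},
}
UNCORRECTED_PERCENT_SD = {6.0: 1.1, 4.0: 1.7, 3.0: 2.0, 2.0: 2.6, 1.0: 5.4}

# corrected output factors (direct method); the 1 cm row is not published
CORRECTED_FOF = {
    6.0: {"CC01": 0.920, "PFD": 0.928, "EFD": 0.916},
    4.0: {"CC01": 0.865, "PFD": 0.873, "EFD": 0.857},
    3.0: {"CC01": 0.831, "PFD": 0.840, "EFD": 0.824},
    2.0: {"CC01": 0.790, "PFD": 0.800, "EFD": 0.782},
}
CORRECTED_PERCENT_SD = {6.0: 0.7, 4.0: 0.9, 3.0: 1.0, 2.0: 1.1}

# intermediate field method output factors
IFM_FOF = {
    6.0: {"CC01": 0.920, "PFD": 0.919, "EFD": 0.925},
    4.0: {"CC01": 0.865, "PFD": 0.865, "EFD": 0.865},
    3.0: {"CC01": 0.831, "PFD": 0.833, "EFD": 0.832},
    2.0: {"CC01": 0.790, "PFD": 0.792, "EFD": 0.790},
    1.0: {"CC01": 0.686, "PFD": 0.701, "EFD": 0.678},
}
IFM_PERCENT_SD = {6.0: 0.3, 4.0: 0.0, 3.0: 0.1, 2.0: 0.2, 1.0: 1.7}

# uncorrected FOF with MLC-defined vs jaw-defined fields, and printed ratios
MLC_JAW = {
    "CC13": {
        10.0: (1.0, 1.0, 1.000),
        6.0: (0.925, 0.922, 1.003),
        4.0: (0.870, 0.865, 1.006),
        3.0: (0.837, 0.833, 1.005),
        2.0: (0.795, 0.790, 1.006),
    },
    "EDGE": {
        10.0: (1.0, 1.0, 1.000),
        6.0: (0.921, 0.918, 1.003),
        4.0: (0.865, 0.863, 1.003),
        3.0: (0.833, 0.830, 1.004),
        2.0: (0.799, 0.794, 1.006),
    },
}

# calculated monitor-unit summaries (mean MU, SD, printed %SD)
MU_SUMMARIES = [
    ("symmetric 1 cm, uncorrected", 183.0, 11.0, 6.0),
    ("symmetric 1 cm, corrected", 187.0, 4.1, 2.2),
    ("IMRT case 10, uncorrected", 3838.0, 231.0, 6.0),
    ("IMRT case 10, corrected", 3981.0, 100.0, 2.5),
]
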