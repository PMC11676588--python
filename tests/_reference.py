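"""Frozen expected values for the ginsenoside Re reference study.

Transcribed observed/printed values from the published negative-mode
Orbitrap annotation table: per formula group, the [M-H]- and [M+HCOO]-
rows (observed m/z, printed theoretical m/z, printed ppm error, ion
formula, printed RDB) and the printed MS2 fragment assignments.
"""

# (group, adduct, observed, theoretical_printed, ppm_printed, ion_formula, rdb)
ION_ROWS = [
    ("DP-1/2", "[M-H]-", 783.4897, 783.4889, 0.997, "C42H71O13", 7.5),
    ("DP-1/2", "[M+HCOO]-", 829.4921, 829.4944, -2.770, "C43H73O15", 7.5),
    ("DP-3/4", "[M-H]-", 797.5040, 797.5046, -0.713, "C43H73O13", 7.5),
    ("DP-3/4", "[M+HCOO]-", 843.5076, 843.5100, -2.902, "C44H75O15", 7.5),
    ("DP-5/6", "[M-H]-", 765.4802, 765.4784, 2.412, "C42H69O12", 8.5),
    ("DP-5/6", "[M+HCOO]-", 811.4828, 811.4838, -1.273, "C43H71O14", 8.5),
    ("DP-7/8", "[M-H]-", 801.5026, 801.4995, 3.889, "C42H73O14", 6.5),
    ("DP-7/8", "[M+HCOO]-", 847.5050, 847.5050, 0.044, "C43H75O16", 6.5),
    ("DP-9/10", "[M-H]-", 979.5447, 979.5472, -2.574, "C48H83O20", 7.5),
    ("DP-9/10", "[M+HCOO]-", 1025.5494, 1025.5527, -3.218, "C49H85O22", 7.5),
    ("DP-11/12", "[M-H]-", 995.5386, 995.5421, -3.552, "C48H83O21", 7.5),
    ("DP-11/12", "[M+HCOO]-", 1041.5441, 1041.5476, -3.375, "C49H85O23", 7.5),
    ("DP-13", "[M-H]-", 961.5375, 961.5367, 0.877, "C48H81O19", 8.5),
    ("DP-13", "[M+HCOO]-", 1007.5393, 1007.5421, -2.814, "C49H83O21", 8.5),
]

# precursor [M-H]- observed -> list of (fragment m/z, fragment ion formula)
FRAGMENTS = {
    783.4897: [(637.4297, "C36H61O9"), (619.4189, "C36H59O8"),
               (475.3777, "C30H51O4"), (391.2837, "C24H39O4")],
    797.5040: [(651.4446, "C37H63O9"), (633.4341, "C37H61O8"),
               (457.3665, "C30H49O3")],
    765.4802: [(619.4189, "C36H59O8"), (601.4085, "C36H57O7"),
               (457.3669, "C30H49O3")],
    801.5026: [(655.4414, "C36H63O10"), (637.4308, "C36H61O9"),
               (493.3900, "C30H53O5")],
    979.5447: [(817.4913, "C42H73O15"), (799.4808, "C42H71O14"),
               (671.4352, "C36H63O11"), (653.4234, "C36H61O10"),
               (491.3716, "C30H51O5")],
    995.5386: [(919.4866, "C45H75O19"), (757.4344, "C39H65O14"),
               (739.4238, "C39H63O13"), (611.3768, "C33H55O10"),
               (593.3664, "C33H53O9"), (575.3556, "C33H51O8"),
               (431.3148, "C27H43O4")],
    961.5375: [(815.4757, "C42H71O15"), (799.4809, "C42H71O14"),
               (781.4704, "C42H69O13"), (653.4238, "C36H61O10"),
               (635.4134, "C36H59O9"), (491.3716, "C30H51O5")],
}

# neutral losses named in the study's fragmentation discussion
NAMED_LOSSES = {"Glc", "Rha", "H2O", "CH4O", "C6H12", "C3H8O2"}

# condition -> neutral degradant formulas reported in the degradation
# behaviour summary (DP groups per stress condition)
CONDITION_FORMULAS = {
    "acidic_methanolic": {"C42H72O13", "C42H70O12", "C43H74O13"},
    "acidic_aqueous": {"C42H72O13", "C42H70O12", "C42H74O14"},
    "basic": {"C42H72O13", "C42H70O12"},
    "oxidative": {"C48H82O19", "C48H84O20", "C48H84O21"},
}

PARENT = "C48H82O18"

# the seven unique [M-H]- observed masses
UNIQUE_MH_PEAKS = [783.4897, 797.5040, 765.4802, 801.5026,
                   979.5447, 995.5386, 961.5375]

# [M-H]- observed -> neutral formula of the degradant
MH_NEUTRALS = {
    783.4897: "C42H72O13",
    797.5040: "C43H74O13",
    765.4802: "C42H70O12",
    801.5026: "C42H74O14",
    979.5447: "C48H84O20",
    995.5386: "C48H84O21",
    961.5375: "C48H82O19",
}
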