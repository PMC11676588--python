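BEGIN IONS
TITLE=DP1_deglycosylation
PEPMASS=783.4897
CHARGE=1-
CONDITION=acidic_methanolic
637.4297 1.0
619.4189 1.0
475.3777 1.0
391.2837 1.0
END IONS
BEGIN IONS
TITLE=DP3_deglyc_dehydration_methanol
PEPMASS=797.5040
CHARGE=1-
CONDITION=acidic_methanolic
651.4446 1.0
633.4341 1.0
457.3665 1.0
END IONS
BEGIN IONS
TITLE=DP5_deglyc_dehydration
PEPMASS=765.4802
CHARGE=1-
CONDITION=acidic_methanolic
619.4189 1.0
601.4085 1.0
457.3669 1.0
END IONS
BEGIN IONS
TITLE=DP7_deglyc_hydration
PEPMASS=801.5026
CHARGE=1-
CONDITION=acidic_aqueous
655.4414 1.0
637.4308 1.0
493.3900 1.0
END IONS
BEGIN IONS
TITLE=DP9_dioxygenation
PEPMASS=979.5447
CHARGE=1-
CONDITION=oxidative
817.4913 1.0
799.4808 1.0
671.4352 1.0
653.4234 1.0
491.3716 1.0
END IONS
BEGIN IONS
TITLE=DP11_trioxygenation
PEPMASS=995.5386
CHARGE=1-
CONDITION=oxidative
919.4866 1.0
757.4344 1.0
739.4238 1.0
611.3768 1.0
593.3664 1.0
575.3556 1.0
431.3148 1.0
END IONS
BEGIN IONS
TITLE=DP13_monooxygenation
PEPMASS=961.5375
CHARGE=1-
CONDITION=oxidative
815.4757 1.0
799.4809 1.0
781.4704 1.0
653.4238 1.0
635.4134 1.0
491.3716 1.0
END IONS
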