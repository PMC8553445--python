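# Carbon-ion MLC leaf material database (400 MeV/n beam).
#
# lambda_cm is the attenuation length (interaction mean free path) governing
# exponential survival of beam nuclei in the leaf.  For pure tungsten the
# published value is 2.7 cm; for the remaining alloys no attenuation length is
# published and the straggling range is used in its place.  Either may be
# overridden by supplying a user table with an explicit lambda_cm column.
#
# secondary_dose_1e4_sv is reference metadata only (Monte-Carlo secondary
# radiation equivalent dose, units 1e-4 Sv); it is never computed here.
materials:
  - name: W100
    composition: "W:100"
    density_g_cm3: 19.3
    thickness_cm: 6.24
    straggling_range_cm: 2.62
    lambda_cm: 2.7
    secondary_dose_1e4_sv: 4.0467
  - name: W90Cu10
    composition: "W:90 Cu:10"
    density_g_cm3: 17.34
    thickness_cm: 6.7
    straggling_range_cm: 2.85
    secondary_dose_1e4_sv: 3.8475
  - name: W50Cu50
    composition: "W:50 Cu:50"
    density_g_cm3: 12.25
    thickness_cm: 8.32
    straggling_range_cm: 3.66
    secondary_dose_1e4_sv: 3.6138
  - name: Fe100
    composition: "Fe:100"
    density_g_cm3: 7.87
    thickness_cm: 11.0
    straggling_range_cm: 5.0
    secondary_dose_1e4_sv: 2.8194
  - name: Ni100
    composition: "Ni:100"
    density_g_cm3: 8.9
    thickness_cm: 9.6
    straggling_range_cm: 4.3
    secondary_dose_1e4_sv: 2.6964
  - name: Cu100
    composition: "Cu:100"
    density_g_cm3: 8.96
    thickness_cm: 10.0
    straggling_range_cm: 4.5
    secondary_dose_1e4_sv: 2.9716
  - name: Cu59Zn41
    composition: "Cu:59 Zn:41"
    density_g_cm3: 8.4
    thickness_cm: 10.6
    straggling_range_cm: 4.8
    secondary_dose_1e4_sv: 2.9352
  - name: SS304
    composition: "Fe:69.5 Cr:19 Ni:9.5 Mn:2"
    density_g_cm3: 7.92
    thickness_cm: 10.8
    straggling_range_cm: 4.9
    secondary_dose_1e4_sv: 2.8231
  - name: Al100
    composition: "Al:100"
    density_g_cm3: 2.7
    thickness_cm: 27.0
    straggling_range_cm: 13.0
    secondary_dose_1e4_sv: 2.5538
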