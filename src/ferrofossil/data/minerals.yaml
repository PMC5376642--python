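# Mineral reference table for Fe-mineralized microfossil analysis.
# d_spacings in Å; density in g/cm³; fe3_max_fraction is the maximum
# ferric fraction (Fe3+/Fe_total) compatible with the phase as observed.
minerals:
  - name: greenalite
    formula: Si2O5(OH)4Fe3
    density_g_cm3: 3.2
    d_spacings_angstrom: [7.2, 23.0]
    fe3_max_fraction: 0.0045
    source_note: >
      Ferrous phyllosilicate, dominant intra-microfossil phase; diagnostic
      7.2 Å (001) basal spacing and 23 Å superlattice modulation.
  - name: siderite
    formula: FeCO3
    density_g_cm3: 3.96
    d_spacings_angstrom: [3.59, 2.79]
    fe3_max_fraction: null
    source_note: >
      Ferrous carbonate, rhombohedral/rod-shaped crystals in mineralized
      microfossils; ~48 wt% Fe.
  - name: pyrite
    formula: FeS2
    density_g_cm3: 5.01
    d_spacings_angstrom: [3.13, 2.71, 2.42, 1.63]
    fe3_max_fraction: null
    source_note: >
      Ferrous disulfide; occurs as replacement of organic structures in
      discrete patches, not part of quota arithmetic.
  - name: ankerite
    formula: Ca0.5Mg0.25Fe0.2Mn0.05CO3
    density_g_cm3: 3.05
    d_spacings_angstrom: [2.90]
    fe3_max_fraction: null
    source_note: >
      Late diagenetic Ca-Mg-Fe-Mn carbonate; occupancies are a documented
      equal-split placeholder, never used in quota arithmetic.
  - name: quartz
    formula: SiO2
    density_g_cm3: 2.65
    d_spacings_angstrom: [4.26, 3.34]
    fe3_max_fraction: null
    source_note: >
      Chert matrix and FIB-lamella contaminant phase; the fixed host vertex
      of composition mixing lines.
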