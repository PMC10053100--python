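# Default configuration shipped with soilrisk.
#
# reference: regional average background values (ABV) and GB15618-2018
#   screening ("guide") values for agricultural land, mg/kg; MDLs are the
#   instrument method detection limits of the demo survey.
# toxicity / exposure: conventional US-EPA point values and generic
#   distribution stand-ins, NOT site-specific measurements. Review and edit
#   before using for any real assessment.
#
# mn_background has no authoritative default; the value below is a regional
# stand-in and should be replaced for other study areas.

reference:
  mn_background: 710.0
  background:
    Cd: 0.17
    Cr: 86.0
    Cu: 30.7
    Zn: 83.6
    Ni: 37.3
    Pb: 26.7
  guide:
    Cd: 0.60
    Cr: 250.0
    Cu: 100.0
    Zn: 300.0
    Ni: 190.0
    Pb: 170.0
  mdl:
    Cd: 0.09
    Cr: 2.0
    Cu: 0.6
    Zn: 1.0
    Ni: 1.0
    Pb: 2.0
    Mn: 1.0

toxicity:
  # RfD in mg/(kg*d); dermal values follow the oral-RfD x GI-absorption
  # convention where no dermal study value exists.
  rfd:
    Cd: {ingestion: 1.0e-03, dermal: 1.0e-05, inhalation: 1.0e-03}
    Cr: {ingestion: 3.0e-03, dermal: 6.0e-05, inhalation: 2.86e-05}
    Cu: {ingestion: 4.0e-02, dermal: 1.2e-02, inhalation: 4.02e-02}
    Zn: {ingestion: 3.0e-01, dermal: 6.0e-02, inhalation: 3.0e-01}
    Ni: {ingestion: 2.0e-02, dermal: 5.4e-03, inhalation: 2.06e-02}
    Pb: {ingestion: 3.5e-03, dermal: 5.25e-04, inhalation: 3.52e-03}
  # SF in (mg/(kg*d))^-1; only metal-routes with a configured SF enter TCR.
  # The Pb oral slope factor is a literature convention, not an IRIS value.
  sf:
    Cd: {ingestion: 6.1, inhalation: 6.3}
    Cr: {ingestion: 0.5, inhalation: 42.0}
    Ni: {inhalation: 0.84}
    Pb: {ingestion: 8.5e-03}

exposure:
  adult:
    IngR: {dist: lognormal, mean: 100.0, sd: 50.0, min: 10.0, max: 400.0}   # mg/d
    InhR: 20.0            # m3/d
    EFreq: {dist: triangular, min: 180.0, mode: 350.0, max: 365.0}          # d/a
    ED: 24.0              # a
    BW: {dist: normal, mean: 70.0, sd: 14.0, min: 40.0, max: 120.0}         # kg
    AT_nc: 8760.0         # d (= ED * 365)
    AT_ca: 25550.0        # d (= 70 * 365)
    SA: 5700.0            # cm2
    AF: 0.07              # mg/(cm2*d)
    ABS: 1.0e-03
    PEF: 1.36e+09         # m3/kg
  child:
    IngR: {dist: lognormal, mean: 200.0, sd: 100.0, min: 20.0, max: 800.0}
    InhR: 7.6
    EFreq: {dist: triangular, min: 180.0, mode: 350.0, max: 365.0}
    ED: 6.0
    BW: {dist: normal, mean: 15.0, sd: 3.0, min: 8.0, max: 30.0}
    AT_nc: 2190.0
    AT_ca: 25550.0
    SA: 2800.0
    AF: 0.2
    ABS: 1.0e-03
    PEF: 1.36e+09
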