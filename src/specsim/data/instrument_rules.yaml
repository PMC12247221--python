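# Token tables for propagating free-text instrument annotations into
# structured (ionization_method, mass_analyzer, dissociation_method,
# manufacturer) fields. Annotations are lowercased and split on
# non-alphanumeric characters; each token is looked up in every table.
# If two tokens map to *different* values within one category the whole
# annotation is treated as conflicting and all four fields are left missing.
ionization:
  esi: ESI
  electrospray: ESI
  nanoesi: ESI
  nsi: ESI
  apci: APCI
  appi: APPI
  maldi: MALDI
  ei: EI
  ci: CI

mass_analyzer:
  orbitrap: Orbitrap
  exactive: Orbitrap
  qexactive: Orbitrap
  lumos: Orbitrap
  velos: Orbitrap
  tof: TOF
  qtof: TOF
  tripletof: TOF
  maxis: TOF
  synapt: TOF
  impact: TOF
  fticr: FTICR
  iontrap: IonTrap
  lcq: IonTrap
  ltq: IonTrap
  qtrap: IonTrap
  quadrupole: Quadrupole
  qqq: Quadrupole

dissociation:
  cid: CID
  hcd: HCD
  etd: ETD
  ecd: ECD
  uvpd: UVPD

manufacturer:
  thermo: Thermo
  exactive: Thermo
  qexactive: Thermo
  orbitrap: Thermo
  lumos: Thermo
  velos: Thermo
  lcq: Thermo
  ltq: Thermo
  bruker: Bruker
  maxis: Bruker
  impact: Bruker
  agilent: Agilent
  sciex: Sciex
  qtrap: Sciex
  tripletof: Sciex
  waters: Waters
  synapt: Waters
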