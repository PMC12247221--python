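# Curated positive-mode adduct list: canonical form -> total mass offset (Da)
# added to the neutral monoisotopic mass, and the (absolute) charge.
# Theoretical precursor m/z = (monoisotopic_mass + mass_offset) / charge.
# Offsets use a proton mass of 1.00727646 Da and account for the electron
# where relevant ([M]+).
canonical:
  "[M+H]+":        {mass_offset: 1.00727646, charge: 1}
  "[M+Na]+":       {mass_offset: 22.98921778, charge: 1}
  "[M+K]+":        {mass_offset: 38.96315787, charge: 1}
  "[M+NH4]+":      {mass_offset: 18.03382553, charge: 1}
  "[M+H-H2O]+":    {mass_offset: -17.00328843, charge: 1}
  "[M+H-2H2O]+":   {mass_offset: -35.01385332, charge: 1}
  "[M+2H]2+":      {mass_offset: 2.01455292, charge: 2}
  "[M+H+Na]2+":    {mass_offset: 23.99649424, charge: 2}
  "[M+Li]+":       {mass_offset: 7.01545542, charge: 1}
  "[M+CH3OH+H]+":  {mass_offset: 33.03348959, charge: 1}
  "[M+ACN+H]+":    {mass_offset: 42.03382553, charge: 1}
  "[M+2Na-H]+":    {mass_offset: 44.97116556, charge: 1}
  "[M+ACN+Na]+":   {mass_offset: 64.01576685, charge: 1}
  "[M+2ACN+H]+":   {mass_offset: 83.06037460, charge: 1}
  "[M]+":          {mass_offset: -0.00054858, charge: 1}

# Raw spellings seen in public libraries -> canonical form. Lookup is applied
# after whitespace stripping; bracket/charge-suffix variants of canonical
# forms are additionally normalized programmatically.
aliases:
  "M+H": "[M+H]+"
  "M+H+": "[M+H]+"
  "M + H": "[M+H]+"
  "[M+H]": "[M+H]+"
  "[M+H]1+": "[M+H]+"
  "M+Na": "[M+Na]+"
  "[M+Na]": "[M+Na]+"
  "M+K": "[M+K]+"
  "M+NH4": "[M+NH4]+"
  "[M+NH4]": "[M+NH4]+"
  "M+NH4+": "[M+NH4]+"
  "M+H-H2O": "[M+H-H2O]+"
  "[M-H2O+H]+": "[M+H-H2O]+"
  "M-H2O+H": "[M+H-H2O]+"
  "M+2H": "[M+2H]2+"
  "[M+2H]++": "[M+2H]2+"
  "M+Li": "[M+Li]+"
  "M+ACN+H": "[M+ACN+H]+"
  "M+CH3CN+H": "[M+ACN+H]+"
  "[M+CH3CN+H]+": "[M+ACN+H]+"
  "M+CH3OH+H": "[M+CH3OH+H]+"
  "M+": "[M]+"
  "M": "[M]+"
  "Cat": "[M]+"
  "Cat+": "[M]+"
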