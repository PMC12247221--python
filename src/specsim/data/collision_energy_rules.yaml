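# Ordered collision-energy extraction rules. The first rule whose regex
# matches (searched in the compound-name field first, then the instrument
# field) wins; the first capture group is interpreted as eV.
#
# Normalized collision energy (NCE, "%" values) is deliberately NOT
# converted: it is relative to precursor m/z and charge and cannot be mapped
# to eV without extra information, so such annotations yield "missing".
# The list is user-extensible: later entries are only reached when earlier
# ones do not match.
rules:
  - name: explicit_collisionenergy_token
    pattern: 'CollisionEnergy[:=]?\s*(\d+(?:\.\d+)?)(?!\s*%)'
  - name: ev_suffix
    pattern: '(\d+(?:\.\d+)?)\s*eV\b'
  - name: ce_prefix
    pattern: '(?<![A-Za-z])CE[:=\s]\s*(\d+(?:\.\d+)?)(?!\s*%)(?!\s*NCE)'
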