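# ILLUSTRATIVE default damage caps per (tissue, route).
#
# The tiering is principled — vital organs (brain, heart) and the
# drug-clearing organs (liver, kidney) get small caps; colon and small
# intestine are extra-protected under oral delivery; everything else is
# mildly protected — but the exact numbers are placeholders meant to be
# overridden by a user config. Inhalant delivery has no entries here: it
# reuses the local baseline with lung added as a target organ.
baseline:
  tonsil:          {iv: 0.40, local: 0.40, oral: 0.40}
  thymus:          {iv: 0.40, local: 0.40, oral: 0.40}
  spleen:          {iv: 0.40, local: 0.40, oral: 0.40}
  lymph_node:      {iv: 0.40, local: 0.40, oral: 0.40}
  testis:          {iv: 0.40, local: 0.40, oral: 0.40}
  prostate:        {iv: 0.40, local: 0.40, oral: 0.40}
  breast:          {iv: 0.40, local: 0.40, oral: 0.40}
  ovary:           {iv: 0.40, local: 0.40, oral: 0.40}
  placenta:        {iv: 0.40, local: 0.40, oral: 0.40}
  lung:            {iv: 0.40, local: 0.40, oral: 0.40}
  brain:           {iv: 0.20, local: 0.20, oral: 0.20}
  heart:           {iv: 0.20, local: 0.20, oral: 0.20}
  liver:           {iv: 0.10, local: 0.10, oral: 0.10}
  kidney:          {iv: 0.10, local: 0.10, oral: 0.10}
  colon:           {iv: 0.40, local: 0.40, oral: 0.10}
  small_intestine: {iv: 0.40, local: 0.40, oral: 0.10}

gender:
  testis: male_only
  prostate: male_only
  breast: female_only
  ovary: female_only
  placenta: female_only

modifiers:
  conservative_factor: 0.75
  aggressive_factor: 1.5
  local_relaxation_factor: 1.2
  target_protection_factor: 0.25
  extra_protection_factor: 0.5
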