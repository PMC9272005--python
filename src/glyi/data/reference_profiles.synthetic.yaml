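# Synthetic stand-in reference GLYI domain profiles.
#
# The curation pipeline anchors conserved-site checks on two reference
# glyoxalase I domains: a Zn2+-dependent human-type profile (HsGLYI, metal
# sites Q34/E100/H127/E173, GSH sites R38/N104, dimer-interface G106) and a
# Ni2+-dependent E. coli-type profile (EcGLYI, metal sites H5/E56/H74/E122).
# The true GenBank reference sequences are not redistributed here; the
# domain_sequence strings below are SYNTHETIC surrogates (fixed-seed random
# backbones) that carry the catalytically diagnostic residues at the
# documented positions, so every positional rule of the pipeline is
# exercised exactly as with the real references.
profiles:
  HsGLYI:
    metal_type: Zn
    domain_sequence: KSCYTAAMTQNQQKLLWVFNYTNARYMRDPDSCQEKKRTMEMRSKRNWYNFGISKMWDWYGQLLWSKCGGISLNETVHVFKWQVFAKPKKIFQQFQYWAECVGNSGALEDSANQLWMWWHCPNGYKHWYELARQQLSVMIGLIRVLPLLKGIVFPHIRCWMGQYTQHRTMLAEYCNCVSW
    metal_sites: [[34, Q], [100, E], [127, H], [173, E]]
    gsh_sites: [[38, R], [104, N]]
    dimer_site: [106, G]
  EcGLYI:
    metal_type: Ni
    domain_sequence: KLFVHGIFRYNWLNVMGATVRHDQWPMWEDSTLPNKFFEASTVIYPIFKYRAFHQEDWLACFKDWAAQGKHVCHGRSNFGAIVWCYRAKFTIWSPAQKHRHANALGMCIMCMFWGYMPSCFEEPADALWC
    metal_sites: [[5, H], [56, E], [74, H], [122, E]]
    gsh_sites: [[9, R], [78, N]]
    dimer_site: [80, G]
thresholds:
  min_domain_len: 100
  zn_len_threshold: 140
scoring:
  matrix: BLOSUM62
  gap_open: 10.0
  gap_extend: 0.5
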