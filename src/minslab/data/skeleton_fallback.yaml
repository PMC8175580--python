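# Fallback parameter set for the skeleton MinDE model (two-membrane slab).
#
# These are NOT measured rates.  They were calibrated with this package's own
# linear stability analysis so that the slab phase diagram has the canonical
# topology of the reconstituted Min system in flat microchambers:
#   - a low-height band where only the lateral (in-vivo-like) mode is unstable,
#   - a membrane-to-membrane oscillation with critical height H_c ~ 5 um
#     (minimum over E:D in [0.6, 0.9]),
#   - membrane decoupling (membrane-to-bulk regime) at large heights.
# The magnitudes sit in the range reported for reconstituted MinDE kinetics.
kinetics:
  k_D: {value: 0.0215, unit: um/s}        # spontaneous MinD-ATP attachment
  k_dD: {value: 0.2924, unit: um^3/s}     # cooperative MinD recruitment
  k_dE: {value: 0.3939, unit: um^3/s}     # MinE recruitment onto membrane MinD
  k_de: {value: 0.3122, unit: 1/s}         # MinDE hydrolysis/detachment
  lambda_exch: {value: 1.5929, unit: 1/s} # cytosolic ADP->ATP exchange
  D_b: {value: 60.0, unit: um^2/s}        # bulk diffusivity (all bulk species)
  D_m: {value: 0.013, unit: um^2/s}       # membrane diffusivity (m_d, m_de)
totals:
  n_D: {value: 231.1, unit: per_um3}      # ~0.38 uM mean total MinD
  n_E: {value: 173.3, unit: per_um3}      # E:D = 0.75 by default
meta:
  note: calibrated fallback set, not a transcription of measured values
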