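# Named parameter modifiers encoding drug mechanisms and solution changes.
# Each entry maps parameter fields to their new values; modifiers are applied
# on top of a base preset and always produce a freshly validated set.
#
# amrinone      - inhibits the strain-dependent transition before ADP release:
#                 reduced dG_AMDH-AMD (to 25% of the physiological value).
# blebbistatin  - blocks entry into the Pi-release state: kPr' 3000 -> 5 s^-1.
# omecamtiv     - stabilizes the pre-power-stroke state while slowing the
#                 stroke: dG_PiR 1 -> 6 kBT, dG_AMDL-AMDH -> 0 kBT.
# low_atp       - [MgATP] 5 mM -> 0.1 mM.
amrinone_standard:
  dG_HD: 0.5
amrinone_optimized:
  dG_HD: 1.0
blebbistatin:
  kPr_prime: 5.0
omecamtiv_standard:
  dG_PiR: 6.0
  dG_LH: 0.0
omecamtiv_optimized:
  dG_PiR: 6.0
  dG_LH: 0.0
low_atp:
  mgatp: 0.1
# [MgATP] levels of the small-ensemble in vitro FV assays.
mgatp_1.2mM:
  mgatp: 1.2
mgatp_0.5mM:
  mgatp: 0.5
mgatp_0.1mM:
  mgatp: 0.1
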