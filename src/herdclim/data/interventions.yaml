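# Default mitigation-technology schedules (adoption by income group within the
# applicable production systems; efficacy as fractional emission reduction;
# growth scales 2010 emissions to the 2050 baseline).
#
# NOTE: these schedules apply to the bundled SYNTHETIC emissions table, whose
# feedlot total is back-calibrated so the TMR inhibitor cell reproduces 0.8 Mt;
# other potentials are illustrative only until a real GLEAM extract is supplied.
- name: ch4_inhibitor_tmr
  systems: [feedlot]
  efficacy: 0.30
  adoption: {high: 1.0, upper_middle: 1.0, lower_middle: 1.0, low: 1.0}
- name: ch4_inhibitor_grazing_low
  systems: [mixed]
  efficacy: 0.20
  adoption: {high: 0.5, upper_middle: 0.5}
- name: ch4_inhibitor_grazing_high
  systems: [mixed]
  efficacy: 0.30
  adoption: {high: 0.5, upper_middle: 0.5, lower_middle: 0.5}
- name: ch4_vaccine_low
  systems: [feedlot, mixed, extensive]
  efficacy: 0.30
  adoption: {high: 0.5, upper_middle: 0.5}
- name: ch4_vaccine_high
  systems: [feedlot, mixed, extensive]
  efficacy: 0.30
  adoption: {high: 1.0, upper_middle: 1.0, lower_middle: 0.5}
- name: low_emissions_breeding_low
  systems: [feedlot, mixed, extensive]
  efficacy: 0.15
  adoption: {high: 0.5}
- name: low_emissions_breeding_high
  systems: [feedlot, mixed, extensive]
  efficacy: 0.15
  adoption: {high: 0.5, upper_middle: 0.5, lower_middle: 0.5}
- name: seaweed_tmr_low
  systems: [feedlot]
  efficacy: 0.20
  adoption: {high: 1.0, upper_middle: 1.0, lower_middle: 1.0, low: 1.0}
- name: seaweed_tmr_high
  systems: [feedlot]
  efficacy: 0.50
  adoption: {high: 1.0, upper_middle: 1.0, lower_middle: 1.0, low: 1.0}
- name: seaweed_grazing_low
  systems: [mixed]
  efficacy: 0.20
  adoption: {high: 0.5}
- name: seaweed_grazing_high
  systems: [mixed]
  efficacy: 0.50
  adoption: {high: 0.5, upper_middle: 0.5}
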