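shaft_length_mm: 9.0
shaft_width_um: 400.0
shaft_thickness_um: 200.0
tip_taper_um: 0.0
sites:
- id: r1
  role: recording
  face: front
  z_offset_um: 300.0
  diameter_um: 20.0
  lateral_offset_um: 0.0
- id: s0
  role: stimulating
  face: front
  z_offset_um: 550.0
  diameter_um: 100.0
  lateral_offset_um: 0.0
- id: r2
  role: recording
  face: front
  z_offset_um: 800.0
  diameter_um: 20.0
  lateral_offset_um: 0.0
- id: s1
  role: stimulating
  face: front
  z_offset_um: 1050.0
  diameter_um: 100.0
  lateral_offset_um: 0.0
- id: r3
  role: recording
  face: front
  z_offset_um: 1300.0
  diameter_um: 20.0
  lateral_offset_um: 0.0
- id: s2
  role: stimulating
  face: front
  z_offset_um: 1550.0
  diameter_um: 100.0
  lateral_offset_um: 0.0
- id: a1
  role: auxiliary
  face: front
  z_offset_um: 1800.0
  diameter_um: 50.0
  lateral_offset_um: 0.0
- id: r4
  role: recording
  face: front
  z_offset_um: 2050.0
  diameter_um: 20.0
  lateral_offset_um: 0.0
- id: a2
  role: auxiliary
  face: front
  z_offset_um: 2300.0
  diameter_um: 50.0
  lateral_offset_um: 0.0
- id: r5
  role: recording
  face: front
  z_offset_um: 2550.0
  diameter_um: 20.0
  lateral_offset_um: 0.0
- id: a3
  role: auxiliary
  face: front
  z_offset_um: 2800.0
  diameter_um: 50.0
  lateral_offset_um: 0.0
- id: r6
  role: recording
  face: front
  z_offset_um: 3050.0
  diameter_um: 20.0
  lateral_offset_um: 0.0
- id: a4
  role: auxiliary
  face: front
  z_offset_um: 3300.0
  diameter_um: 50.0
  lateral_offset_um: 0.0
- id: r7
  role: recording
  face: front
  z_offset_um: 3550.0
  diameter_um: 20.0
  lateral_offset_um: 0.0
- id: r1
  role: recording
  face: back
  z_offset_um: 300.0
  diameter_um: 20.0
  lateral_offset_um: 0.0
- id: s0
  role: stimulating
  face: back
  z_offset_um: 550.0
  diameter_um: 100.0
  lateral_offset_um: 0.0
- id: r2
  role: recording
  face: back
  z_offset_um: 800.0
  diameter_um: 20.0
  lateral_offset_um: 0.0
- id: s1
  role: stimulating
  face: back
  z_offset_um: 1050.0
  diameter_um: 100.0
  lateral_offset_um: 0.0
- id: r3
  role: recording
  face: back
  z_offset_um: 1300.0
  diameter_um: 20.0
  lateral_offset_um: 0.0
- id: s2
  role: stimulating
  face: back
  z_offset_um: 1550.0
  diameter_um: 100.0
  lateral_offset_um: 0.0
- id: a1
  role: auxiliary
  face: back
  z_offset_um: 1800.0
  diameter_um: 50.0
  lateral_offset_um: 0.0
- id: r4
  role: recording
  face: back
  z_offset_um: 2050.0
  diameter_um: 20.0
  lateral_offset_um: 0.0
- id: a2
  role: auxiliary
  face: back
  z_offset_um: 2300.0
  diameter_um: 50.0
  lateral_offset_um: 0.0
- id: r5
  role: recording
  face: back
  z_offset_um: 2550.0
  diameter_um: 20.0
  lateral_offset_um: 0.0
- id: a3
  role: auxiliary
  face: back
  z_offset_um: 2800.0
  diameter_um: 50.0
  lateral_offset_um: 0.0
- id: r6
  role: recording
  face: back
  z_offset_um: 3050.0
  diameter_um: 20.0
  lateral_offset_um: 0.0
- id: a4
  role: auxiliary
  face: back
  z_offset_um: 3300.0
  diameter_um: 50.0
  lateral_offset_um: 0.0
- id: r7
  role: recording
  face: back
  z_offset_um: 3550.0
  diameter_um: 20.0
  lateral_offset_um: 0.0
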