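# Abductor rig: fixed pelvis, ball hip, femur; three gluteus-medius-like
# elements fanning from the iliac region to the greater trochanter, each with
# its own wrap cylinder over the lateral pelvis brim so the elements keep an
# abduction lever over the swept range of hip ab/adduction. Right-side
# geometry (x anterior, y left, z up); hip ab/adduction is the hip_rx dof
# (adduction positive). Units: m, kg, N.
root: pelvis
subject_mass: 60.0
subject_height: 1.7
floating_base: false
segments:
- name: pelvis
  mass: 10.0
  length: 0.2
- name: femur
  mass: 9.0
  com: [0.0, 0.0, -0.18]
  inertia: [[0.14, 0.0, 0.0], [0.0, 0.14, 0.0], [0.0, 0.0, 0.02]]
  length: 0.42
joints:
- name: hip
  kind: ball
  parent: pelvis
  child: femur
  location_in_parent: [0.0, -0.09, -0.06]
  location_in_child: [0.0, 0.0, 0.0]
wrap_cylinders:
- {name: crest_ant, segment: pelvis, center: [0.03, -0.10, -0.02], axis: [1.0, 0.0, 0.0], radius: 0.028, wrap_side: -1}
- {name: crest_mid, segment: pelvis, center: [0.0, -0.10, -0.02], axis: [1.0, 0.0, 0.0], radius: 0.028, wrap_side: -1}
- {name: crest_post, segment: pelvis, center: [-0.03, -0.10, -0.02], axis: [1.0, 0.0, 0.0], radius: 0.028, wrap_side: -1}
muscles:
- name: abductor_ant
  group: abductor
  strength: 800.0
  nodes:
  - {segment: pelvis, point: [0.035, -0.095, 0.06]}
  - {segment: femur, point: [0.005, -0.042, -0.035]}
  wraps:
  - {cylinder: crest_ant, span: 0}
- name: abductor_mid
  group: abductor
  strength: 800.0
  nodes:
  - {segment: pelvis, point: [0.0, -0.10, 0.06]}
  - {segment: femur, point: [0.0, -0.044, -0.032]}
  wraps:
  - {cylinder: crest_mid, span: 0}
- name: abductor_post
  group: abductor
  strength: 800.0
  nodes:
  - {segment: pelvis, point: [-0.035, -0.095, 0.06]}
  - {segment: femur, point: [-0.005, -0.042, -0.035]}
  wraps:
  - {cylinder: crest_post, span: 0}
markers:
- {name: FEM1, segment: femur, point: [0.03, -0.04, -0.15], weight: 1}
- {name: FEM2, segment: femur, point: [0.0, 0.05, -0.25], weight: 1}
- {name: FEM3, segment: femur, point: [-0.03, -0.02, -0.35], weight: 1}
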