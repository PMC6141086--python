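# Minimal planar rig: a fixed base and one link hanging from a single hinge
# (axis +y), with an antagonist pair of straight-line muscles. Geometry is
# simple enough that moment arms and static equilibrium have closed forms,
# which the unit tests exploit. Units: m, kg, N.
root: base
subject_mass: 10.0
subject_height: 1.0
floating_base: false
segments:
- name: base
  mass: 0.0
  length: 0.5
- name: link
  mass: 2.0
  com: [0.0, 0.0, -0.2]
  inertia: [[0.03, 0.0, 0.0], [0.0, 0.03, 0.0], [0.0, 0.0, 0.001]]
  length: 0.4
joints:
- name: hinge
  kind: hinge
  parent: base
  child: link
  location_in_parent: [0.0, 0.0, 0.0]
  location_in_child: [0.0, 0.0, 0.0]
  axis: [0.0, 1.0, 0.0]
muscles:
- name: flexor
  group: flexor
  strength: 1000.0
  nodes:
  - {segment: base, point: [0.25, 0.0, 0.05]}
  - {segment: link, point: [0.02, 0.0, -0.15]}
- name: extensor
  group: extensor
  strength: 1000.0
  nodes:
  - {segment: base, point: [-0.25, 0.0, 0.05]}
  - {segment: link, point: [-0.02, 0.0, -0.15]}
markers:
- {name: LNK1, segment: link, point: [0.03, 0.0, -0.10], weight: 1}
- {name: LNK2, segment: link, point: [0.0, 0.04, -0.30], weight: 1}
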