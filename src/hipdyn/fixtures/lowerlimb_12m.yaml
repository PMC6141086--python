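# Toy right lower limb: pelvis + femur + shank + talus + foot (12 dofs),
# 12 muscle elements spanning hip, knee and ankle, including two biarticular
# hamstring-like elements with individual posterior-condyle wrap cylinders and
# an ilio-psoas element wrapped over the anterior hip. World frame: x anterior,
# y left, z up; right-leg geometry. The hip joint centre in the pelvis frame is
# pinned to the pelvic-landmark regression of the ASIS/PSIS markers below
# (width 0.240 m, depth 0.182 m, leg length 0.94 m). All coordinates in metres,
# masses in kg, strengths in N.
root: pelvis
subject_mass: 75.0
subject_height: 1.72
floating_base: true
segments:
- name: pelvis
  mass: 11.0
  com:
  - 0
  - 0
  - 0
  inertia:
  - - 0.08
    - 0
    - 0
  - - 0
    - 0.08
    - 0
  - - 0
    - 0
    - 0.06
  length: 0.2
- name: femur
  mass: 10.0
  com:
  - 0
  - 0
  - -0.18
  inertia:
  - - 0.15
    - 0
    - 0
  - - 0
    - 0.15
    - 0
  - - 0
    - 0
    - 0.025
  length: 0.42
- name: shank
  mass: 4.0
  com:
  - 0
  - 0
  - -0.17
  inertia:
  - - 0.055
    - 0
    - 0
  - - 0
    - 0.055
    - 0
  - - 0
    - 0
    - 0.007
  length: 0.4
- name: talus
  mass: 0.1
  com:
  - 0
  - 0
  - -0.01
  inertia:
  - - 0.0001
    - 0
    - 0
  - - 0
    - 0.0001
    - 0
  - - 0
    - 0
    - 0.0001
  length: 0.04
- name: foot
  mass: 1.1
  com:
  - 0.06
  - 0
  - -0.02
  inertia:
  - - 0.004
    - 0
    - 0
  - - 0
    - 0.004
    - 0
  - - 0
    - 0
    - 0.004
  length: 0.08
joints:
- name: hip
  kind: ball
  parent: pelvis
  child: femur
  location_in_parent:
  - 0.0263
  - -0.0974
  - -0.0831
  location_in_child:
  - 0
  - 0
  - 0
- name: knee
  kind: hinge
  parent: femur
  child: shank
  location_in_parent:
  - 0
  - 0
  - -0.42
  location_in_child:
  - 0
  - 0
  - 0
  axis:
  - 0
  - 1
  - 0
- name: talocrural
  kind: hinge
  parent: shank
  child: talus
  location_in_parent:
  - 0
  - 0
  - -0.4
  location_in_child:
  - 0
  - 0
  - 0
  axis:
  - 0
  - 1
  - 0
- name: subtalar
  kind: hinge
  parent: talus
  child: foot
  location_in_parent:
  - 0
  - 0
  - -0.03
  location_in_child:
  - 0
  - 0
  - 0
  axis:
  - 1
  - 0
  - 0
wrap_cylinders:
- name: psoas_cyl
  segment: pelvis
  center:
  - 0.0263
  - -0.0974
  - -0.0831
  axis:
  - 0
  - 1
  - 0
  radius: 0.035
  wrap_side: -1
- name: gmax_cyl
  segment: pelvis
  center:
  - -0.055
  - -0.075
  - -0.055
  axis:
  - 0
  - 1
  - 0
  radius: 0.045
  wrap_side: -1
- name: condyle_med
  segment: femur
  center:
  - -0.022
  - 0.018
  - -0.415
  axis:
  - 0
  - 1
  - 0
  radius: 0.024
  wrap_side: 1
- name: condyle_lat
  segment: femur
  center:
  - -0.022
  - -0.02
  - -0.415
  axis:
  - 0
  - 1
  - 0
  radius: 0.024
  wrap_side: 1
muscles:
- name: iliopsoas
  group: iliopsoas
  strength: 1600
  nodes:
  - segment: pelvis
    point:
    - 0.055
    - -0.05
    - 0.03
  - segment: femur
    point:
    - -0.005
    - 0.018
    - -0.07
  wraps:
  - cylinder: psoas_cyl
    span: 0
- name: glut_max
  group: glut_max
  strength: 1800
  nodes:
  - segment: pelvis
    point:
    - -0.09
    - -0.055
    - 0.0
  - segment: femur
    point:
    - -0.012
    - -0.012
    - -0.08
  wraps:
  - cylinder: gmax_cyl
    span: 0
- name: glut_med_ant
  group: glut_med
  strength: 1200
  nodes:
  - segment: pelvis
    point:
    - 0.035
    - -0.105
    - 0.025
  - segment: femur
    point:
    - 0.018
    - -0.036
    - -0.018
- name: glut_med_post
  group: glut_med
  strength: 1200
  nodes:
  - segment: pelvis
    point:
    - -0.04
    - -0.095
    - 0.02
  - segment: femur
    point:
    - -0.006
    - -0.04
    - -0.03
- name: adductor
  group: adductor
  strength: 1500
  nodes:
  - segment: pelvis
    point:
    - 0.035
    - -0.025
    - -0.095
  - segment: femur
    point:
    - 0.0
    - 0.018
    - -0.2
- name: ham_med
  group: hamstrings
  strength: 1800
  nodes:
  - segment: pelvis
    point:
    - -0.05
    - -0.062
    - -0.1
  - segment: shank
    point:
    - 0.008
    - 0.018
    - -0.06
  wraps:
  - cylinder: condyle_med
    span: 0
- name: ham_lat
  group: hamstrings
  strength: 1800
  nodes:
  - segment: pelvis
    point:
    - -0.05
    - -0.072
    - -0.1
  - segment: shank
    point:
    - 0.008
    - -0.022
    - -0.06
  wraps:
  - cylinder: condyle_lat
    span: 0
- name: rectus_fem
  group: quadriceps
  strength: 1800
  nodes:
  - segment: pelvis
    point:
    - 0.06
    - -0.085
    - -0.02
  - segment: femur
    point:
    - 0.05
    - 0.0
    - -0.3
  - segment: shank
    point:
    - 0.04
    - 0.0
    - -0.06
- name: vastus
  group: quadriceps
  strength: 3200
  nodes:
  - segment: femur
    point:
    - 0.045
    - 0.0
    - -0.18
  - segment: femur
    point:
    - 0.05
    - 0.0
    - -0.3
  - segment: shank
    point:
    - 0.04
    - 0.0
    - -0.06
- name: tibialis_ant
  group: tibialis_ant
  strength: 900
  nodes:
  - segment: shank
    point:
    - 0.032
    - 0.005
    - -0.16
  - segment: foot
    point:
    - 0.09
    - 0.012
    - 0.0
- name: soleus
  group: triceps_surae
  strength: 3200
  nodes:
  - segment: shank
    point:
    - -0.025
    - 0.0
    - -0.1
  - segment: foot
    point:
    - -0.062
    - 0.0
    - -0.015
- name: tfl
  group: tfl
  strength: 700
  nodes:
  - segment: pelvis
    point:
    - 0.055
    - -0.11
    - 0.0
  - segment: femur
    point:
    - 0.005
    - -0.047
    - -0.045
  - segment: femur
    point:
    - -0.005
    - -0.043
    - -0.11
markers:
- name: RASI
  segment: pelvis
  point:
  - 0.08
  - -0.12
  - 0.0
  weight: 10
  bony: true
- name: LASI
  segment: pelvis
  point:
  - 0.08
  - 0.12
  - 0.0
  weight: 10
  bony: true
- name: RPSI
  segment: pelvis
  point:
  - -0.1
  - -0.05
  - 0.03
  weight: 10
  bony: true
- name: LPSI
  segment: pelvis
  point:
  - -0.1
  - 0.05
  - 0.03
  weight: 10
  bony: true
- name: THI1
  segment: femur
  point:
  - 0.02
  - -0.05
  - -0.15
  weight: 1
- name: THI2
  segment: femur
  point:
  - 0.05
  - 0.03
  - -0.25
  weight: 1
- name: LKNE
  segment: femur
  point:
  - 0.0
  - -0.06
  - -0.42
  weight: 10
  bony: true
- name: TIB1
  segment: shank
  point:
  - 0.03
  - -0.04
  - -0.12
  weight: 1
- name: TIB2
  segment: shank
  point:
  - 0.01
  - 0.04
  - -0.22
  weight: 1
- name: LANK
  segment: shank
  point:
  - 0.0
  - -0.045
  - -0.4
  weight: 10
  bony: true
- name: HEEL
  segment: foot
  point:
  - -0.06
  - 0.0
  - -0.03
  weight: 10
  bony: true
- name: TOE
  segment: foot
  point:
  - 0.17
  - 0.012
  - -0.04
  weight: 1
- name: MET5
  segment: foot
  point:
  - 0.1
  - -0.045
  - -0.04
  weight: 1
# Analysis conventions for this model: the femur-based clinical frame is
# built from the hip and knee centres (proximo-distal along the mechanical
# axis) with the femur +x axis as the anterior reference; recruitment
# balances the hip ball, knee and talocrural dofs (the subtalar hinge is
# locked in the gait profiles and its small net moment is left to passive
# structures).
analysis:
  # columns of pelvis_axes express the landmark-regression frame
  # (x anterior, y superior, z right) in the pelvis segment frame
  pelvis_axes: [[1.0, 0.0, 0.0], [0.0, 0.0, -1.0], [0.0, 1.0, 0.0]]
  hip_joint: hip
  knee_joint: knee
  femur_segment: femur
  pelvis_segment: pelvis
  foot_segment: foot
  anterior_axis: [1.0, 0.0, 0.0]
  harrington_side: right
  constrained_dofs: [hip_rx, hip_ry, hip_rz, knee_angle, talocrural_angle]
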