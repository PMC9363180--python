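# Default anthropometry and muscle architecture for the planar hip model
# (170 cm / 70 kg reference subject).  Lengths in m, areas in cm^2, angles
# in degrees.  Attachment coordinates are pelvis-frame positions relative to
# the hip joint center; the third coordinate is dropped in the sagittal
# projection.
body_height: 1.70
body_mass: 70.0
thigh_link: 0.434
single_joint_insertion: 0.210
muscles:
  iliopsoas:
    attachment: [0.026, 0.022, 0.005]
    moment_arm: 0.028
    pcsa_cm2: 28.9
    pennation_deg: 13.9
  rectus_femoris:
    attachment: [0.041, -0.004, -0.036]
    moment_arm: 0.050
    knee_moment_arm: 0.040   # modeling default for the knee-level work proxy
    pcsa_cm2: 34.8
    pennation_deg: 12.4
  gluteus_maximus:
    attachment: [-0.088, 0.066, -0.039]
    moment_arm: 0.060
    pcsa_cm2: 46.8
    pennation_deg: 21.0
  hamstring:
    # Synthetic ischial-tuberosity-like origin: the source parameter set
    # gives only moment arms for the hamstring group, so this coordinate is
    # a package modeling default, not a measured value.
    attachment: [-0.060, -0.040, 0.020]
    moment_arm: 0.028
    knee_moment_arm: 0.028
    pcsa_cm2: 73.0
    pennation_deg: 11.3
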