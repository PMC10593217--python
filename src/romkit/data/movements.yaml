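# Built-in movement registry: the 11 standing range-of-motion evaluation
# movements, the subject's recording orientation relative to the camera,
# and the two segment endpoints per device dialect.
#
# Endpoint syntax: a list of one marker (the endpoint IS that landmark) or
# two markers (the endpoint is the midpoint of the two).  For bilateral
# movements a marker may be written "LEFT/RIGHT"; the registry expands the
# row into a left and a right sided variant.
movements:
  - name: Back Flexion and Extension
    orientation: lateral_sagittal
    endpoints:
      pose33:
        joint1: [LHIP]
        joint2: [LSHO]
      mocap39:
        joint1: [LPSI]
        joint2: [C7]
  - name: Back Lateral Flexion
    orientation: anterior_coronal
    endpoints:
      pose33:
        joint1: [LHIP]
        joint2: [LSHO]
      mocap39:
        joint1: [LPSI]
        joint2: [C7]
  - name: Trunk Rotation
    orientation: anterior_coronal
    endpoints:
      pose33:
        joint1: [LSHO]
        joint2: [RSHO]
      mocap39:
        joint1: [LSHO]
        joint2: [RSHO]
  - name: Neck Flexion and Extension
    orientation: lateral_sagittal
    endpoints:
      pose33:
        joint1: [LSHO, RSHO]
        joint2: [NOSE]
      mocap39:
        joint1: [LSHO, RSHO]
        joint2: [LFHD, LBHD]
  - name: Neck Lateral Bending
    orientation: lateral_sagittal
    endpoints:
      pose33:
        joint1: [LSHO, RSHO]
        joint2: [NOSE]
      mocap39:
        joint1: [LSHO, RSHO]
        joint2: [LFHD, LBHD]
  - name: Neck Rotation
    orientation: anterior_coronal
    endpoints:
      pose33:
        joint1: [LEAR]
        joint2: [REAR]
      mocap39:
        joint1: [LFHD, LBHD]
        joint2: [RFHD, RBHD]
  - name: Shoulder Adduction and Abduction
    orientation: anterior_coronal
    endpoints:
      pose33:
        joint1: [LSHO/RSHO]
        joint2: [LELB/RELB]
      mocap39:
        joint1: [LSHO/RSHO]
        joint2: [LELB/RELB]
  - name: Shoulder Flexion and Extension
    orientation: anterior_coronal
    endpoints:
      pose33:
        joint1: [LSHO/RSHO]
        joint2: [LELB/RELB]
      mocap39:
        joint1: [LSHO/RSHO]
        joint2: [LELB/RELB]
  - name: Elbow Flexion
    orientation: lateral_sagittal
    endpoints:
      pose33:
        joint1: [LELB/RELB]
        joint2: [LWRI/RWRI]
      mocap39:
        joint1: [LELB/RELB]
        joint2: [LWRA/RWRA, LWRB/RWRB]
  - name: Hip Flexion and Extension
    orientation: lateral_sagittal
    endpoints:
      pose33:
        joint1: [LHIP/RHIP]
        joint2: [LKNE/RKNE]
      mocap39:
        joint1: [LASI/RASI]
        joint2: [LKNE/RKNE]
  - name: Hip Adduction and Abduction
    orientation: anterior_coronal
    endpoints:
      pose33:
        joint1: [LHIP/RHIP]
        joint2: [LKNE/RKNE]
      mocap39:
        joint1: [LASI/RASI]
        joint2: [LKNE/RKNE]
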