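# Landmark vocabularies for the two supported device dialects.
#
# pose33: the 33 body landmarks inferred by single-camera pose estimation
#   (acronym-style names; LEAR/REAR = ears, LWRI/RWRI = wrists, ...).
#   Every landmark carries a per-frame visibility index in [0, 1].
#
# mocap39: the conventional 39-marker full-body optical motion-capture
#   set (Helen Hayes style names: LFHD = left front head, LPSI = left
#   posterior superior iliac spine, ...). No visibility channel.
pose33:
  - NOSE
  - LEYEI
  - LEYE
  - LEYEO
  - REYEI
  - REYE
  - REYEO
  - LEAR
  - REAR
  - LMTH
  - RMTH
  - LSHO
  - RSHO
  - LELB
  - RELB
  - LWRI
  - RWRI
  - LPNK
  - RPNK
  - LIDX
  - RIDX
  - LTHM
  - RTHM
  - LHIP
  - RHIP
  - LKNE
  - RKNE
  - LANK
  - RANK
  - LHEE
  - RHEE
  - LFTI
  - RFTI
mocap39:
  - LFHD
  - RFHD
  - LBHD
  - RBHD
  - C7
  - T10
  - CLAV
  - STRN
  - RBAK
  - LSHO
  - LUPA
  - LELB
  - LFRM
  - LWRA
  - LWRB
  - LFIN
  - RSHO
  - RUPA
  - RELB
  - RFRM
  - RWRA
  - RWRB
  - RFIN
  - LASI
  - RASI
  - LPSI
  - RPSI
  - LTHI
  - LKNE
  - LTIB
  - LANK
  - LHEE
  - LTOE
  - RTHI
  - RKNE
  - RTIB
  - RANK
  - RHEE
  - RTOE
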