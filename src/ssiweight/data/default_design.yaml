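n_sessions: 3
n_participants: 31
sequences:
- - S3
  - S5
  - L7
  - L3
  - L4
  - M2
  - M3
  - S4
  - M6
  - M4
  - S2
  - M5
  - S1
  - L5
  - L6
- - M3
  - S2
  - L4
  - L7
  - L3
  - S5
  - S4
  - S3
  - M4
  - S1
  - M5
  - M2
  - L6
  - L5
  - M6
- - L3
  - L6
  - L5
  - M3
  - S3
  - S5
  - S2
  - L7
  - M5
  - L4
  - S4
  - M6
  - M2
  - S1
  - M4
boxes:
- box_id: S1
  size_class: small
  side_cm: 6.8
  height_cm: 7.4
  weight_g: 114.0
  weight_rank: 1
- box_id: S2
  size_class: small
  side_cm: 6.8
  height_cm: 7.4
  weight_g: 235.0
  weight_rank: 2
- box_id: S3
  size_class: small
  side_cm: 6.8
  height_cm: 7.4
  weight_g: 455.0
  weight_rank: 3
- box_id: S4
  size_class: small
  side_cm: 6.8
  height_cm: 7.4
  weight_g: 649.0
  weight_rank: 4
- box_id: S5
  size_class: small
  side_cm: 6.8
  height_cm: 7.4
  weight_g: 1140.0
  weight_rank: 5
- box_id: M2
  size_class: medium
  side_cm: 12.3
  height_cm: 12.8
  weight_g: 235.0
  weight_rank: 2
- box_id: M3
  size_class: medium
  side_cm: 12.3
  height_cm: 12.8
  weight_g: 455.0
  weight_rank: 3
- box_id: M4
  size_class: medium
  side_cm: 12.3
  height_cm: 12.8
  weight_g: 649.0
  weight_rank: 4
- box_id: M5
  size_class: medium
  side_cm: 12.3
  height_cm: 12.8
  weight_g: 1140.0
  weight_rank: 5
- box_id: M6
  size_class: medium
  side_cm: 12.3
  height_cm: 12.8
  weight_g: 2199.0
  weight_rank: 6
- box_id: L3
  size_class: large
  side_cm: 22.4
  height_cm: 22.8
  weight_g: 455.0
  weight_rank: 3
- box_id: L4
  size_class: large
  side_cm: 22.4
  height_cm: 22.8
  weight_g: 649.0
  weight_rank: 4
- box_id: L5
  size_class: large
  side_cm: 22.4
  height_cm: 22.8
  weight_g: 1140.0
  weight_rank: 5
- box_id: L6
  size_class: large
  side_cm: 22.4
  height_cm: 22.8
  weight_g: 2199.0
  weight_rank: 6
- box_id: L7
  size_class: large
  side_cm: 22.4
  height_cm: 22.8
  weight_g: 3808.0
  weight_rank: 7
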