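# Catalog of clinical gait/balance tests: which parameters feed each item.
#
# Schema: {test_id: [{item: n, params: [...]}]}
# Parameter vocabulary (long names; the typeset source table abbreviates
# both Speed and Stride as "S", disambiguated here by column position):
#   speed, trajectory, trunk_swing, separation_of_arms, separation_of_heels,
#   stride, trunk_tilt, hand_separation, arm_support
#
# The mapping is the minimum parameter set applicable to each item; it is
# expected to be refined by clinicians, hence shipped as data rather than
# code.  Cells marked "per table, unverified" reproduce the printed table
# where no prose cross-check exists.
version: 1
tinetti:
  - {item: 1, params: [trunk_tilt]}                      # seated balance
  - {item: 2, params: [trunk_tilt, arm_support]}         # per table, unverified
  - {item: 3, params: [trunk_tilt]}
  - {item: 4, params: [trunk_swing, separation_of_heels]}
  - {item: 5, params: [trunk_swing, separation_of_heels]}
  - {item: 6, params: [trunk_swing, separation_of_heels]}
  - {item: 7, params: [trunk_swing, separation_of_heels]}
  - {item: 8, params: [trajectory, trunk_swing, separation_of_heels, stride]}  # per table, unverified
  - {item: 9, params: [trunk_swing, trunk_tilt, arm_support]}  # sitting down
  - {item: 10, params: [trajectory]}
  - {item: 11, params: [stride]}
  - {item: 12, params: [stride]}
  - {item: 13, params: [stride]}
  - {item: 14, params: [trajectory]}
  - {item: 15, params: [trajectory, trunk_swing, separation_of_arms]}
  - {item: 16, params: [separation_of_heels]}
berg:
  - {item: 1, params: [trunk_tilt, arm_support]}         # sit to stand
  - {item: 2, params: [trunk_swing]}
  - {item: 3, params: [trunk_tilt, arm_support]}
  - {item: 4, params: [trunk_tilt, arm_support]}
  - {item: 5, params: [trunk_tilt, arm_support]}
  - {item: 6, params: [trunk_swing]}
  - {item: 7, params: [trunk_swing, separation_of_heels]}
  - {item: 8, params: [separation_of_arms, trunk_tilt]}  # functional reach
  - {item: 9, params: [trunk_tilt]}
  - {item: 10, params: [trunk_swing]}
  - {item: 11, params: [speed, trajectory]}
  - {item: 12, params: [trunk_swing, stride]}
  - {item: 13, params: [separation_of_heels, stride]}
  - {item: 14, params: [trunk_swing, stride]}
dgi:
  - {item: 1, params: [speed, trajectory, trunk_swing]}
  - {item: 2, params: [speed, trajectory, trunk_swing]}
  - {item: 3, params: [speed, trajectory, trunk_swing]}
  - {item: 4, params: [speed, trajectory, trunk_swing]}
  - {item: 5, params: [speed, trajectory, trunk_swing, stride]}
  - {item: 6, params: [speed, trajectory, trunk_swing]}
  - {item: 7, params: [speed, trajectory, trunk_swing, stride]}
  - {item: 8, params: [stride, arm_support]}             # per table, unverified
tug:
  - {item: 1, params: [speed, trajectory]}
frt:
  - {item: 1, params: [trunk_tilt, hand_separation]}
fsst:
  - {item: 1, params: [speed, trajectory, separation_of_heels]}
sls:
  - {item: 1, params: [separation_of_heels]}
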