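# Example study protocol: brief training bouts for each dictionary activity
# followed by a mixed test course.  Durations are in seconds; `label`
# overrides the emitted ground-truth label when an activity variant (e.g.
# slow walking) should still count as its parent activity.
rate_h: 10
orientation:
  upside_down: true
  screen_to_leg: true
segments:
  # training bouts
  - {activity: stand, duration: 10}
  - {activity: walk, duration: 15}
  - {activity: stairsUp, duration: 8}
  - {activity: stairsDown, duration: 8}
  - {activity: standToSit, duration: 1.5}
  - {activity: sit, duration: 10}
  - {activity: sitToStand, duration: 1.5}
  - {activity: stand, duration: 3}
  - {activity: standToSit, duration: 1.5}
  - {activity: sit, duration: 10}
  - {activity: sitToStand, duration: 1.5}
  # test course
  - {activity: stand, duration: 10}
  - {activity: walk, duration: 40}
  - {activity: stairsUp, duration: 25}
  - {activity: stairsDown, duration: 25}
  - {activity: walk, duration: 20}
  - {activity: standToSit, duration: 1.5}
  - {activity: sit, duration: 20}
  - {activity: sitToStand, duration: 1.5}
  - {activity: stand, duration: 5}
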