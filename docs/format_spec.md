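# Session file formats (v1)

One recorded or simulated session is a directory with three plain-text
files. Delimited text was chosen over binary containers because no
standard exists for this modality mix and diffable files simplify
testing and review. Times are seconds from session start; positions
are meters in the robot base frame; EMG is millivolts.

## trajectory.csv

```
# reachmetrics trajectory v1; sample_rate_hz=100; units=s,m
time,x,y,z
0.000000000,0.383200000,-0.033600000,0.266400000
...
```

* Line 1: versioned header comment carrying the nominal sample rate.
* Uniform, strictly increasing time grid; successive deltas may deviate
  from `1/sample_rate_hz` by at most 1 %.
* At least 2 samples. Floats are written with 9 decimal places;
  read(write(x)) round-trips to 1e-9.

## emg.csv

Same conventions; columns are `time` plus one column per muscle label.
Labels must be unique; the default channel set is `biceps brachii`,
`triceps brachii`, `upper trapezius`, `anterior deltoid`,
`posterior deltoid`.

```
# reachmetrics emg v1; sample_rate_hz=1000; units=s,mV
time,biceps brachii,triceps brachii,upper trapezius,anterior deltoid,posterior deltoid
```

## events.jsonl

JSON-lines: a header record, then one record per movement segment
(mixed field types rule out flat CSV here).

```
{"format": "reachmetrics-events", "version": 1}
{"index": 0, "appear": 1.0, "disappear": 4.52, "target": [0.41, -0.03, 0.27],
 "ball_mode": "big", "phase": "baseline", "feedback": "none"}
```

* `index`: consecutive from 0, chronological.
* `appear < disappear`; intervals pairwise disjoint.
* `ball_mode ∈ {big, small}`; `phase ∈ {baseline, training, retention}`;
  `feedback ∈ {none, TV, TH, TM}` (retention blocks carry the feedback
  label of the training block they follow; baseline carries `none`).

Readers reject rather than repair: any violation raises a format error
naming the file and line.
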