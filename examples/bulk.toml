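# Bulk-solution study conditions: BR 33.7%, CFR 0.45%, 1 ps snapshots.
[global]
temperature = 277.0

[generate]
regime = "bulk"
n_steps = 100000
dt = 1.0

[populations]
block_count = 5

[csar]
baseline_days = 14.0
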