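# anchor=forepaw_swing_time
# positive_group=uninjured
parameter,weight
forepaw_swing_time,1
forepaw_stride_length,0.0015
forepaw_duty_cycle,0.0005
hindpaw_bos,-0.0103
regularity_index,0.00002
body_speed,0.001
ab_sequence,-0.0001
forepaw_max_contact_at,-0.0015
hindpaw_stride_length,-0.0017
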