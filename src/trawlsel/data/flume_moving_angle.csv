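flow_velocity_kt,moving_angle_deg,sem_deg
1.0,21.0,0.08
1.2,21.6,0.16
1.4,22.0,0.07
1.6,22.5,0.12
1.8,22.6,0.15
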