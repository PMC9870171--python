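haul_id,subsample,amplitude_ratio,period_s
2,1,0.13,7.7
2,2,0.08,10.5
2,3,0.14,9.1
2,4,0.24,20.7
3,1,0.07,6.8
3,2,0.05,4.6
3,3,0.19,10.8
4,1,0.04,4.0
4,2,0.08,8.2
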