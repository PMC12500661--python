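criterion_id,arm,estimate,ci_low,ci_high,k
kps,experimental,-9.38,-10.91,-7.86,4
kps,control,-3.63,-5.35,-1.92,4
ca211,experimental,4.98,4.24,5.72,2
ca211,control,3.89,3.19,4.60,2
cea,experimental,9.96,8.68,11.25,2
cea,control,7.58,6.50,8.67,2
fatigue,experimental,14.58,11.17,17.98,2
fatigue,control,3.70,0.29,7.11,2
gi_adverse,experimental,0.44,0.31,0.57,2
gi_adverse,control,0.76,0.62,0.86,2
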