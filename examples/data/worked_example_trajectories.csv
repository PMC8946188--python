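lesion_id,patient_id,time_months,volume_cm3
TE-01,P01,-0.3,10.0
TE-01,P01,3.0,10.0
TE-01,P01,6.0,25.0
TE-01,P01,9.0,11.0
TE-01,P01,21.0,9.0
PD-01,P02,-0.3,8.0
PD-01,P02,3.0,8.2
PD-01,P02,9.0,9.6
PD-01,P02,15.0,12.0
PD-01,P02,21.0,14.5
SD-01,P03,-0.3,5.0
SD-01,P03,3.0,4.8
SD-01,P03,9.0,4.5
SD-01,P03,21.0,4.4
MR-01,P04,-0.3,12.0
MR-01,P04,3.0,10.0
MR-01,P04,9.0,8.0
MR-01,P04,21.0,6.0
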