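# Independent validation population (pooled means/SDs) with the published model values.
# provenance: pooled from 8 clinical studies not used for model tuning.
condition,cohort,variable,units,mean,sd,n,model_paper
rest,htxr,HR,bpm,90.8,11,253,93.8
rest,htxr,CO,L/min,5.5,1,55,5.2
rest,htxr,MAP,mmHg,91.1,10.7,55,91.5
rest,htxr,SV,mL,59.5,9.9,55,55.4
rest,htxr,SVR,mmHg.s/mL,0.95,0.23,145,1.08
rest,htxr,LVEDVI,mL/m^2,50,15,22,51.9
rest,healthy,HR,bpm,71.3,10.2,223,69.5
rest,healthy,CO,L/min,4.9,1.3,223,5.6
rest,healthy,MAP,mmHg,94,11.7,223,86.7
rest,healthy,SV,mL,68.8,14.9,223,82
rest,healthy,SVR,mmHg.s/mL,1.17,0.38,223,0.97
peak,htxr,HR,bpm,127,17,94,133.9
peak,htxr,CO,L/min,10.8,4.3,32,13
peak,htxr,MAP,mmHg,105.1,12.5,33,116.3
peak,htxr,SV,mL,87.8,22.1,55,95.7
peak,htxr,SVR,mmHg.s/mL,0.61,0.13,33,0.57
peak,htxr,LVEDVI,mL/m^2,59,19,20,75.8
peak,htxr,MTP,kpm/min,584,10,123,
peak,healthy,HR,bpm,168,15,10,169
peak,healthy,CO,L/min,20.8,10,10,19.8
peak,healthy,MAP,mmHg,123,9.5,10,133.7
peak,healthy,SV,mL,123,35.6,10,115.1
peak,healthy,SVR,mmHg.s/mL,0.35,0.13,10,0.45
peak,healthy,MTP,kpm/min,1211,288,10,
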