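# Pooled literature means/SDs (modeling population) with the published model values.
# condition: rest = 300-s resting window; peak = final exercise segment
#   (HTxR terminates at 50% of healthy MTP; peak LVEDVI rows were measured
#   at the exercise-echo workloads, 37% intensity for HTxR and 71% for healthy).
# provenance: mean/sd/n pooled from 15 clinical studies; model_paper = published simulation value.
condition,cohort,variable,units,mean,sd,n,model_paper
rest,htxr,HR,bpm,92.7,10.3,502,93.8
rest,htxr,CO,L/min,5.9,1.4,203,5.2
rest,htxr,SBP,mmHg,114.8,27.4,339,111.3
rest,htxr,DBP,mmHg,75.9,20.7,333,81.7
rest,htxr,MAP,mmHg,91.6,21.4,387,91.5
rest,htxr,SV,mL,58.7,15,384,55.4
rest,htxr,SVR,mmHg.s/mL,0.96,0.3,110,1.08
rest,htxr,LVEDVI,mL/m^2,49.2,12.1,110,51.9
rest,healthy,HR,bpm,67.4,10.8,178,69.5
rest,healthy,CO,L/min,6.1,1.2,113,5.6
rest,healthy,SBP,mmHg,119.7,14.9,141,111.9
rest,healthy,DBP,mmHg,74.9,10.3,141,74.2
rest,healthy,MAP,mmHg,91.5,9.7,187,86.7
rest,healthy,SV,mL,86.2,14.5,113,82
rest,healthy,SVR,mmHg.s/mL,0.87,0.16,68,0.97
rest,healthy,LVEDVI,mL/m^2,65.7,8.2,110,65.7
peak,htxr,HR,bpm,129.3,17.5,192,133.9
peak,htxr,CO,L/min,12.9,3.1,227,13
peak,htxr,SBP,mmHg,173,22,54,161.3
peak,htxr,DBP,mmHg,97.4,11.2,48,93.7
peak,htxr,MAP,mmHg,120.1,15.9,109,116.3
peak,htxr,SV,mL,97.1,19.7,186,95.7
peak,htxr,SVR,mmHg.s/mL,0.62,0.14,97,0.57
peak,htxr,LVEDVI,mL/m^2,58.0,11.6,30,66.1
peak,htxr,MTP,kpm/min,523,115,100,
peak,healthy,HR,bpm,166.5,14.9,97,169
peak,healthy,CO,L/min,19.9,3.6,97,19.8
peak,healthy,SBP,mmHg,211.5,20.4,51,210.8
peak,healthy,DBP,mmHg,93.1,11.9,51,95.2
peak,healthy,MAP,mmHg,131.2,14.4,97,133.7
peak,healthy,SV,mL,120.7,16.2,97,115.1
peak,healthy,SVR,mmHg.s/mL,0.43,0.07,82,0.45
peak,healthy,LVEDVI,mL/m^2,67.3,15.1,30,75.3
peak,healthy,MTP,kpm/min,1160,212,90,
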