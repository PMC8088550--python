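scenario_id,question_id,description,overall,n_experts,mean,median,hdi_lower,hdi_upper,bandwidth
S1,Q1,WGS testing kit with 50% cheaper initial investment costs,0,18,65.5,69.2,51.5,100.0,48.5
S1,Q2,Interpretation MTB only required for 5% of the patients,0,17,38.8,31.6,1.8,68.9,67.1
S1,Q3,Average turnaround time reduced to 7 days,0,17,54.2,63.4,17.6,98.1,80.5
S1,Q4,Overall scenario taking place within the next 5 years,1,16,46.0,52.1,0.1,85.5,85.4
S2,Q1,WGS is the only technique that can identify new biomarkers,0,17,28.3,21.8,0.0,49.0,49.0
S2,Q2,WGS detects new biomarker for immunotherapy in 20% of the patients,0,17,46.9,48.4,11.6,90.2,78.6
S2,Q3,90% of the physicians offer WGS to patients,0,16,65.5,72.1,43.7,98.0,54.3
S2,Q4,90% of patients prefer WGS to other molecular diagnostics,0,15,66.7,80.3,25.9,99.3,73.4
S2,Q5,Overall scenario taking place within the next 5 years,1,17,45.3,45.5,0.3,81.3,81.0
S3,Q1,Centralizing WGS leads to large reduction costs and turnaround time,0,16,52.5,51.4,19.3,88.8,69.5
S3,Q2,Costs WGS decreased to EUR 1000 per patient,0,16,54.9,54.9,30.7,85.6,54.9
S3,Q3,Turnaround time WGS decreased to 5 days,0,16,37.9,29.9,0.0,69.5,69.5
S3,Q4,All hospitals will adopt WGS,0,15,58.7,68.7,24.1,97.1,73.0
S3,Q5,Overall scenario taking place within the next 5 years,1,15,26.5,24.1,0.0,45.1,45.1
S4,Q1,WGS available as standard diagnostic test in clinical practice,0,17,64.5,76.1,31.6,99.9,68.3
S4,Q2,WGS detects actionable target (targeted therapy) in 12% of the patients,0,17,68.8,74.7,55.3,100.0,44.7
S4,Q3,Turnaround time WGS decreased to 14 days,0,17,76.1,80.3,61.2,99.8,38.6
S4,Q4,Costs WGS decreased to EUR 3000 per patient,0,16,81.1,83.6,69.7,99.8,30.1
S4,Q5,WGS will be used instead of standard diagnostics,0,17,58.7,65.7,23.2,95.9,72.7
S4,Q6,Overall scenario taking place within next 5 years,1,17,55.3,68.3,15.5,99.0,83.5
S5,Q1,New liquid NGS panel X enters the market,0,16,67.1,75.7,45.0,100.0,55.0
S5,Q2,NGS panel X detects actionable targets in 8% of the patients,0,15,66.6,77.4,46.2,95.2,49.0
S5,Q3,Less invasive liquid biopsies can be used for NGS panel X,0,15,56.1,59.9,16.7,88.0,71.3
S5,Q4,Turnaround time NGS panel X is on average 2 days,0,15,48.5,51.9,0.0,74.5,74.5
S5,Q5,Costs NGS panel X are EUR 300 per patient,0,15,51.6,51.6,18.4,93.4,75.0
S5,Q6,NGS panel X will be used instead of WGS,0,16,56.3,62.4,21.6,94.2,72.6
S5,Q7,Overall scenario taking place within the next 5 years,1,15,40.8,39.8,0.0,78.1,78.1
S6,Q1,Success rate tissue biopsies and sequencing process of WGS improve,0,15,59.0,64.7,22.9,86.1,63.2
S6,Q2,Tissue biopsies successfully taken in 80% of the patients,0,15,55.1,58.5,20.2,96.9,76.7
S6,Q3,Sequencing process of WGS successful in 95% of the patients,0,14,50.7,59.6,0.0,73.3,73.3
S6,Q4,More than 80% of the patients sequenced successful,0,14,52.7,58.4,18.5,89.9,71.4
S6,Q5,Costs WGS stay fixed at EUR 4500 per patient,0,14,47.0,47.3,22.8,80.0,57.2
S6,Q6,Overall scenario taking place within the next 5 years,1,15,40.0,39.2,0.0,69.7,69.7
S7,Q1,Approval new targeted therapies for new targets discovered by WGS,0,14,55.0,54.6,26.1,97.8,71.7
S7,Q2,New actionable targets can only be detected by WGS,0,15,34.6,27.9,0.0,56.2,56.2
S7,Q3,WGS detects new biomarker for targeted therapy in 20% of the patients,0,15,41.5,44.4,0.0,62.8,62.8
S7,Q4,90% of the physicians prefer using WGS as molecular diagnostic,0,14,66.8,71.4,53.6,95.2,41.6
S7,Q5,90% of patients prefer to receive WGS as molecular diagnostics,0,14,68.6,78.6,28.4,98.7,70.3
S7,Q6,Overall scenario taking place within the next 5 years,1,14,35.5,28.1,0.0,69.8,69.8
S8,Q1,Off-label drug use will be allowed based on research on WGS data,0,15,65.6,66.9,39.5,99.7,60.2
S8,Q2,Off-label drug prescription only allowed for targets found by WGS,0,14,47.9,42.0,6.3,92.0,85.7
S8,Q3,WGS detects actionable target for off-label targeted therapy in 5% of the patients,0,14,60.4,73.1,17.8,89.8,72.0
S8,Q4,95% of the physicians prefer using WGS as molecular diagnostic,0,15,72.1,83.6,43.9,98.8,54.9
S8,Q5,All patients prefer to receive WGS as molecular diagnostics,0,14,69.5,85.2,36.6,99.5,62.9
S8,Q6,Overall scenario taking place within the next 5 years,1,14,47.3,43.9,25.2,92.3,67.1
S9,Q1,Better treatment response in patients with targets identified with WGS,0,14,18.5,9.3,0.0,39.7,39.7
S9,Q2,Treatment response targeted therapy increased to 10%,0,16,35.7,24.0,0.0,73.7,73.7
S9,Q3,WGS detects biomarkers that are better predictors for treatment response,0,14,42.5,48.6,0.0,64.7,64.7
S9,Q4,All physicians prefer using WGS as molecular diagnostic,0,16,54.6,60.3,13.1,96.4,83.3
S9,Q5,All patients prefer to receive WGS as molecular diagnostics,0,16,55.5,60.5,15.9,96.9,81.0
S9,Q6,Overall scenario taking place within the next 5 years,1,15,25.7,26.1,0.0,42.3,42.3
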