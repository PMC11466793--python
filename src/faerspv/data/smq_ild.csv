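smq_code,smq_name,pt_code,pt_name,scope
20000042,Interstitial lung disease,10066728,Acute interstitial pneumonitis,narrow
20000042,Interstitial lung disease,10078268,Idiopathic interstitial pneumonia,narrow
20000042,Interstitial lung disease,10087834,Interstitial lung abnormality,narrow
20000042,Interstitial lung disease,10022611,Interstitial lung disease,narrow
20000042,Interstitial lung disease,10035742,Pneumonitis,narrow
20000042,Interstitial lung disease,10037383,Pulmonary fibrosis,narrow
20000042,Interstitial lung disease,10025102,Lung infiltration,broad
20000042,Interstitial lung disease,10081792,Lung opacity,broad
20000042,Interstitial lung disease,10001409,Alveolitis,broad
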