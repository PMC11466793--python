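generic,synonym
crizotinib,crizotinib
crizotinib,xalkori
ceritinib,ceritinib
ceritinib,zykadia
alectinib,alectinib
alectinib,alecensa
brigatinib,brigatinib
brigatinib,alunbrig
lorlatinib,lorlatinib
lorlatinib,lorbrena
lorlatinib,lorviqua
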