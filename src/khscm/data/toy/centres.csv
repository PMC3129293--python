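centre_id,name,kind,output_measure,output_count
admin,administration,support,none,0
opd,outpatient department,final,outpatient_visits,50
ward,general ward,final,bed_days,60
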