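centre_id,cost_unit_id,category,year,amount_ksh,traceability
admin,,staffing,2006/2007,300,indirect
admin,,other_recurrent,2006/2007,200,indirect
admin,,fixed,2006/2007,100,indirect
opd,,drugs_supplies,2006/2007,150,indirect
opd,,staffing,2006/2007,50,indirect
ward,,drugs_supplies,2006/2007,100,indirect
,outpatient_visit,drugs_supplies,2006/2007,100,direct
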