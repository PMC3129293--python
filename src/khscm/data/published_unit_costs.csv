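stratum,cost_per_visit,cost_per_admission,cost_per_bed_day
Dispensary (Public),174,,
Health Centre (Public),223,3500,3500
District Hospital (Public),518,12970,2186
Provincial Hospital (Public),434,12953,1885
Tertiary Hospital (Public),1405,48474,4921
"Dispensary, Health Centre (FBO/NGO)",633,2242,4194
District Hospital (FBO/NGO),947,15110,3746
"Dispensary, Health Centre (Private)",850,5614,11871
District Hospital (Private),1592,47491,8300
Tertiary Hospital (Private),2277,96857,18704
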