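{
 "id": "toy-hc",
 "level": "3",
 "trustee": "public",
 "location": "rural",
 "beds": 2,
 "outpatient_visits": 50,
 "admissions": 10,
 "bed_days": 60,
 "catchment_population": 5000,
 "year_order": ["2006/2007"]
}
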