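stratum,drugs_supplies,staffing,other_recurrent,fixed,group
Community (Public),398041,233770,0,91992,public
Dispensary (Public),12927460,24728165,1813250,13616947,public
Health Centre (Public),6125265,20227027,1711340,9587565,public
District Hospital (Public),42745105,76685778,13503152,62136920,public
Provincial Hospital (Public),5434795,16563988,2361242,4098631,public
Tertiary Hospital (Public),9536341,28296419,5281557,4251671,public
Nursing Home/Enhanced HC (Public),206159,456053,47458,142743,public
"Dispensary, Health Centre (FBO/NGO)",17067193,10931167,4474101,13846061,fbo_ngo
District Hospital (FBO/NGO),16619036,19528286,8954498,25072792,fbo_ngo
Nursing Home/Enhanced HC (FBO/NGO),45077,237802,45778,137972,fbo_ngo
"Dispensary, Health Centre (Private)",27602561,32701781,7688156,34615153,private
District Hospital (Private),8098325,8729259,3797198,19077125,private
Tertiary Hospital (Private),7608513,3203292,3543382,4251671,private
Nursing Home/Enhanced HC,1709668,1460479,929799,781843,
District Administration,99635,8629723,7006815,0,administration
Provincial Administration,0,982387,610011,0,administration
Ministry of Health,0,6138911,25512818,0,administration
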