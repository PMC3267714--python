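name,monthly_opd_visits,opd_share_pct,monthly_bed_days,bed_day_share_pct,alos_days,opd_cost_branded,ipd_cost_branded,opd_cost_generic,ipd_cost_generic,costed
ent,735,6.8,97,8,3.7,463360,107519,272963,59386,1
dental,554,5.1,2,0.2,,346745,3658,300278,3658,1
dermatology,1290,11.9,170,8.3,6.3,292776,64107,168410,51121,1
ophthalmology,727,6.7,78,9.3,2.6,951991,588683,867041,568222,1
psychiatry,168,1.6,17,0.3,16.2,200055,14338,141003,9302,1
general_medicine,2400,22.2,343,15.3,6.9,4119882,716528,2332485,413427,1
orthopedics,974,9,488,14.9,10,,,,,0
gynecology,1540,14.3,214,14.7,4.5,1132900,293062,812763,221684,1
pediatrics,1263,11.7,253,11.3,6.9,771727,164589,566264,100540,1
surgery,1148,10.6,321,17.6,5.6,,,,,0
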