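item_id,category,price_branded,price_generic
ent_opd_kit,drug,630.421768707483,371.378231292517
ent_ipd_kit,drug,4101.240206185567,2265.2391752577323
dental_opd_kit,drug,625.8935018050541,542.0180505415162
dental_ipd_kit,drug,3658.0,3658.0
dermatology_opd_kit,drug,226.9581395348837,130.5503875968992
dermatology_ipd_kit,drug,2375.73,1894.4841176470588
ophthalmology_opd_kit,drug,1309.4786795048144,1192.6286107290234
ophthalmology_ipd_kit,drug,19622.766666666666,18940.733333333334
psychiatry_opd_kit,drug,1190.8035714285713,839.3035714285714
psychiatry_ipd_kit,drug,13663.270588235295,8864.258823529412
general_medicine_opd_kit,drug,1716.6175,971.86875
general_medicine_ipd_kit,drug,14414.120116618078,8316.75306122449
gynecology_opd_kit,drug,735.6493506493506,527.7681818181818
gynecology_ipd_kit,drug,6162.518691588785,4661.579439252337
pediatrics_opd_kit,drug,611.0269200316707,448.34837688044337
pediatrics_ipd_kit,drug,4488.79090909091,2742.0
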