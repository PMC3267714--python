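condition,specialty,setting,item_id,category,quantity,episode_weight
ent outpatient episode (pooled),ent,OPD,ent_opd_kit,drug,1,1.0
ent inpatient episode (pooled),ent,IPD,ent_ipd_kit,drug,1,1.0
dental outpatient episode (pooled),dental,OPD,dental_opd_kit,drug,1,1.0
dental inpatient episode (pooled),dental,IPD,dental_ipd_kit,drug,1,1.0
dermatology outpatient episode (pooled),dermatology,OPD,dermatology_opd_kit,drug,1,1.0
dermatology inpatient episode (pooled),dermatology,IPD,dermatology_ipd_kit,drug,1,1.0
ophthalmology outpatient episode (pooled),ophthalmology,OPD,ophthalmology_opd_kit,drug,1,1.0
ophthalmology inpatient episode (pooled),ophthalmology,IPD,ophthalmology_ipd_kit,drug,1,1.0
psychiatry outpatient episode (pooled),psychiatry,OPD,psychiatry_opd_kit,drug,1,1.0
psychiatry inpatient episode (pooled),psychiatry,IPD,psychiatry_ipd_kit,drug,1,1.0
general_medicine outpatient episode (pooled),general_medicine,OPD,general_medicine_opd_kit,drug,1,1.0
general_medicine inpatient episode (pooled),general_medicine,IPD,general_medicine_ipd_kit,drug,1,1.0
gynecology outpatient episode (pooled),gynecology,OPD,gynecology_opd_kit,drug,1,1.0
gynecology inpatient episode (pooled),gynecology,IPD,gynecology_ipd_kit,drug,1,1.0
pediatrics outpatient episode (pooled),pediatrics,OPD,pediatrics_opd_kit,drug,1,1.0
pediatrics inpatient episode (pooled),pediatrics,IPD,pediatrics_ipd_kit,drug,1,1.0
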