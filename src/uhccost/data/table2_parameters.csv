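name,base,low,high,units,kind,flags
population,100000,80000,120000,persons,count,
morbidity_rate,0.1,0.08,0.12,illness episodes per person per month,rate,
reporting_adjustment,1.2,1.125,1.425,ratio,ratio,
monthly_patient_load,12000,7200,41040,patients per month,count,derived;range_inconsistent
ipd_opd_cost_ratio,10,8,15,ratio,ratio,
ipd_treatment_proportion,0.05,0.02,0.1,proportion,proportion,
ipd_correction_factor,0.3,0.2,0.5,ratio,ratio,
opd_days_per_month,24,24,24,days,days,fixed
household_size,4,4,4,persons per household,count,fixed
opd_fraction,0.9,0.9,0.9,proportion,proportion,derived
opd_share_general_medicine,0.22,0.12,0.32,proportion,proportion,
opd_share_ent,0.07,0.01,0.11,proportion,proportion,
opd_share_ophthalmology,0.07,0.01,0.11,proportion,proportion,
opd_share_dermatology,0.12,0.06,0.16,proportion,proportion,
opd_share_gynecology,0.14,0.04,0.24,proportion,proportion,
opd_share_psychiatry,0.02,0.005,0.025,proportion,proportion,
opd_share_pediatrics,0.12,0.06,0.16,proportion,proportion,
opd_share_surgery,0.11,0.05,0.15,proportion,proportion,
opd_share_dental,0.05,0.01,0.09,proportion,proportion,
opd_share_orthopedics,0.09,0.04,0.14,proportion,proportion,
alos_gynecology,4.5,3,7,days,days,
alos_ophthalmology,2.6,1,5,days,days,
alos_surgery,5.6,3,9,days,days,
alos_general_medicine,6.9,4,10,days,days,
alos_ent,3.7,2,5,days,days,
alos_psychiatry,16.2,6,26,days,days,
alos_pediatrics,6.9,4,10,days,days,
alos_orthopedics,10,7,20,days,days,
alos_dermatology,6.3,3,10,days,days,
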