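# Three worked-example fields for the recommend command.
field_id,district,acz,season,year,water_regime,variety_name,growth_duration_days,seedling_age_days,transplant_delay_days,historical_yield_GYR,variety_yield_ceiling,previous_crop_yield,residue_retained_fraction,selected_products,farmer_applies_zinc
F001,Puri,east_south_eastern_coastal_plain,kharif,2014,irrigated,Swarna,140,25,0,4.6,,4.5,0.15,urea;DAP;MOP,False
F002,Mayurbhanj,north_central_plateau,rabi,2014-2015,irrigated,MTU-1010,110,20,0,2.0,,2.0,0.15,urea;DAP;MOP,False
F003,Cuttack,east_south_eastern_coastal_plain,kharif,2015,rainfed,Pooja,150,22,0,6.4,,6.0,0.15,urea;DAP;MOP,False
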