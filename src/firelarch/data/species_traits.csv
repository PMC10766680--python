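name,deciduous,min_active_layer_cm,bark_coef,resprout_prob,growth_rate_cm_per_yr,temp_optimum_c,temp_tolerance_c,maturity_height_cm,seeds_per_year,dispersal_sd_m,max_age_yr,background_mortality,max_height_cm
Dahurian larch,True,20.0,0.005,0.15,35.0,11.5,6.0,200.0,60.0,5.0,350,0.015,1450.0
Cajander larch,True,25.0,0.0045,0.1,30.0,10.0,5.0,200.0,50.0,5.0,350,0.016,1300.0
Siberian larch,True,30.0,0.0045,0.1,33.0,13.0,5.0,200.0,55.0,5.0,350,0.015,1400.0
Siberian spruce,False,200.0,0.001,0.0,25.0,13.5,5.0,250.0,60.0,4.0,300,0.018,1300.0
Scots pine,False,100.0,0.004,0.0,30.0,14.0,5.0,220.0,50.0,6.0,320,0.016,1400.0
Siberian pine,False,200.0,0.003,0.0,22.0,13.0,5.0,260.0,40.0,4.0,400,0.015,1350.0
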