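name,role,nominal,measure_linked,unit,description
Gc,gain_threshold,1.2,0,L/min/mmHg,central chemoreflex gain on alveolar CO2 above threshold
Bc,gain_threshold,36.0,1,mmHg,central chemoreflex CO2 threshold (apneic point)
Gp,gain_threshold,60.0,0,L/min,peripheral hypoxic drive amplitude
KpO2,gain_threshold,30.0,0,mmHg,hypoxic drive exponential shape constant
Gm,gain_threshold,8.0,0,dimensionless,metabolic (exercise) ventilatory drive gain per L/min CO2
kVT,gain_threshold,0.055,0,L per L/min,tidal-volume recruitment slope above basal ventilation
VTmax,gain_threshold,1.5,1,L,maximum recruitable tidal volume
rI,gain_threshold,0.4,1,dimensionless,inspiratory duty cycle TI/Ttot
GHR,gain_threshold,33.0,0,bpm per L/min,heart-rate gain on O2 uptake
GPM,gain_threshold,10.0,0,mmHg per L/min,mean arterial pressure gain on O2 uptake
GPP,gain_threshold,15.0,0,mmHg per L/min,pulse-pressure gain on O2 uptake
VTn,covariate,0.6,1,L,basal (resting) tidal volume
VEn,covariate,9.0,1,L/min,ventilation at onset of tidal-volume recruitment
HR0,covariate,60.0,1,bpm,basal heart rate at zero O2 uptake
PM0,covariate,85.0,1,mmHg,basal mean arterial pressure
PP0,covariate,40.0,1,mmHg,basal pulse pressure
V0dead,covariate,0.15,0,L,series dead-space volume
FiO2,covariate,21.0379,1,%,inspired dry O2 fraction
FiCO2,covariate,0.0421,1,%,inspired dry CO2 fraction
Patm,covariate,640.0,1,mmHg,atmospheric pressure
AT,covariate,1.0,1,L/min,anaerobic threshold expressed as VCO2
Vtot,covariate,5000.0,1,mL,total blood volume
Vu_ven,covariate,3000.0,1,mL,unstressed venous blood volume
Vu_art,covariate,700.0,1,mL,unstressed arterial blood volume
tau_HR,time_constant,30.0,0,s,heart-rate response time constant (transient only)
tau_VE,time_constant,60.0,0,s,ventilatory response time constant (transient only)
k_gas,conversion,863.0,0,mmHg,BTPS/STPD alveolar gas-equation conversion factor
ve_init,initial_value,8.0,0,L/min,ventilation iteration starting point
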