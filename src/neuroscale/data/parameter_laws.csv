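task,parameter,coefficient,exponent,units,source
swing,t_sm,31,0.21,ms,literature
swing,limb_mass,5.8e-2,1.00,kg,literature
swing,inertia,2.52e-4,1.75,kg.m^2,literature
swing,l_com,5.6e-2,0.36,m,literature
swing,tau_iso,0.54,1.19,N.m,literature
swing,available_time,147.9,0.17,ms,literature
posture,t_sm,31,0.21,ms,literature
posture,inertia,2.64e-2,1.74,kg.m^2,literature
posture,l_com,1.62e-1,0.37,m,literature
posture,tau_iso,3.41,1.21,N.m,literature
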