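name,viscosity_ref_Pas,T_ref_K,xi0,xi1,molar_mass_gmol,diffusion_volume
helium,1.863e-05,273.15,0.6958,-0.0071,4.0026,2.67
hydrogen,8.382e-06,273.15,0.6892,0.005,2.0159,6.12
nitrogen,1.662e-05,273.15,0.7665,-0.0378,28.0134,18.5
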