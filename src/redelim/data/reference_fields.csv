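# Reference snapshot table: projected electric fields (MV/cm) by source
# group and bond dipoles (Debye) for the reactant (RS) and transition
# state (TS) of the catalyzed and uncatalyzed reductive elimination.
# q_au_e, q_c_e and d_A are SYNTHETIC placeholder raw values chosen to be
# self-consistent with the dipoles (two-point dipole model, q_au fixed at
# +0.30 e, d = 2.05 A in RS / 2.60 A in TS); they are not measured data.
reaction,state,bond,group,field_MV_cm,dipole_D,q_au_e,q_c_e,d_A
uncatalyzed,RS,1,bulk_water,-21.49,-6.15,0.3,-0.949165996256,2.05
uncatalyzed,RS,1,complexed_water,59.73,-6.15,0.3,-0.949165996256,2.05
uncatalyzed,RS,2,bulk_water,-12.75,-2.83,0.3,-0.274819474700,2.05
uncatalyzed,RS,2,complexed_water,-14.89,-2.83,0.3,-0.274819474700,2.05
uncatalyzed,TS,1,bulk_water,-4.55,-1.26,0.3,0.098211646759,2.6
uncatalyzed,TS,1,complexed_water,9.63,-1.26,0.3,0.098211646759,2.6
uncatalyzed,TS,2,bulk_water,-15.81,3.67,0.3,0.887748616187,2.6
uncatalyzed,TS,2,complexed_water,-21.2,3.67,0.3,0.887748616187,2.6
catalyzed,RS,1,bulk_water,-6.72,-6.15,0.3,-0.949165996256,2.05
catalyzed,RS,1,complexed_water,40.81,-6.15,0.3,-0.949165996256,2.05
catalyzed,RS,1,cage,-0.21,-6.15,0.3,-0.949165996256,2.05
catalyzed,RS,2,bulk_water,-6.87,-2.83,0.3,-0.274819474700,2.05
catalyzed,RS,2,complexed_water,-7.97,-2.83,0.3,-0.274819474700,2.05
catalyzed,RS,2,cage,-14.13,-2.83,0.3,-0.274819474700,2.05
catalyzed,TS,1,bulk_water,-51.63,2.05,0.3,0.628306447734,2.6
catalyzed,TS,1,complexed_water,19.3,2.05,0.3,0.628306447734,2.6
catalyzed,TS,1,cage,27.27,2.05,0.3,0.628306447734,2.6
catalyzed,TS,2,bulk_water,-31.37,0.71,0.3,0.413706135557,2.6
catalyzed,TS,2,complexed_water,22.27,0.71,0.3,0.413706135557,2.6
catalyzed,TS,2,cage,9.95,0.71,0.3,0.413706135557,2.6
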