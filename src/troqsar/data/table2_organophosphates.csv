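name,cas,abbreviation,log_kow,log_lc50,log_noec,printed_log_tro,printed_type
Triisobutyl phosphate,126-71-6,TIBP,3.60,0.20,0.50,0.30,N
Tributyl phosphate,126-73-8,TNBP,4.00,0.12,0.24,0.12,N
Tributoxyethyl phosphate,78-51-3,TBEP,3.00,0.59,1.40,0.81,N
Triphenyl phosphate,115-86-6,TPHP,4.70,-0.10,-0.73,0.63,N
Diphenyl chlorophosphate,2524-64-3,,3.16,0.36,1.03,0.67,N
Tripropyl phosphate,513-08-6,TPP,1.87,0.57,1.90,1.36,T
Diethyl phthalate,84-66-2,DEP,2.42,1.10,0.79,0.30,N
Di-n-butyl phthalate,84-74-2,DNBP,4.61,0.05,-0.25,0.30,N
Bis(2-ethylhexyl)phthalate,117-81-7,BEHP,8.39,-2.0,-2.30,0.30,N
Bis(2-butoxyethyl) phosphate,14260-97-0,BBOEP,1.74,2.62,2.32,0.30,N
Tricresyl phosphate,1330-78-5,TCP,6.34,-0.84,-8.15,0.30,N
Diethyl phthalate,84-66-2,DEP,2.42,1.10,0.79,0.30,N
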