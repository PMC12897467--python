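case,context,ph,paco2_mmhg,hco3_mmol_l,sbe_mmol_l,na,k,cl,ca,mg,lactate,albumin_g_l,pi_mmol_l
1,urosepsis with acute kidney injury,7.32,29.1,16,-10.1,145,2.3,121,1.43,0.93,1,27,1.6
2,COPD with abdominal sepsis,7.37,55,31,5.2,136,3.3,92,1.2,0.91,3.4,24,1.4
3,diabetic ketoacidosis with acute kidney injury,7.45,18,18,-9,125,2.4,86,1.1,0.94,2.0,38,1.2
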