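cell_line,k_idsb,k_idsb_err,k_cdsb,k_cdsb_err,hrf,reference
CHO,5.56e-3,1.12e-3,7.65e-1,0.44e-1,2.90,Hirayama et al. 2013
AA8,14.00e-3,1.48e-3,9.16e-1,0.89e-1,2.85,Hirayama et al. 2013
V79,4.79e-3,0.52e-3,3.17e-1,0.13e-1,,Chapman et al. 1979
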