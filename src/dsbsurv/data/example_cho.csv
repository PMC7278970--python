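cell_line,dose_Gy,dmso_M,oxygen,survival,survival_err
CHO,2,0,normoxic,0.4628608198,0.02314304099
CHO,2,0.1,normoxic,0.6397474371,0.03198737186
CHO,2,0.5,normoxic,0.657577537,0.03287887685
CHO,2,1,normoxic,0.8053750348,0.04026875174
CHO,4,0,normoxic,0.08596273496,0.004298136748
CHO,4,0.1,normoxic,0.206230485,0.01031152425
CHO,4,0.5,normoxic,0.3566412008,0.01783206004
CHO,4,1,normoxic,0.4422547219,0.02211273609
CHO,8,0,normoxic,0.0002741436443,1.370718221e-05
CHO,8,0.1,normoxic,0.006051191863,0.0003025595931
CHO,8,0.5,normoxic,0.0332084099,0.001660420495
CHO,8,1,normoxic,0.07770987536,0.003885493768
CHO,2,0,hypoxic,0.8366031472,0.04183015736
CHO,2,0.1,hypoxic,0.7827644617,0.03913822309
CHO,2,0.5,hypoxic,0.8220233416,0.04110116708
CHO,2,1,hypoxic,0.8955647159,0.04477823579
CHO,4,0,hypoxic,0.6557456616,0.03278728308
CHO,4,0.1,hypoxic,0.6600939794,0.03300469897
CHO,4,0.5,hypoxic,0.67975952,0.033987976
CHO,4,1,hypoxic,0.7695240544,0.03847620272
CHO,8,0,hypoxic,0.2893114968,0.01446557484
CHO,8,0.1,hypoxic,0.3414872123,0.01707436062
CHO,8,0.5,hypoxic,0.4393461675,0.02196730837
CHO,8,1,hypoxic,0.4497667478,0.02248833739
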