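model,class,rmse,mae,ccc,ae_gt_010,ae_gt_005,aic,bic,arv_printed
OLS M1,ols,0.0977,0.0764,0.7482,58.24,29.92,-1129.08,-1120.20,4.64
OLS M2,ols,0.0977,0.0763,0.7485,57.92,29.44,-1127.63,-1114.31,4.36
OLS M3,ols,0.0849,0.0658,0.8211,55.20,21.28,-1297.23,-1270.60,2.50
OLS M4,ols,0.0841,0.0654,0.8251,53.12,21.60,-1299.07,-1250.25,2.00
OLS M5,ols,0.0838,0.0653,0.8265,53.60,21.28,-1299.42,-1241.73,1.50
TOBIT M1,tobit,0.0980,0.0763,0.7558,57.76,30.08,-888.24,-874.92,4.14
TOBIT M2,tobit,0.0981,0.0765,0.7555,57.92,29.92,-886.38,-868.63,4.86
TOBIT M3,tobit,0.0851,0.0658,0.8250,54.08,19.84,-1035.70,-1004.64,2.43
TOBIT M4,tobit,0.0844,0.0655,0.8286,53.60,21.44,-1037.33,-984.08,1.93
TOBIT M5,tobit,0.0841,0.0655,0.8300,52.96,21.60,-1038.11,-975.99,1.64
OPROBIT M1,oprobit,0.0975,0.0761,0.7519,59.20,28.96,8089.15,14211.95,4.86
OPROBIT M2,oprobit,0.0973,0.0760,0.7529,57.60,29.44,8088.51,14151.67,4.14
OPROBIT M3,oprobit,0.0852,0.0662,0.8204,53.92,20.32,7570.70,13350.07,2.57
OPROBIT M4,oprobit,0.0843,0.0657,0.8245,54.40,21.92,7567.43,13290.18,2.00
OPROBIT M5,oprobit,0.0839,0.0655,0.8262,52.96,21.76,7568.51,13309.17,1.43
BETAMIX M1a,betamix,0.0973,0.0768,0.7500,58.24,30.24,-476.33,-454.14,9.93
BETAMIX M1b,betamix,0.0980,0.0724,0.7312,59.36,29.76,-500.06,-460.12,10.00
BETAMIX M2a,betamix,0.0973,0.0721,0.7506,58.56,29.60,-474.50,-443.44,9.50
BETAMIX M3a,betamix,0.0847,0.0657,0.8225,54.40,21.12,-628.08,-570.39,3.64
BETAMIX M3b,betamix,0.0848,0.0661,0.8217,54.24,21.28,-665.21,-572.02,4.07
BETAMIX M3c,betamix,0.0850,0.0663,0.8219,54.88,21.92,-672.91,-544.21,5.00
BETAMIX M4a,betamix,0.0842,0.0654,0.8250,53.92,21.12,-620.49,-518.42,2.86
BETAMIX M5a,betamix,0.0948,0.0653,0.8265,54.08,21.76,-624.50,-504.69,3.86
BETAMIX M1a#,betamix,0.1585,0.1213,0.3480,72.16,47.84,155.21,168.52,13.43
BETAMIX M2a#,betamix,0.1585,0.1211,0.3480,72.00,47.68,154.95,172.70,13.00
BETAMIX M2b#,betamix,0.0968,0.0763,0.7549,58.72,29.44,-542.86,-489.61,8.43
BETAMIX M3a#,betamix,0.0851,0.0660,0.8226,54.24,20.96,-589.12,-531.43,4.50
BETAMIX M4a#,betamix,0.1538,0.1206,0.3992,75.68,48.48,44.94,98.21,12.57
BETAMIX M5a#,betamix,0.0843,0.0656,0.8263,53.92,22.40,-589.44,-469.62,4.21
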