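model,rmse,mae,ccc,ae_gt_010,ae_gt_005,arv_printed
OLS M4,0.0856,0.0665,0.8186,53.60,22.08,3.9
OLS M5,0.0854,0.0665,0.8194,54.24,22.40,4.3
TOBIT M4,0.0859,0.0666,0.8222,54.56,22.24,5.2
TOBIT M5,0.0857,0.0667,0.8230,54.08,22.40,4.6
OPROBIT M4,0.0857,0.0667,0.8185,54.72,22.56,6.9
OPROBIT M5,0.0854,0.0655,0.8197,53.44,21.76,2.1
BETAMIX M3a,0.0853,0.0661,0.8194,54.24,20.8,2.8
BETAMIX M4a,0.0858,0.0667,0.8176,54.88,18.88,6.2
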