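{
  "mu_alpha": [
    0.8754687373538999,
    -0.002,
    0.012,
    0.35,
    0.012,
    0.2,
    -0.8,
    0.06,
    1.5
  ],
  "sigma_alpha": [
    0.15,
    0.001,
    0.004,
    0.12,
    0.004,
    0.05,
    0.3,
    0.02,
    0.5
  ],
  "sigma_obs": 0.1,
  "weights_P_blocks": [
    0.07056074363591808,
    0.06655141647405692,
    0.06278500216511168,
    0.059246783363320926,
    0.055922934401826434,
    0.023751765854800225,
    0.022578451289529067,
    0.02147622426012402,
    0.020440777790514827,
    0.01946806585111986,
    0.018554287548897593,
    0.017695872275274475,
    0.035644717016364735,
    0.03375084496610546,
    0.031971716822794566,
    0.030300380604549225,
    0.02873030552877627,
    0.013533721544567343,
    0.012979486988089383,
    0.012458831805871352,
    0.011969721526474204,
    0.02258885157511408,
    0.029824673857313133,
    0.03567350352197828,
    0.03251248528718302,
    0.017152316489121952,
    0.016167595098497335,
    0.022654388195108587,
    0.03284006873062361,
    0.026413279483238523,
    0.01856883360453191,
    0.025324333759673745,
    0.028843646038859666,
    0.021063972644669474
  ],
  "weights_T_blocks": [
    0.07794968895538652,
    0.07349268822758007,
    0.030353868356532226,
    0.028780552621689638,
    0.05021915362461635,
    0.04744226109904395,
    0.04483361198649215,
    0.02338448892307245,
    0.022233426542193936,
    0.021152103505483483,
    0.020136294519676547,
    0.019182030289086202,
    0.0391350076453139,
    0.03702966957595577,
    0.01665233394415332,
    0.015909152214112526,
    0.026036030265455076,
    0.024724319115818155,
    0.02349208052721115,
    0.013360232206425796,
    0.01281650883758035,
    0.024131621815791003,
    0.0321753817475868,
    0.029985946519472187,
    0.024441864824413392,
    0.027404178057408086,
    0.01699338050139865,
    0.02371474793099625,
    0.030932246142833776,
    0.025097948144988766,
    0.021304583688563847,
    0.026193086158567157,
    0.025773781697682175,
    0.023535729787418296
  ],
  "weights_P_monthly": [
    0.0,
    0.0,
    0.0,
    0.07056074363591808,
    0.06655141647405692,
    0.06278500216511168,
    0.059246783363320926,
    0.055922934401826434,
    0.023751765854800225,
    0.022578451289529067,
    0.02147622426012402,
    0.020440777790514827,
    0.01946806585111986,
    0.018554287548897593,
    0.017695872275274475,
    0.035644717016364735,
    0.03375084496610546,
    0.031971716822794566,
    0.030300380604549225,
    0.02873030552877627,
    0.013533721544567343,
    0.012979486988089383,
    0.012458831805871352,
    0.011969721526474204,
    0.01129442578755704,
    0.01129442578755704,
    0.014912336928656567,
    0.014912336928656567,
    0.01783675176098914,
    0.01783675176098914,
    0.01625624264359151,
    0.01625624264359151,
    0.008576158244560976,
    0.008576158244560976,
    0.008083797549248668,
    0.008083797549248668,
    0.007551462731702862,
    0.007551462731702862,
    0.007551462731702862,
    0.010946689576874537,
    0.010946689576874537,
    0.010946689576874537,
    0.008804426494412841,
    0.008804426494412841,
    0.008804426494412841,
    0.0061896112015106365,
    0.0061896112015106365,
    0.0061896112015106365,
    0.006331083439918436,
    0.006331083439918436,
    0.006331083439918436,
    0.006331083439918436,
    0.0072109115097149165,
    0.0072109115097149165,
    0.0072109115097149165,
    0.0072109115097149165,
    0.005265993161167369,
    0.005265993161167369,
    0.005265993161167369,
    0.005265993161167369
  ],
  "weights_T_monthly": [
    0.0,
    0.0,
    0.0,
    0.07794968895538652,
    0.07349268822758007,
    0.030353868356532226,
    0.028780552621689638,
    0.05021915362461635,
    0.04744226109904395,
    0.04483361198649215,
    0.02338448892307245,
    0.022233426542193936,
    0.021152103505483483,
    0.020136294519676547,
    0.019182030289086202,
    0.0391350076453139,
    0.03702966957595577,
    0.01665233394415332,
    0.015909152214112526,
    0.026036030265455076,
    0.024724319115818155,
    0.02349208052721115,
    0.013360232206425796,
    0.01281650883758035,
    0.012065810907895502,
    0.012065810907895502,
    0.0160876908737934,
    0.0160876908737934,
    0.014992973259736093,
    0.014992973259736093,
    0.012220932412206696,
    0.012220932412206696,
    0.013702089028704043,
    0.013702089028704043,
    0.008496690250699325,
    0.008496690250699325,
    0.00790491597699875,
    0.00790491597699875,
    0.00790491597699875,
    0.010310748714277925,
    0.010310748714277925,
    0.010310748714277925,
    0.008365982714996254,
    0.008365982714996254,
    0.008365982714996254,
    0.007101527896187948,
    0.007101527896187948,
    0.007101527896187948,
    0.006548271539641789,
    0.006548271539641789,
    0.006548271539641789,
    0.006548271539641789,
    0.006443445424420544,
    0.006443445424420544,
    0.006443445424420544,
    0.006443445424420544,
    0.005883932446854574,
    0.005883932446854574,
    0.005883932446854574,
    0.005883932446854574
  ],
  "r2_true": 0.8855869405037516,
  "ar_share_true_pct": 3.5181388848448014,
  "center_gprev": 0.8722049671724812,
  "mean_width_mm": 1.5458182947960257
}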