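{
 "note": "end-diastolic state after 1 Hz pre-pacing of the reference parameter set",
 "state": {
  "v": -85.04741290234425,
  "m": 0.001533290214604306,
  "h": 0.9850617930116534,
  "j": 0.9905840116390258,
  "xkr": 0.0002089726545997981,
  "xs1": 0.005582519150473039,
  "xs2": 0.008867593867341855,
  "y_lcc": 0.9999096753812207,
  "ito_a": 0.0003341271605176022,
  "ito_i": 0.9999979715469155,
  "caru_0": 0.7534110225104559,
  "caru_1": 1.3337489448719591e-06,
  "caru_2": 1.1511988267865711e-09,
  "caru_3": 0.000530296546399206,
  "caru_4": 8.196978401556265e-05,
  "caru_5": 1.4510955192310876e-10,
  "caru_6": 1.2578111847764355e-13,
  "caru_7": 5.7695369245753795e-08,
  "caru_8": 2.972721700964019e-09,
  "caru_9": 5.273547294727556e-15,
  "caru_10": 2.843075953865698e-16,
  "caru_11": 2.0923887733418848e-12,
  "caru_12": 3.546148499827559e-14,
  "caru_13": 7.147545989353774e-18,
  "caru_14": 1.9117607014216526e-16,
  "caru_15": 2.6891789992449633e-17,
  "caru_16": 2.9457044747071417e-16,
  "caru_17": 3.1869027048908253e-16,
  "caru_18": 8.953152783333554e-15,
  "caru_19": 8.645037784364516e-17,
  "caru_20": 0.24577513058128536,
  "caru_21": 4.3800282402925075e-07,
  "caru_22": 1.6142082036084986e-08,
  "caru_23": 0.00017297098646421814,
  "caru_24": 2.6739900969386255e-05,
  "caru_25": 4.765399012405729e-11,
  "caru_26": 1.7570075702736326e-12,
  "caru_27": 1.8818995236360434e-08,
  "caru_28": 9.69751370449143e-10,
  "caru_29": 1.7492235888510777e-15,
  "caru_30": 4.416233347800502e-16,
  "caru_31": 6.825005427678497e-13,
  "caru_32": 1.1731175128076709e-14,
  "caru_33": 1.3728615230515134e-17,
  "caru_34": 2.482009421497256e-16,
  "caru_35": 1.3160133882643045e-17,
  "caru_36": 7.289805909320438e-16,
  "caru_37": 6.147564299183824e-16,
  "caru_38": 1.1172791587740848e-14,
  "caru_39": 2.2002097265064714e-16,
  "ca_i": 0.00011801854144182454,
  "ca_nsr": 0.4484256020471736,
  "na_i": 6.702868170939804,
  "k_i": 131.60322616594223,
  "ltrpn": 0.011499253338371393,
  "htrpn": 0.12961302634176655,
  "cmdn": 0.00506509331097868,
  "csqn": 0.6292402620452875,
  "xb_n0": 0.8265944774996292,
  "xb_n1": 0.050940124163857264,
  "xb_p0": 0.007989444749177359,
  "xb_p1": 0.004060956763616341,
  "xb_p2": 0.0315053739356632,
  "xb_p3": 0.07890962288759291,
  "ca_m": 4.1568803198494855e-05,
  "nadh": 0.6166076959343115,
  "adp_m": 0.009169382259091623,
  "dpsi": 185.75403633969356,
  "na_m": 28.49669150208899,
  "isoc": 0.19748161198647815,
  "akg": 0.2520230952985342,
  "scoa": 0.010065022883778934,
  "suc": 0.0022472814422648786,
  "fum": 0.05094051089370612,
  "mal": 0.04381019402812692,
  "oaa": 0.003432283467869859,
  "adp_i": 0.01971307142390677,
  "crp": 19.69424190624264
 }
}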