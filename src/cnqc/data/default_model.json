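{
 "format_version": 1,
 "kernel": "rbf",
 "gamma": 0.4,
 "C": 1.0,
 "support_vectors": [
  [
   -0.5945236353984468,
   -2.0862528311262243,
   -0.8079802757650066,
   -0.33956980165386497
  ],
  [
   -0.36012143285920883,
   -2.2213728331421714,
   -0.8035315351209971,
   -0.3547304654220158
  ],
  [
   0.9598245680646059,
   -0.005404800080637964,
   -0.6656205751567024,
   -0.3442252446988075
  ],
  [
   0.6867709505652668,
   0.2107872031448775,
   -0.6834155377327404,
   -0.34454286416626306
  ],
  [
   0.3528101873065173,
   -1.1404128170145942,
   -0.7190054628848165,
   -0.3488606432401354
  ],
  [
   -0.6968372585665633,
   0.9134112136278028,
   -0.8213264976970351,
   -0.34265230257066953
  ],
  [
   -0.6965301565870244,
   0.9134112136278028,
   -0.8213264976970351,
   -0.3469373833321002
  ],
  [
   -0.1624370528809959,
   0.9134112136278028,
   0.8336050218745014,
   -0.14909471932983068
  ],
  [
   0.01332904798732684,
   -0.9782688145954576,
   0.7891176154344063,
   -0.15523630753256157
  ],
  [
   -0.04258580279272344,
   -0.005404800080637964,
   0.7846688747903967,
   -0.14090478626148542
  ],
  [
   0.020959201020939636,
   0.8863872132246133,
   0.8024638373664348,
   -0.14940798472967814
  ],
  [
   -0.07918170003334987,
   -1.6538688246751934,
   0.8580730954165536,
   -0.1683245284362635
  ],
  [
   1.9588254023446883,
   -0.5188608077412372,
   1.5654228578140652,
   -1.0580838259526943
  ],
  [
   2.2652435456373348,
   0.9134112136278028,
   1.583217820390103,
   -1.0565491642877447
  ],
  [
   2.513631278758321,
   -1.9781568295134666,
   1.405268194629723,
   -1.0606003377327249
  ],
  [
   4.611894999850334,
   -0.3567168053221006,
   1.747821224218455,
   -1.058104030661536
  ],
  [
   -0.29350679800321117,
   0.8863872132246133,
   1.4074925649517276,
   -1.060349840305839
  ],
  [
   0.10887021044059499,
   -2.059228830723035,
   1.4297362681717751,
   -1.0586489547898015
  ],
  [
   4.073757444075049,
   -1.194460817820973,
   1.43196063849378,
   -1.0566275505783556
  ],
  [
   -0.6969657319627376,
   0.9134112136278028,
   -0.8302239789850542,
   1.866125428747103
  ]
 ],
 "dual_coef": [
  -0.6563818576227708,
  -0.7772172329615324,
  -1.0,
  -0.11256257358549243,
  -0.44178646587098747,
  -1.0,
  -0.5199228993373286,
  0.04527120338084884,
  0.0002853723263957494,
  0.3513334035426987,
  0.7769330124680626,
  0.93999712496967,
  0.11707596445757888,
  0.42203530717380605,
  0.4025195456018512,
  0.4129945762544771,
  0.059459646456436206,
  0.09116943126628661,
  0.13312517839567017,
  0.7556712630843296
 ],
 "intercept": 0.4465942929598963,
 "scale_mean": [
  2.046796801784406,
  86.2,
  395.24,
  0.21933642489813635
 ],
 "scale_sd": [
  1.4541474311581963,
  37.00414391209,
  449.5654298690392,
  0.20142846761075311
 ],
 "platt_a": 8.70055620801092,
 "platt_b": 0.10186097491406193,
 "min_v": 22.0,
 "min_sigma": 0.005499962066700426,
 "thr1": 1.5,
 "thr2": 2.5
}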