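{
 "sample_ids": [
  "S0001",
  "S0002",
  "S0003",
  "S0004",
  "S0005",
  "S0006",
  "S0007",
  "S0008",
  "S0009",
  "S0010",
  "S0011",
  "S0012"
 ],
 "aps": [
  0.43175853018372706,
  0.06720430107526881,
  -0.07246376811594193,
  -0.41256830601092875,
  0.19047619047619052,
  -0.6875,
  0.02964205816554827,
  -0.5779569892473118,
  0.07801418439716318,
  0.25333333333333347,
  0.3192488262910799,
  0.36029411764705893
 ],
 "tmb": [
  1.236842105263158,
  4.2368421052631575,
  12.052631578947368,
  1.868421052631579,
  4.447368421052632,
  3.3947368421052633,
  4.2368421052631575,
  4.526315789473684,
  2.236842105263158,
  2.973684210526316,
  1.8421052631578947,
  1.8157894736842106
 ],
 "b2m_lof": [
  false,
  false,
  false,
  false,
  false,
  true,
  false,
  false,
  false,
  false,
  false,
  false
 ],
 "aps_normalized": [
  1.0,
  0.6389535249355386,
  0.5006293469830082,
  0.16379730731441794,
  0.7610392877357219,
  0.0,
  0.6017527072924798,
  0.0,
  0.6496593951671713,
  0.8232916168794416,
  0.8885728685679262,
  0.9292232206384851
 ],
 "tigs": [
  0.8050650967639307,
  1.0579272773021045,
  1.2861116694585104,
  0.17260333269695466,
  1.2900625320460863,
  0.0,
  0.996333189177301,
  0.0,
  0.7630887533478518,
  1.1358902382085652,
  0.928154406886171,
  0.9619715323601399
 ],
 "auc_tigs_response": 0.8125,
 "response": [
  0.0,
  0.0,
  1.0,
  1.0,
  1.0,
  0.0,
  0.0,
  0.0,
  0.0,
  1.0,
  0.0,
  0.0
 ]
}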