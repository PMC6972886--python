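{
 "catalyzed": {
  "per_group_kcal_mol": {
   "bulk_water": 9.068478,
   "cage": -1.041286,
   "complexed_water": -13.625601
  },
  "total_kcal_mol": -5.598409
 },
 "difference_kcal_mol": -4.89134,
 "uncatalyzed": {
  "per_group_kcal_mol": {
   "bulk_water": 10.588085,
   "complexed_water": -11.295154
  },
  "total_kcal_mol": -0.707069
 }
}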