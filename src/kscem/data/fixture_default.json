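{
 "n_malignant": 47,
 "n_benign": 21,
 "tables": {
  "benign": {
   "mri": {
    "2": 6,
    "3": 10,
    "5": 4,
    "7": 1
   },
   "cem": {
    "2": 6,
    "3": 10,
    "5": 4,
    "7": 1
   }
  },
  "malignant": {
   "mri": {
    "3": 4,
    "4": 1,
    "6": 2,
    "7": 3,
    "8": 12,
    "9": 18,
    "10": 4,
    "11": 3
   },
   "cem": {
    "3": 5,
    "4": 1,
    "6": 3,
    "7": 2,
    "8": 12,
    "9": 17,
    "10": 4,
    "11": 3
   }
  }
 }
}
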