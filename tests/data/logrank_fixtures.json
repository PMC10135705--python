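{
 "seed": 20240901,
 "n_cohorts": 50,
 "fixtures": [
  {
   "n_a": 19,
   "n_b": 19,
   "chi_square": 6.2585730315563195
  },
  {
   "n_a": 20,
   "n_b": 18,
   "chi_square": 0.07566788637431239
  },
  {
   "n_a": 23,
   "n_b": 16,
   "chi_square": 0.7786815864776057
  },
  {
   "n_a": 27,
   "n_b": 21,
   "chi_square": 3.446519142729754
  },
  {
   "n_a": 25,
   "n_b": 7,
   "chi_square": 2.024743859008776
  },
  {
   "n_a": 7,
   "n_b": 17,
   "chi_square": 3.444509273805191
  },
  {
   "n_a": 7,
   "n_b": 29,
   "chi_square": 1.3772600315942574
  },
  {
   "n_a": 16,
   "n_b": 15,
   "chi_square": 1.1821103909831714
  },
  {
   "n_a": 5,
   "n_b": 30,
   "chi_square": 2.1028827290821352
  },
  {
   "n_a": 25,
   "n_b": 16,
   "chi_square": 5.4997597415420945
  },
  {
   "n_a": 14,
   "n_b": 17,
   "chi_square": 5.385383058677371
  },
  {
   "n_a": 15,
   "n_b": 27,
   "chi_square": 2.6524117226006574
  },
  {
   "n_a": 12,
   "n_b": 20,
   "chi_square": 2.20366217935692
  },
  {
   "n_a": 9,
   "n_b": 29,
   "chi_square": 2.0131049288986285
  },
  {
   "n_a": 5,
   "n_b": 29,
   "chi_square": 1.1392212250625395
  },
  {
   "n_a": 13,
   "n_b": 29,
   "chi_square": 0.002744063297462048
  },
  {
   "n_a": 11,
   "n_b": 20,
   "chi_square": 2.9975613343407117
  },
  {
   "n_a": 14,
   "n_b": 23,
   "chi_square": 0.1770103612225157
  },
  {
   "n_a": 27,
   "n_b": 23,
   "chi_square": 7.142661625973699
  },
  {
   "n_a": 22,
   "n_b": 20,
   "chi_square": 3.545677852779499
  },
  {
   "n_a": 16,
   "n_b": 13,
   "chi_square": 0.17331792331321536
  },
  {
   "n_a": 5,
   "n_b": 20,
   "chi_square": 0.033303969127934936
  },
  {
   "n_a": 29,
   "n_b": 16,
   "chi_square": 0.004624832791245336
  },
  {
   "n_a": 22,
   "n_b": 13,
   "chi_square": 0.14696623784567778
  },
  {
   "n_a": 26,
   "n_b": 14,
   "chi_square": 1.7541557203697729
  },
  {
   "n_a": 22,
   "n_b": 29,
   "chi_square": 1.4209188649724789
  },
  {
   "n_a": 28,
   "n_b": 9,
   "chi_square": 0.028264811817720184
  },
  {
   "n_a": 16,
   "n_b": 25,
   "chi_square": 2.2777566563943252
  },
  {
   "n_a": 7,
   "n_b": 16,
   "chi_square": 0.01524069783350029
  },
  {
   "n_a": 19,
   "n_b": 15,
   "chi_square": 3.61266200767379
  },
  {
   "n_a": 23,
   "n_b": 20,
   "chi_square": 0.46317053818166953
  },
  {
   "n_a": 11,
   "n_b": 27,
   "chi_square": 2.5493245294667646
  },
  {
   "n_a": 24,
   "n_b": 18,
   "chi_square": 0.030631378123375144
  },
  {
   "n_a": 27,
   "n_b": 19,
   "chi_square": 0.14245709299055614
  },
  {
   "n_a": 6,
   "n_b": 15,
   "chi_square": 0.3503991707772707
  },
  {
   "n_a": 29,
   "n_b": 19,
   "chi_square": 4.365635395819519
  },
  {
   "n_a": 7,
   "n_b": 16,
   "chi_square": 2.080007414136421
  },
  {
   "n_a": 30,
   "n_b": 13,
   "chi_square": 0.6127416127300652
  },
  {
   "n_a": 16,
   "n_b": 25,
   "chi_square": 4.132964100932635
  },
  {
   "n_a": 9,
   "n_b": 5,
   "chi_square": 0.550888243065244
  },
  {
   "n_a": 11,
   "n_b": 19,
   "chi_square": 4.273783159945961
  },
  {
   "n_a": 24,
   "n_b": 27,
   "chi_square": 2.308065835765994
  },
  {
   "n_a": 23,
   "n_b": 16,
   "chi_square": 1.143009201207745
  },
  {
   "n_a": 21,
   "n_b": 28,
   "chi_square": 0.612843699364574
  },
  {
   "n_a": 22,
   "n_b": 24,
   "chi_square": 3.5400828679979317
  },
  {
   "n_a": 18,
   "n_b": 15,
   "chi_square": 0.0013885168105585359
  },
  {
   "n_a": 6,
   "n_b": 23,
   "chi_square": 0.022953524005634905
  },
  {
   "n_a": 8,
   "n_b": 17,
   "chi_square": 0.5863229590781781
  },
  {
   "n_a": 29,
   "n_b": 29,
   "chi_square": 4.198131374856461
  },
  {
   "n_a": 30,
   "n_b": 5,
   "chi_square": 3.814130023746107
  }
 ]
}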