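{
 "format_version": 1,
 "coefficients": {
  "intercept": -4.194964945022965,
  "j": 2.519968980271908,
  "l": 0.643175567924696
 },
 "cv_folds": 10,
 "regularization": 1.0,
 "zero_mass": 0.001666666666666668,
 "cells": [
  [
   2,
   5,
   3.7570345335514377,
   100
  ],
  [
   2,
   10,
   5.3288580975526605,
   100
  ],
  [
   3,
   5,
   6.898769519980162,
   100
  ],
  [
   3,
   10,
   10.401634052523182,
   99
  ],
  [
   4,
   5,
   8.875813151132457,
   100
  ],
  [
   4,
   10,
   13.769556485589028,
   100
  ]
 ]
}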