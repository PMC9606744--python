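{
 "n_raters": 35,
 "means": {
  "S": {
   "F1": [
    0.429,
    0.679,
    0.9
   ],
   "F2": [
    0.343,
    0.593,
    0.843
   ],
   "F3": [
    0.35,
    0.6,
    0.843
   ],
   "F4": [
    0.357,
    0.607,
    0.829
   ],
   "F5": [
    0.293,
    0.543,
    0.779
   ],
   "F6": [
    0.364,
    0.614,
    0.85
   ]
  },
  "O": {
   "F1": [
    0.414,
    0.664,
    0.893
   ],
   "F2": [
    0.4,
    0.65,
    0.871
   ],
   "F3": [
    0.314,
    0.564,
    0.8
   ],
   "F4": [
    0.357,
    0.607,
    0.843
   ],
   "F5": [
    0.314,
    0.564,
    0.807
   ],
   "F6": [
    0.364,
    0.614,
    0.843
   ]
  },
  "D": {
   "F1": [
    0.429,
    0.679,
    0.893
   ],
   "F2": [
    0.364,
    0.614,
    0.821
   ],
   "F3": [
    0.314,
    0.564,
    0.807
   ],
   "F4": [
    0.336,
    0.586,
    0.807
   ],
   "F5": [
    0.329,
    0.579,
    0.807
   ],
   "F6": [
    0.407,
    0.657,
    0.836
   ]
  }
 }
}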