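{
 "options": [
  "traditional_rpn",
  "fuzzy_rpn"
 ],
 "votes": {
  "Expert 1": "fuzzy_rpn",
  "Expert 2": "fuzzy_rpn",
  "Expert 3": "fuzzy_rpn",
  "Expert 4": "fuzzy_rpn",
  "Expert 5": "fuzzy_rpn",
  "Expert 6": "traditional_rpn",
  "Expert 7": "traditional_rpn",
  "Expert 8": "fuzzy_rpn",
  "Expert 9": "fuzzy_rpn",
  "Expert 10": "traditional_rpn",
  "Expert 11": "fuzzy_rpn",
  "Expert 12": "fuzzy_rpn",
  "Expert 13": "fuzzy_rpn"
 }
}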