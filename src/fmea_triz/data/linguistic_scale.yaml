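# Default five-level linguistic scale: Likert scores 1..5 mapped to
# triangular fuzzy numbers (q, o, p) on [0, 1].
levels:
  - {label: "NI (Not Important)", score: 1, q: 0.00, o: 0.00, p: 0.25}
  - {label: "LI (A Little Important)", score: 2, q: 0.00, o: 0.25, p: 0.50}
  - {label: "I (Important)", score: 3, q: 0.25, o: 0.50, p: 0.75}
  - {label: "VI (Very Important)", score: 4, q: 0.50, o: 0.75, p: 1.00}
  - {label: "EI (Extremely Important)", score: 5, q: 0.75, o: 1.00, p: 1.00}
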