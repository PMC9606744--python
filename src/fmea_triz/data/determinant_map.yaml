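# Service-quality determinant -> improving TRIZ parameter map for the
# bundled combined medical and elderly care (CMEC) case study, plus the
# case's worsening parameter set and expert screening roster.
# Only the five determinants used by the case ship as defaults; the map is
# user-extensible (add entries under `determinants`).
determinants:
  5:
    name: service adaptability
    parameter: 35   # adaptability or versatility
  7:
    name: healthcare workers' attitude
    parameter: 17   # temperature
  13:
    name: number of nursing staff
    parameter: 26   # amount of substance
  18:
    name: service capacity
    parameter: 26   # amount of substance
  20:
    name: service delivery time
    parameter: 9    # speed
worsening: [22, 36]  # loss of energy (costs), system complexity
roster: [1, 4, 21, 25, 27, 10, 28]
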