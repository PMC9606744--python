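{
 "cells": [
  {
   "improving": 9,
   "worsening": 22,
   "principles": [
    20,
    14,
    19,
    35
   ]
  },
  {
   "improving": 9,
   "worsening": 36,
   "principles": [
    10,
    28,
    4,
    34
   ]
  },
  {
   "improving": 17,
   "worsening": 22,
   "principles": [
    21,
    17,
    35,
    38
   ]
  },
  {
   "improving": 17,
   "worsening": 36,
   "principles": [
    2,
    17,
    16
   ]
  },
  {
   "improving": 26,
   "worsening": 22,
   "principles": [
    25,
    7,
    8
   ]
  },
  {
   "improving": 26,
   "worsening": 36,
   "principles": [
    3,
    13,
    10,
    27
   ]
  },
  {
   "improving": 35,
   "worsening": 22,
   "principles": [
    18,
    15,
    1
   ]
  },
  {
   "improving": 35,
   "worsening": 36,
   "principles": [
    15,
    29,
    28,
    37
   ]
  }
 ]
}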