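[
 {
  "id": "F1",
  "point": "Detection of sudden illness in the elderly",
  "situation": "Human resource misallocation",
  "causes": [
   {
    "text": "Inadequate healthcare workers",
    "determinants": [
     13
    ]
   },
   {
    "text": "Prolonged interval between ward rounds",
    "determinants": [
     5
    ]
   }
  ],
  "effects": [
   "Failure to detect the patient's illness in time, causing their condition to deteriorate"
  ]
 },
 {
  "id": "F2",
  "point": "Healthcare worker's response",
  "situation": "Slow response by healthcare workers",
  "causes": [
   {
    "text": "Inadequate healthcare workers",
    "determinants": [
     13
    ]
   },
   {
    "text": "Prolonged arrival time of healthcare workers",
    "determinants": [
     20
    ]
   }
  ],
  "effects": [
   "Inability of elderly care facilities to provide responsive services"
  ]
 },
 {
  "id": "F3",
  "point": "Healthcare worker's judgement of patient's condition",
  "situation": "Error in judgement",
  "causes": [
   {
    "text": "Inexperienced healthcare workers",
    "determinants": []
   }
  ],
  "effects": [
   "Failure causing the elderly to miss optimal treatment window, leading to death"
  ]
 },
 {
  "id": "F4",
  "point": "Provision of testing equipment",
  "situation": "Poor testing equipment",
  "causes": [
   {
    "text": "Inadequate maintenance of testing equipment",
    "determinants": []
   },
   {
    "text": "Inadequate service resources",
    "determinants": []
   }
  ],
  "effects": [
   "Failure to meet the needs of the elderly",
   "Failure causing illness in the elderly"
  ],
  "scenario": "mild"
 },
 {
  "id": "F5",
  "point": "Arranging referrals",
  "situation": "Referral delays",
  "causes": [
   {
    "text": "Inadequate healthcare workers",
    "determinants": []
   },
   {
    "text": "Prolonged arrival time of ambulances",
    "determinants": []
   }
  ],
  "effects": [
   "Failure to detect the patient's illness in time, leading to deterioration of their condition",
   "Missing the optimal treatment window"
  ],
  "scenario": "severe"
 },
 {
  "id": "F6",
  "point": "Commencing rehabilitation services",
  "situation": "Inappropriate rehabilitation services",
  "causes": [
   {
    "text": "Inadequate service resources (e.g., equipment, funding and rehabilitation staff)",
    "determinants": [
     18
    ]
   },
   {
    "text": "Impatience of nursing staff",
    "determinants": [
     7
    ]
   }
  ],
  "effects": [
   "Failure leading to the degeneration and atrophy of physical functions in the elderly"
  ]
 }
]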