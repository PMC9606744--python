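{
  "title": "CMEC service blueprint (severe illness)",
  "scenario": "severe",
  "actions": [
    {"id": "c_contact", "lane": "customer", "label": "Contact nursing staff",
     "successors": ["f_request"]},
    {"id": "c_transfer", "lane": "customer", "label": "Transfer to hospital",
     "successors": ["f_rehab"]},
    {"id": "c_rehab", "lane": "customer",
     "label": "Receive rehabilitation services after return", "successors": []},
    {"id": "f_request", "lane": "front_stage", "label": "Receive request from the elderly",
     "successors": ["f_arrive"]},
    {"id": "f_arrive", "lane": "front_stage", "label": "Arrive at the bed",
     "successors": ["b_assess"]},
    {"id": "f_referral", "lane": "front_stage", "label": "Arrange referral to hospital",
     "successors": ["c_transfer"]},
    {"id": "f_rehab", "lane": "front_stage", "label": "Perform rehabilitation activities",
     "successors": ["c_rehab"]},
    {"id": "b_assess", "lane": "back_stage",
     "label": "Assess the elderly person's health status (ward rounds)",
     "successors": ["f_referral", "s_ambulance"]},
    {"id": "s_ambulance", "lane": "support",
     "label": "Coordinate ambulance and hospital admission",
     "successors": ["f_referral"]}
  ],
  "failure_points": [
    {"failure_id": "F1", "action_id": "b_assess",
     "note": "Detection of sudden illness in the elderly"},
    {"failure_id": "F2", "action_id": "f_arrive",
     "note": "Healthcare worker's response"},
    {"failure_id": "F3", "action_id": "b_assess",
     "note": "Healthcare worker's judgement of patient's condition"},
    {"failure_id": "F5", "action_id": "f_referral",
     "note": "Arranging referrals (severe-illness scenario only)"},
    {"failure_id": "F6", "action_id": "f_rehab",
     "note": "Commencing rehabilitation services"}
  ]
}
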