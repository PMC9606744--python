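{
 "4": "S1. Differential distribution of resident healthcare workers according to the level of care needed by the elderly",
 "21": "S2. Reduce unnecessary workflows for nursing staff and speed up service completion by establishing remote ward rounds",
 "25": "S3. Guiding the elderly to voluntarily engage in self-help services",
 "10": "S4. Provide educational training and internships on CMEC services for pre-service healthcare workers",
 "27": "S5. Use of inexpensive devices and methods for CMEC services",
 "1": "S6. Segmentation of some services in CMEC institutions for outsourcing",
 "28": "S7. Building intelligent wards with telemedicine systems"
}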