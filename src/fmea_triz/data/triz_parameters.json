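{
 "1": "Weight of moving object",
 "2": "Weight of stationary object",
 "3": "Length of moving object",
 "4": "Length of stationary object",
 "5": "Area of moving object",
 "6": "Area of stationary object",
 "7": "Volume of moving object",
 "8": "Volume of stationary object",
 "9": "Speed",
 "10": "Force",
 "11": "Stress or pressure",
 "12": "Shape",
 "13": "Stability of the object's composition",
 "14": "Strength",
 "15": "Duration of action of moving object",
 "16": "Duration of action of stationary object",
 "17": "Temperature",
 "18": "Illumination intensity",
 "19": "Use of energy by moving object",
 "20": "Use of energy by stationary object",
 "21": "Power",
 "22": "Loss of energy (costs)",
 "23": "Loss of substance",
 "24": "Loss of information",
 "25": "Loss of time",
 "26": "Amount of substance",
 "27": "Reliability",
 "28": "Measurement accuracy",
 "29": "Manufacturing precision",
 "30": "External harm affecting the object",
 "31": "Object-generated harmful factors",
 "32": "Ease of manufacture",
 "33": "Ease of operation",
 "34": "Ease of repair",
 "35": "Adaptability or versatility",
 "36": "System complexity",
 "37": "Difficulty of detecting and measuring",
 "38": "Extent of automation",
 "39": "Productivity"
}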