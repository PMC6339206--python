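{
 "dimensions": [
  [
   "D1",
   "Physical capacity"
  ],
  [
   "D2",
   "Psychological state"
  ],
  [
   "D3",
   "Social relations"
  ],
  [
   "D4",
   "Environment"
  ]
 ],
 "criteria": [
  [
   "C11",
   "Pain and discomfort",
   "D1"
  ],
  [
   "C12",
   "Dependence on medical substances and medical aids",
   "D1"
  ],
  [
   "C13",
   "Energy and fatigue",
   "D1"
  ],
  [
   "C14",
   "Daily life activities",
   "D1"
  ],
  [
   "C15",
   "Sleep and rest",
   "D1"
  ],
  [
   "C16",
   "Mobility",
   "D1"
  ],
  [
   "C17",
   "Work capacity",
   "D1"
  ],
  [
   "C21",
   "Positive feelings",
   "D2"
  ],
  [
   "C22",
   "Spirituality, religion, personal beliefs, thinking, and learning",
   "D2"
  ],
  [
   "C23",
   "Memory and concentration",
   "D2"
  ],
  [
   "C24",
   "Body image",
   "D2"
  ],
  [
   "C25",
   "Self-esteem",
   "D2"
  ],
  [
   "C26",
   "Negative feelings",
   "D2"
  ],
  [
   "C31",
   "Personal relationships",
   "D3"
  ],
  [
   "C32",
   "Relationship between husband and wife",
   "D3"
  ],
  [
   "C33",
   "Social support",
   "D3"
  ],
  [
   "C34",
   "Respected by others",
   "D3"
  ],
  [
   "C41",
   "Freedom, physical safety, and security",
   "D4"
  ],
  [
   "C42",
   "Physical environment",
   "D4"
  ],
  [
   "C43",
   "Financial resources",
   "D4"
  ],
  [
   "C44",
   "Opportunities for acquiring new information and skills",
   "D4"
  ],
  [
   "C45",
   "Participation in and opportunities for recreation activities",
   "D4"
  ],
  [
   "C46",
   "Home environment",
   "D4"
  ],
  [
   "C47",
   "Health and social care: accessibility and quality",
   "D4"
  ],
  [
   "C48",
   "Transport",
   "D4"
  ],
  [
   "C49",
   "Convenience of dining",
   "D4"
  ]
 ],
 "influence_scale": [
  0,
  4
 ],
 "performance_scale": [
  0.0,
  7.0
 ],
 "f_aspired": 7.0,
 "f_worst": 0.0
}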