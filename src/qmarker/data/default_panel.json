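{
  "total_herbs": 19,
  "markers": [
    {"id": "hesperidin", "neutral_formula": "C28H34O15", "polarity": "negative", "herbs": ["Chenpi", "Zhishi"]},
    {"id": "saikosaponin_a", "neutral_formula": "C42H68O13", "polarity": "negative", "herbs": ["Chaihu"]},
    {"id": "caffeine", "neutral_formula": "C8H10N4O2", "polarity": "positive", "herbs": ["Hongcha"]},
    {"id": "senkyunolide_a", "neutral_formula": "C12H16O2", "polarity": "positive", "herbs": ["Chuanxiong"]},
    {"id": "magnolol", "neutral_formula": "C18H18O2", "polarity": "negative", "herbs": ["Houpo"]},
    {"id": "glycyrrhetinic_acid_18b", "neutral_formula": "C30H46O4", "polarity": "negative", "herbs": ["Gancao"]}
  ]
}
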