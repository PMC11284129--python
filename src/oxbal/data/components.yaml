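- name: dietary_fiber
  cls: dietary
  polarity: antioxidant
  rule: tertile
- name: carotene
  cls: dietary
  polarity: antioxidant
  rule: tertile
- name: riboflavin
  cls: dietary
  polarity: antioxidant
  rule: tertile
- name: niacin
  cls: dietary
  polarity: antioxidant
  rule: tertile
- name: vitamin_b6
  cls: dietary
  polarity: antioxidant
  rule: tertile
- name: total_folate
  cls: dietary
  polarity: antioxidant
  rule: tertile
- name: vitamin_b12
  cls: dietary
  polarity: antioxidant
  rule: tertile
- name: vitamin_c
  cls: dietary
  polarity: antioxidant
  rule: tertile
- name: vitamin_e
  cls: dietary
  polarity: antioxidant
  rule: tertile
- name: calcium
  cls: dietary
  polarity: antioxidant
  rule: tertile
- name: magnesium
  cls: dietary
  polarity: antioxidant
  rule: tertile
- name: zinc
  cls: dietary
  polarity: antioxidant
  rule: tertile
- name: copper
  cls: dietary
  polarity: antioxidant
  rule: tertile
- name: selenium
  cls: dietary
  polarity: antioxidant
  rule: tertile
- name: total_fat
  cls: dietary
  polarity: prooxidant
  rule: tertile
- name: iron
  cls: dietary
  polarity: prooxidant
  rule: tertile
- name: physical_activity
  cls: lifestyle
  polarity: antioxidant
  rule: tertile
- name: bmi
  cls: lifestyle
  polarity: prooxidant
  rule: tertile
- name: cotinine
  cls: lifestyle
  polarity: prooxidant
  rule: tertile
- name: alcohol
  cls: lifestyle
  polarity: prooxidant
  rule: alcohol
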