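# Packaged six-intent nursing-care fixture ontology.
# Slot values follow the printed sample-value inventory for each intent's
# entities; shared record slots (start-time, stop-time, target) carry the
# time-expression and care-target shapes described for the data model.
# change-diaper has no printed activity-class inventory, so its activity
# slot (diaper-type) is populated from the printed sample utterances.
version: "1.0"
slots:
  - name: vital-type
    kind: activity
    values: [blood pressure, body temperature, pulse beats]
    synonyms:
      blood pressure: [pressure]
      pulse beats: [beats, heartbeats]
  - name: vital-value
    kind: record
    values: [mmHg, systolic BP, c, celcius, bpm, heartrate, systolic blood pressure]
    number_prefixes: ["103", "114", "80", "39", "155", "88"]
  - name: oral-type
    kind: activity
    values: [mouth, dentures, partial denture, orthodontic braces]
    synonyms:
      partial denture: [partial dentures]
  - name: oral-material
    kind: record
    values: [interdental brushes, dental floss, detergent, water]
    synonyms:
      detergent: [detergents, dishwashing liquid]
  - name: toilet-type
    kind: activity
    values: [portable toilets, port potty, urinals, waterless urinal]
    synonyms:
      port potty: [porta potty]
  - name: toilet-place
    kind: record
    values: [toilets, lavatory, restroom, bathroom, loo]
  - name: meal-type
    kind: record
    values: [breakfasts, lunch, brunch, dinner, meal, supper]
  - name: food-type
    kind: activity
    values: [noodles, tofu, vegetable soup, chicken soup, fruits]
    synonyms:
      noodles: [udon]
  - name: bath-type
    kind: activity
    values: [baths, shower, wipe]
  - name: bath-material
    kind: record
    values: [lift, steal, bar stool, worktable, swivel chair]
    synonyms:
      swivel chair: [bath transfer chairs]
  - name: diaper-type
    kind: activity
    values: [dirty diaper, soiled diaper, nappies]
  - name: start-time
    kind: record
    values: [8 a.m., half-past six, 10:30 p.m., noon]
  - name: stop-time
    kind: record
    values: [9 a.m., 11 o'clock, seven in the evening]
  - name: target
    kind: record
    values: [patient A, patient B, patient's room 303]
intents:
  - name: add-vital
    verbs: [add, set, put]
    activity_slot: vital-type
    record_templates:
      - {preposition: with, slot: vital-value, pattern: 1}
      - {preposition: to, modifiers: [a], slot: target, pattern: 2}
      - {preposition: at, slot: start-time, pattern: 1}
  - name: clean-oral
    verbs: [clean, wash, brush]
    activity_slot: oral-type
    record_templates:
      - {preposition: with, slot: oral-material, pattern: 1}
      - {preposition: for, modifiers: [a], slot: target, pattern: 2}
      - {preposition: at, slot: start-time, pattern: 1}
  - name: assist-toilet
    verbs: [help to use, assist to use]
    activity_slot: toilet-type
    record_templates:
      - {preposition: at, slot: toilet-place, pattern: 1}
      - {preposition: for, modifiers: [a], slot: target, pattern: 2}
      - {preposition: since, slot: start-time, pattern: 1}
  - name: prepare-meal
    verbs: [prepare, make, cook]
    activity_slot: food-type
    record_templates:
      - {preposition: for, slot: meal-type, pattern: 1}
      - {preposition: to, modifiers: [a], slot: target, pattern: 2}
      - {preposition: at, slot: start-time, pattern: 1}
  - name: assist-bath
    verbs: [help to, assist to]
    activity_slot: bath-type
    record_templates:
      - {preposition: with, slot: bath-material, pattern: 1}
      - {preposition: for, modifiers: [a], slot: target, pattern: 2}
      - {preposition: at, slot: start-time, pattern: 1}
  - name: change-diaper
    verbs: [change, help to change]
    activity_slot: diaper-type
    record_templates:
      - {preposition: at, slot: toilet-place, pattern: 1}
      - {preposition: until, slot: stop-time, pattern: 1}
      - {preposition: for, modifiers: [a], slot: target, pattern: 2}
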