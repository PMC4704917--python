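{
  "_comment": "Declared instrument configurations: item counts, response-scale bounds, reverse-keyed item ids (1-based) and the TFEQ-R18 subscale partition. Scale content for the borrowed instruments is fixture configuration, not a transcription of the original questionnaires.",
  "conscientiousness": {
    "n_items": 15,
    "item_min": 1,
    "item_max": 5,
    "reversed": [2, 4, 6, 8, 10]
  },
  "fear_of_negative_evaluation": {
    "n_items": 5,
    "item_min": 1,
    "item_max": 5,
    "reversed": []
  },
  "social_desirability": {
    "n_items": 7,
    "item_min": 0,
    "item_max": 1,
    "reversed": [2, 5]
  },
  "tfeq_r18": {
    "n_items": 18,
    "item_min": 1,
    "item_max": 4,
    "reversed": [],
    "subscales": {
      "cognitive_restraint": [2, 11, 12, 15, 16, 18],
      "uncontrolled_eating": [1, 4, 5, 7, 8, 9, 13, 14, 17],
      "emotional_eating": [3, 6, 10]
    }
  },
  "figure_rating_scale": {
    "min": 1,
    "max": 9
  }
}
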