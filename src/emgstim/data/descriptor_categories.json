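{
  "vibration": "tactile",
  "pressure": "tactile",
  "tickling": "tactile",
  "tingle": "tactile",
  "electrical": "tactile",
  "pulsing": "tactile",
  "buzzing": "tactile",
  "tap": "tactile",
  "contraction": "proprioceptive",
  "movement": "proprioceptive",
  "tight": "proprioceptive",
  "sharp": "pain",
  "ache": "pain",
  "shock": "pain"
}
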