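{
 "description": "synthetic schematic chick lumbar hemicord template; a stand-in for the atlas-derived laminar polygons, not a measured atlas",
 "units": "um",
 "lamina_order": [
  "I",
  "II",
  "III",
  "IV",
  "V",
  "VI",
  "VII",
  "VIII",
  "IX",
  "X"
 ],
 "landmarks": {
  "central_canal": [
   50.0,
   620.0
  ],
  "dorsal_pole": [
   160.0,
   1600.0
  ],
  "ventral_midline": [
   0.0,
   0.0
  ],
  "lateral_extreme": [
   900.0,
   450.0
  ]
 }
}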