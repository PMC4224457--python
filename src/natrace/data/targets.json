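{
 "sugar": {
  "name": "sugar",
  "high_probes": [
   [
    0.9504860324891409,
    -0.6252601199845165,
    0.48868000000000045
   ],
   [
    0.4963006731869126,
    0.7779712612906833,
    0.8624800000000006
   ],
   [
    -0.9311617776916759,
    0.8043947609016842,
    0.3136800000000006
   ],
   [
    -0.9160347765056824,
    -0.17774515979959737,
    -0.8550199999999997
   ],
   [
    0.400409848521305,
    -0.7793607424082545,
    -0.8098199999999998
   ],
   [
    -1.3020736016693302,
    -1.5484556272092065,
    -0.3309199999999999
   ],
   [
    -1.7627348191768824,
    0.3030595071292792,
    1.3552800000000005
   ],
   [
    0.49497141099806097,
    -1.746066918504153,
    1.3098800000000006
   ],
   [
    -0.23399434780987016,
    -3.539708087881972,
    2.6240566540304044
   ]
  ],
  "low_probes": [
   [
    -1.49985,
    3.49965,
    -3.49965
   ],
   [
    -4.49955,
    1.9998,
    -2.49975
   ],
   [
    -3.49965,
    0.49995,
    -4.49955
   ],
   [
    1.9998,
    3.9996,
    -3.9996
   ],
   [
    3.9996,
    1.9998,
    3.9996
   ],
   [
    -5.49945,
    -0.49995,
    -1.9998
   ],
   [
    -3.9996,
    -1.9998,
    -3.9996
   ],
   [
    0.0,
    5.9994,
    0.0
   ],
   [
    5.49945,
    1.49985,
    1.49985
   ]
  ],
  "high_names": [
   "C1'",
   "C2'",
   "C3'",
   "C4'",
   "O4'",
   "C5'",
   "O3'",
   "N9",
   "extra0"
  ],
  "frame_atoms": {
   "P": [
    1.2822908319557538,
    -1.5551879532333768,
    -0.14402000000000026
   ],
   "OP1": [
    1.608102497920442,
    -0.6410460122191193,
    0.9685800000000002
   ],
   "OP2": [
    2.252928779599302,
    -2.6212014168417497,
    -0.46232000000000006
   ],
   "O5'": [
    -0.13551979754718868,
    -2.2209035598316214,
    0.1381800000000002
   ],
   "C5'": [
    -1.3020736016693302,
    -1.5484556272092065,
    -0.3309199999999999
   ],
   "C4'": [
    -0.9160347765056824,
    -0.17774515979959737,
    -0.8550199999999997
   ],
   "O4'": [
    0.400409848521305,
    -0.7793607424082545,
    -0.8098199999999998
   ],
   "C3'": [
    -0.9311617776916759,
    0.8043947609016842,
    0.3136800000000006
   ],
   "O3'": [
    -1.7627348191768824,
    0.3030595071292792,
    1.3552800000000005
   ],
   "C2'": [
    0.4963006731869126,
    0.7779712612906833,
    0.8624800000000006
   ],
   "C1'": [
    0.9504860324891409,
    -0.6252601199845165,
    0.48868000000000045
   ],
   "O2'": [
    1.27905045614256,
    1.746318527142603,
    0.19188000000000027
   ],
   "N9": [
    0.49497141099806097,
    -1.746066918504153,
    1.3098800000000006
   ],
   "C4": [
    -0.5041019205493842,
    -2.633460837832505,
    0.9840613649742798
   ],
   "C5": [
    -0.6261928161707049,
    -3.5338820882885758,
    2.016586743710211
   ],
   "N7": [
    0.2974241921658489,
    -3.202979105934757,
    2.9805411570415954
   ],
   "C8": [
    0.9903417915266539,
    -2.0980485654053203,
    2.5437723693499237
   ]
  }
 },
 "phosphate": {
  "name": "phosphate",
  "high_probes": [
   [
    0.6332773334054682,
    -0.20813206623405867,
    -0.5151599999999998
   ],
   [
    0.9590889993701563,
    0.7060098747801988,
    0.5974400000000006
   ],
   [
    1.6039152810490163,
    -1.2741455298424316,
    -0.8334599999999996
   ],
   [
    -0.7845332960974742,
    -0.8738476728323032,
    -0.2329599999999994
   ],
   [
    0.36698158554570304,
    0.6522628685177119,
    -1.8258599999999996
   ]
  ],
  "low_probes": [
   [
    5.49945,
    1.49985,
    0.0
   ],
   [
    5.49945,
    -0.49995,
    -1.49985
   ],
   [
    -4.9995,
    2.9997,
    0.49995
   ],
   [
    1.9998,
    5.49945,
    0.49995
   ],
   [
    -2.9997,
    4.9995,
    0.0
   ]
  ],
  "high_names": [
   "P",
   "OP1",
   "OP2",
   "O5'",
   "O3'"
  ],
  "frame_atoms": {
   "O3'": [
    0.36698158554570304,
    0.6522628685177119,
    -1.8258599999999996
   ],
   "P": [
    0.6332773334054682,
    -0.20813206623405867,
    -0.5151599999999998
   ],
   "OP1": [
    0.9590889993701563,
    0.7060098747801988,
    0.5974400000000006
   ],
   "OP2": [
    1.6039152810490163,
    -1.2741455298424316,
    -0.8334599999999996
   ],
   "O5'": [
    -0.7845332960974742,
    -0.8738476728323032,
    -0.2329599999999994
   ]
  }
 }
}
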