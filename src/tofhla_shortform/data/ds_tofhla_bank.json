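{
 "name": "ds_tofhla",
 "items": [
  {
   "item_id": "R1",
   "part": "reading",
   "position": 1,
   "set_id": "S01"
  },
  {
   "item_id": "R2",
   "part": "reading",
   "position": 2,
   "set_id": "S02"
  },
  {
   "item_id": "R3",
   "part": "reading",
   "position": 3,
   "set_id": "S02"
  },
  {
   "item_id": "R4",
   "part": "reading",
   "position": 4,
   "set_id": "S03"
  },
  {
   "item_id": "R5",
   "part": "reading",
   "position": 5,
   "set_id": "S03"
  },
  {
   "item_id": "R6",
   "part": "reading",
   "position": 6,
   "set_id": "S03"
  },
  {
   "item_id": "R7",
   "part": "reading",
   "position": 7,
   "set_id": "S03"
  },
  {
   "item_id": "R8",
   "part": "reading",
   "position": 8,
   "set_id": "S03"
  },
  {
   "item_id": "R9",
   "part": "reading",
   "position": 9,
   "set_id": "S03"
  },
  {
   "item_id": "R10",
   "part": "reading",
   "position": 10,
   "set_id": "S04"
  },
  {
   "item_id": "R11",
   "part": "reading",
   "position": 11,
   "set_id": "S04"
  },
  {
   "item_id": "R12",
   "part": "reading",
   "position": 12,
   "set_id": "S05"
  },
  {
   "item_id": "R13",
   "part": "reading",
   "position": 13,
   "set_id": "S06"
  },
  {
   "item_id": "R14",
   "part": "reading",
   "position": 14,
   "set_id": "S06"
  },
  {
   "item_id": "R15",
   "part": "reading",
   "position": 15,
   "set_id": "S07"
  },
  {
   "item_id": "R16",
   "part": "reading",
   "position": 16,
   "set_id": "S07"
  },
  {
   "item_id": "R17",
   "part": "reading",
   "position": 17,
   "set_id": "S08"
  },
  {
   "item_id": "R18",
   "part": "reading",
   "position": 18,
   "set_id": "S09"
  },
  {
   "item_id": "R19",
   "part": "reading",
   "position": 19,
   "set_id": "S09"
  },
  {
   "item_id": "R20",
   "part": "reading",
   "position": 20,
   "set_id": "S09"
  },
  {
   "item_id": "R21",
   "part": "reading",
   "position": 21,
   "set_id": "S09"
  },
  {
   "item_id": "R22",
   "part": "reading",
   "position": 22,
   "set_id": "S10"
  },
  {
   "item_id": "R23",
   "part": "reading",
   "position": 23,
   "set_id": "S11"
  },
  {
   "item_id": "R24",
   "part": "reading",
   "position": 24,
   "set_id": "S11"
  },
  {
   "item_id": "R25",
   "part": "reading",
   "position": 25,
   "set_id": "S11"
  },
  {
   "item_id": "R26",
   "part": "reading",
   "position": 26,
   "set_id": "S12"
  },
  {
   "item_id": "R27",
   "part": "reading",
   "position": 27,
   "set_id": "S12"
  },
  {
   "item_id": "R28",
   "part": "reading",
   "position": 28,
   "set_id": "S12"
  },
  {
   "item_id": "R29",
   "part": "reading",
   "position": 29,
   "set_id": "S12"
  },
  {
   "item_id": "R30",
   "part": "reading",
   "position": 30,
   "set_id": "S12"
  },
  {
   "item_id": "R31",
   "part": "reading",
   "position": 31,
   "set_id": "S13"
  },
  {
   "item_id": "R32",
   "part": "reading",
   "position": 32,
   "set_id": "S13"
  },
  {
   "item_id": "R33",
   "part": "reading",
   "position": 33,
   "set_id": "S13"
  },
  {
   "item_id": "R34",
   "part": "reading",
   "position": 34,
   "set_id": "S13"
  },
  {
   "item_id": "R35",
   "part": "reading",
   "position": 35,
   "set_id": "S14"
  },
  {
   "item_id": "R36",
   "part": "reading",
   "position": 36,
   "set_id": "S14"
  },
  {
   "item_id": "R37",
   "part": "reading",
   "position": 37,
   "set_id": "S15"
  },
  {
   "item_id": "R38",
   "part": "reading",
   "position": 38,
   "set_id": "S15"
  },
  {
   "item_id": "R39",
   "part": "reading",
   "position": 39,
   "set_id": "S15"
  },
  {
   "item_id": "R40",
   "part": "reading",
   "position": 40,
   "set_id": "S15"
  },
  {
   "item_id": "R41",
   "part": "reading",
   "position": 41,
   "set_id": "S15"
  },
  {
   "item_id": "R42",
   "part": "reading",
   "position": 42,
   "set_id": "S16"
  },
  {
   "item_id": "R43",
   "part": "reading",
   "position": 43,
   "set_id": "S16"
  },
  {
   "item_id": "R44",
   "part": "reading",
   "position": 44,
   "set_id": "S16"
  },
  {
   "item_id": "R45",
   "part": "reading",
   "position": 45,
   "set_id": "S16"
  },
  {
   "item_id": "R46",
   "part": "reading",
   "position": 46,
   "set_id": "S17"
  },
  {
   "item_id": "R47",
   "part": "reading",
   "position": 47,
   "set_id": "S17"
  },
  {
   "item_id": "R48",
   "part": "reading",
   "position": 48,
   "set_id": "S18"
  },
  {
   "item_id": "R49",
   "part": "reading",
   "position": 49,
   "set_id": "S19"
  },
  {
   "item_id": "R50",
   "part": "reading",
   "position": 50,
   "set_id": "S19"
  },
  {
   "item_id": "N1",
   "part": "numeracy",
   "position": 1,
   "set_id": null
  },
  {
   "item_id": "N2",
   "part": "numeracy",
   "position": 2,
   "set_id": null
  },
  {
   "item_id": "N3",
   "part": "numeracy",
   "position": 3,
   "set_id": null
  },
  {
   "item_id": "N4",
   "part": "numeracy",
   "position": 4,
   "set_id": null
  },
  {
   "item_id": "N5",
   "part": "numeracy",
   "position": 5,
   "set_id": null
  },
  {
   "item_id": "N6",
   "part": "numeracy",
   "position": 6,
   "set_id": null
  },
  {
   "item_id": "N7",
   "part": "numeracy",
   "position": 7,
   "set_id": null
  },
  {
   "item_id": "N8",
   "part": "numeracy",
   "position": 8,
   "set_id": null
  },
  {
   "item_id": "N9",
   "part": "numeracy",
   "position": 9,
   "set_id": null
  },
  {
   "item_id": "N10",
   "part": "numeracy",
   "position": 10,
   "set_id": null
  },
  {
   "item_id": "N11",
   "part": "numeracy",
   "position": 11,
   "set_id": null
  },
  {
   "item_id": "N12",
   "part": "numeracy",
   "position": 12,
   "set_id": null
  },
  {
   "item_id": "N13",
   "part": "numeracy",
   "position": 13,
   "set_id": null
  },
  {
   "item_id": "N14",
   "part": "numeracy",
   "position": 14,
   "set_id": null
  },
  {
   "item_id": "N15",
   "part": "numeracy",
   "position": 15,
   "set_id": null
  },
  {
   "item_id": "N16",
   "part": "numeracy",
   "position": 16,
   "set_id": null
  },
  {
   "item_id": "N17",
   "part": "numeracy",
   "position": 17,
   "set_id": null
  }
 ]
}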