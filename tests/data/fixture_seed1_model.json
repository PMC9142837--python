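{
 "format_version": 1,
 "components": [
  {
   "name": "g0",
   "role": "gene",
   "condition_menu": [
    2,
    4,
    8
   ]
  },
  {
   "name": "g1",
   "role": "gene",
   "condition_menu": [
    3,
    14,
    15
   ]
  },
  {
   "name": "g2",
   "role": "gene",
   "condition_menu": [
    6,
    12,
    15
   ]
  },
  {
   "name": "g3",
   "role": "gene",
   "condition_menu": [
    0,
    3,
    15
   ]
  },
  {
   "name": "g4",
   "role": "gene",
   "condition_menu": [
    0,
    12,
    13
   ]
  },
  {
   "name": "g5",
   "role": "gene",
   "condition_menu": [
    7,
    8,
    14
   ]
  }
 ],
 "interactions": [
  {
   "source": "g1",
   "target": "g0",
   "sign": "activate",
   "definite": true
  },
  {
   "source": "g3",
   "target": "g2",
   "sign": "activate",
   "definite": true
  },
  {
   "source": "g0",
   "target": "g1",
   "sign": "activate",
   "definite": true
  },
  {
   "source": "g5",
   "target": "g3",
   "sign": "activate",
   "definite": true
  },
  {
   "source": "g5",
   "target": "g2",
   "sign": "activate",
   "definite": true
  },
  {
   "source": "g5",
   "target": "g4",
   "sign": "activate",
   "definite": true
  },
  {
   "source": "g2",
   "target": "g5",
   "sign": "activate",
   "definite": false
  },
  {
   "source": "g0",
   "target": "g0",
   "sign": "activate",
   "definite": false
  },
  {
   "source": "g2",
   "target": "g0",
   "sign": "activate",
   "definite": false
  },
  {
   "source": "g3",
   "target": "g3",
   "sign": "activate",
   "definite": false
  }
 ]
}
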