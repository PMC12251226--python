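{
  "table1.csv": "382b6a8c0c3512de8946f44fb2564bd6f0d23e014eee1ceaae9690abf519a539",
  "table2.csv": "b489c985688d0e8a02cca499160d25036e1dace1d55416152168cc0cc0a01c99",
  "table3.csv": "600992342449dcc32f3703acb1702d1dde0a36a503c5d96e5d216e0274cd9eac",
  "table4.csv": "81f6becaa3e049d175bc507f20142c9b82441279f3481a20c73db34b6f1e7693"
}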