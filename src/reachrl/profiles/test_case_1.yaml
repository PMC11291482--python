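# Simulated stroke patient: the hard corner (zone 1) is unreachable for the
# first three sessions, then pops with difficulty for the rest of the program.
name: test_case_1
schedule:
- days: [1, 3]
  zone: 1
  pop: false
  m: [0.0, 0.0, 0.0, 0.0]
- days: [1, 3]
  zone: 2
  pop: true
  m: [0.3, 0.5, 0.7, 0.6]
- days: [1, 3]
  zone: 3
  pop: true
  m: [[0.8, 0.9], [0.8, 0.9], [0.8, 0.9], [0.8, 0.9]]
- days: [4, 6]
  zone: 1
  pop: true
  m: [0.4, 0.4, 0.4, 0.4]
- days: [4, 6]
  zone: 2
  pop: true
  m: [0.6, 0.8, 0.8, 0.9]
- days: [4, 6]
  zone: 3
  pop: true
  m: [[0.8, 0.9], [0.8, 0.9], [0.8, 0.9], [0.8, 0.9]]
- days: [7, 10]
  zone: 1
  pop: true
  m: [0.4, 0.4, 0.4, 0.4]
- days: [7, 10]
  zone: 2
  pop: true
  m: [0.6, 0.6, 0.6, 0.6]
- days: [7, 10]
  zone: 3
  pop: true
  m: [[0.8, 0.9], [0.8, 0.9], [0.8, 0.9], [0.8, 0.9]]
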