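# Simulated frozen-shoulder patient: pain removes zones 1 and 2 from reach on
# days 4-6 and degrades zone 3 to 30% of good performance; recovery follows.
name: test_case_2
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
  pop: false
  m: [0.0, 0.0, 0.0, 0.0]
- days: [4, 6]
  zone: 2
  pop: false
  m: [0.0, 0.0, 0.0, 0.0]
- days: [4, 6]
  zone: 3
  pop: true
  m: [[0.24, 0.27], [0.24, 0.27], [0.24, 0.27], [0.24, 0.27]]
- days: [7, 10]
  zone: 1
  pop: false
  m: [0.0, 0.0, 0.0, 0.0]
- days: [7, 10]
  zone: 2
  pop: true
  m: [0.3, 0.5, 0.7, 0.6]
- days: [7, 10]
  zone: 3
  pop: true
  m: [[0.8, 0.9], [0.8, 0.9], [0.8, 0.9], [0.8, 0.9]]
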