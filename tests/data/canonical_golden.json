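{
 "ADP": [
  4,
  9,
  2,
  11,
  6,
  12,
  13,
  14,
  5,
  15,
  10,
  3,
  1,
  8,
  7,
  23,
  21,
  25,
  19,
  22,
  26,
  27,
  16,
  17,
  18,
  20,
  24
 ],
 "ATP": [
  4,
  9,
  2,
  11,
  6,
  12,
  13,
  14,
  5,
  15,
  10,
  3,
  1,
  8,
  7,
  23,
  27,
  25,
  21,
  29,
  19,
  26,
  22,
  30,
  31,
  16,
  17,
  18,
  24,
  20,
  28
 ],
 "BPG13": [
  1,
  2,
  3,
  9,
  13,
  5,
  7,
  10,
  11,
  14,
  15,
  4,
  6,
  8,
  12
 ],
 "CO2": [
  1,
  2,
  3
 ],
 "DHAP": [
  2,
  1,
  3,
  8,
  4,
  9,
  10,
  5,
  6,
  7
 ],
 "F16BP": [
  2,
  3,
  4,
  5,
  1,
  6,
  18,
  14,
  7,
  12,
  19,
  20,
  15,
  16,
  8,
  9,
  10,
  11,
  17,
  13
 ],
 "F6P": [
  2,
  3,
  4,
  5,
  1,
  6,
  14,
  12,
  15,
  16,
  8,
  9,
  10,
  11,
  7,
  13
 ],
 "G6P": [
  1,
  2,
  3,
  4,
  5,
  6,
  14,
  12,
  15,
  16,
  7,
  8,
  9,
  10,
  11,
  13
 ],
 "GABA": [
  1,
  4,
  2,
  3,
  5,
  6,
  7
 ],
 "GAP": [
  1,
  2,
  3,
  8,
  6,
  9,
  10,
  4,
  5,
  7
 ],
 "PEP": [
  1,
  2,
  3,
  8,
  6,
  9,
  10,
  4,
  5,
  7
 ],
 "PG2": [
  1,
  2,
  3,
  9,
  6,
  10,
  11,
  4,
  5,
  7,
  8
 ],
 "PG3": [
  1,
  2,
  3,
  9,
  7,
  10,
  11,
  4,
  5,
  6,
  8
 ],
 "acetoacetate": [
  1,
  3,
  2,
  4,
  5,
  7,
  6
 ],
 "acetyl-CoA": [
  1,
  2,
  3,
  4
 ],
 "ammonia": [
  1
 ],
 "benzene": [
  1,
  2,
  6,
  3,
  5,
  4
 ],
 "fumarate": [
  1,
  4,
  2,
  3,
  5,
  7,
  6,
  8
 ],
 "glucose": [
  1,
  2,
  3,
  4,
  5,
  6,
  7,
  8,
  9,
  10,
  11,
  12
 ],
 "glutamate": [
  1,
  5,
  2,
  4,
  3,
  6,
  7,
  9,
  8,
  10
 ],
 "glutamine": [
  1,
  5,
  2,
  4,
  3,
  10,
  6,
  7,
  9,
  8
 ],
 "malate": [
  1,
  4,
  2,
  3,
  5,
  8,
  6,
  9,
  7
 ],
 "pyruvate": [
  1,
  2,
  3,
  4,
  6,
  5
 ],
 "water": [
  1
 ]
}
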