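# Default item keymap for the 31-item cognitive/affective empathy
# questionnaire.  Item-to-subscale assignment is configurable: published
# instrument versions differ in keying, so this file is an editable asset
# rather than a claim of fidelity to any specific printed version.
instrument: QCAE
response_min: 1
response_max: 4
subscales:
  cognitive_empathy: [1, 2, 3, 4, 5, 6, 7, 8, 9, 10, 11, 12, 13, 14, 15, 16, 17, 18, 19]
  affective_empathy: [20, 21, 22, 23, 24, 25, 26, 27, 28, 29, 30, 31]
reverse_keyed: []
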