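# Default item keymap for the 27-item short dark-triad questionnaire.
# Nine items per subscale; the narcissism subscale is parsed and
# validated but not returned by the scorer.  Reverse keying is supported
# and editable (the shipped default keys no items in reverse).
instrument: SD3
response_min: 1
response_max: 5
subscales:
  machiavellianism: [1, 2, 3, 4, 5, 6, 7, 8, 9]
  narcissism: [10, 11, 12, 13, 14, 15, 16, 17, 18]
  psychopathy: [19, 20, 21, 22, 23, 24, 25, 26, 27]
reverse_keyed: []
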