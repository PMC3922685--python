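barrelene
  ringkit

  8  9  0  0  0  0  0  0  0  0999 V2000
    0.0000    0.0000    0.0000 C  0  0  0  0  0  0  0  0  0  0  0  0
    0.0000    0.0000    0.0000 C  0  0  0  0  0  0  0  0  0  0  0  0
    0.0000    0.0000    0.0000 C  0  0  0  0  0  0  0  0  0  0  0  0
    0.0000    0.0000    0.0000 C  0  0  0  0  0  0  0  0  0  0  0  0
    0.0000    0.0000    0.0000 C  0  0  0  0  0  0  0  0  0  0  0  0
    0.0000    0.0000    0.0000 C  0  0  0  0  0  0  0  0  0  0  0  0
    0.0000    0.0000    0.0000 C  0  0  0  0  0  0  0  0  0  0  0  0
    0.0000    0.0000    0.0000 C  0  0  0  0  0  0  0  0  0  0  0  0
  1  3  1  0
  3  4  1  0
  2  4  1  0
  1  5  1  0
  5  6  1  0
  2  6  1  0
  1  7  1  0
  7  8  1  0
  2  8  1  0
M  END
$$$$
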