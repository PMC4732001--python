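# Default bond dissociation energies, kJ/mol (mean bond enthalpies).
# Format: element1 element2 order energy
# order: 1, 2, 3 or "ar" (aromatic); pairs are unordered.
# Aromatic entries are the mean of the single- and double-bond values.
H  H  1 436
C  H  1 413
C  C  1 348
C  C  2 614
C  C  3 839
C  C  ar 481
C  N  1 293
C  N  2 615
C  N  3 891
C  N  ar 454
C  O  1 358
C  O  2 799
C  O  3 1072
C  O  ar 578.5
C  F  1 485
C  Cl 1 328
C  Br 1 276
C  I  1 240
C  S  1 259
C  S  2 573
C  S  ar 416
C  P  1 264
C  Si 1 301
N  H  1 391
N  N  1 163
N  N  2 418
N  N  3 941
N  N  ar 290.5
N  O  1 201
N  O  2 607
N  O  ar 404
N  F  1 272
N  Cl 1 200
O  H  1 463
O  O  1 146
O  O  2 495
O  F  1 190
O  P  1 335
O  P  2 544
O  S  1 265
O  S  2 522
O  Si 1 368
F  F  1 155
S  H  1 339
S  S  1 266
S  S  2 425
S  F  1 327
S  Cl 1 253
P  H  1 322
P  P  1 201
Cl Cl 1 242
Br Br 1 193
I  I  1 151
H  F  1 567
H  Cl 1 431
H  Br 1 366
H  I  1 298
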