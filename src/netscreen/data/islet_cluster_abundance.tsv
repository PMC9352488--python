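cluster	p	fc
C0	8.20E-140	0.41759
C1	0.002008	0.892653
C2	0	22.39432
C3	1.10E-24	0.533703
C4	1.40E-11	0.660653
C5	1.95E-20	0.554438
C6	1.24E-24	0.422659
C7	0.061583	0.842438
C8	1.96E-60	6.80658
C9	2.12E-22	0.274513
C10	1.06E-14	0.076347
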