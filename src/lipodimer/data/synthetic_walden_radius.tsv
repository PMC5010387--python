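# synthetic stand-in for the cryo-EM radius distribution of 0.4 um extruded liposomes (truncated lognormal, 2.5 nm bins on [10, 100] nm, calibrated so P(r < 27.5 nm) = 0.40)
radius_nm	probability
11.25	5.2898824902e-03
13.75	1.7517278435e-02
16.25	3.7750079436e-02
18.75	6.1316572656e-02
21.25	8.2007747776e-02
23.75	9.5527496941e-02
26.25	1.0059094227e-01
28.75	9.8231448863e-02
31.25	9.0586940844e-02
33.75	7.9930558416e-02
36.25	6.8143933408e-02
38.75	5.6546812138e-02
41.25	4.5931564056e-02
43.75	3.6681501930e-02
46.25	2.8901479773e-02
48.75	2.2528225636e-02
51.25	1.7411202940e-02
53.75	1.3366053936e-02
56.25	1.0206673775e-02
58.75	7.7623245567e-03
61.25	5.8851110082e-03
63.75	4.4517222141e-03
66.25	3.3620758800e-03
68.75	2.5365283187e-03
71.25	1.9126310156e-03
73.75	1.4419667345e-03
76.25	1.0873203607e-03
78.75	8.2027714424e-04
81.25	6.1925243785e-04
83.75	4.6791370220e-04
86.25	3.5393852387e-04
88.75	2.6804971912e-04
91.25	2.0327304506e-04
93.75	1.5437043414e-04
96.25	1.1740972726e-04
98.75	8.9439458629e-05
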