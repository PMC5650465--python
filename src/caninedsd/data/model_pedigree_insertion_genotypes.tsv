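animal_id	sire	dam	gonad_histology	genotype	breeding_stock
C743	C676	C671	2 ov	G+G+	1
C989	C752	C743	2 ov	G+G+	1
C3052	C1012	C871	2 ov	G+G+	1
C3440	C3428	C3064	2 ov	G+G+	1
C3441	C3428	C3064	2 ov	G+G+	1
C3567	C3428	C3535	1 ovt, 1 ov	G+G+	0
C3542	C3472	C3441	1 ovt, 1 ov	G+G+	0
C730	C205	C672	1 ovt, 1 ov	G+G+	0
C796	C734	C750	1 ovt, 1 ov	G+/-	0
C2021	C734	C871	1 ovt, 1 ov	G+G+	0
C2026	C752	C989	1 ovt, 1 ov	G+/-	0
C3120	C1012	C3038	1 ovt, 1 ov	G+/-	0
C2085	C2005	C871	1 ovt >.5t, 1 ovt < .5t	G+G+	0
C726	C676	C333	2 ovt < .5t	G+G+	0
C795	C734	C750	2 ovt < .5t	G+G+	0
C930	C734	C786	2 ovt < .5t	G+G+	0
C964	C752	C854	2 ovt < .5t	G+G+	0
C3103	C2005	C3052	2 ovt < .5t	G+G+	0
C3104	C2005	C3052	2 ovt < .5t	G+G+	0
C3022	C2005	C948	2 ovt < .5t	G+G+	0
C3023	C1012	C854	2 ovt < .5t	G+/-	0
C3072	C1012	C871	2 ovt < .5t	G+G+	0
C3457	C3428	C3052	2 ovt < .5t	G+G+	0
C3468	C3428	C3053	2 ovt < .5t	G+G+	0
C3497	C3442	C3466	2 ovt < .5t	G+G+	0
C3670	C3428	C3596	2 ovt < .5t	G+/-	0
C3549	C3472	C3466	2 ovt < .5t	G+G+	0
C709	C205	C333	2 ovt >.5t	G+G+	0
C798	C734	C750	2 ovt >.5t	G+G+	0
C2032	C752	C948	2 ovt >.5t	G+G+	0
C3006	C1012	C948	2 ovt >.5t	G+G+	0
C783	C734	C743	2 ovt >.5t	G+G+	0
C2080	C2005	C854	2 t	G+G+	0
C3481	C3428	C3440	2 t	G+G+	0
C3582	C3428	C3466	2 t	G+G+	0
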