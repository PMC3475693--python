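# minimal nearest-neighbor parameters (kcal/mol at 37C); editable
# kind	key1	key2	value
stack	AU	AU	-0.9
stack	AU	CG	-2.2
stack	AU	GC	-2.1
stack	AU	GU	-0.6
stack	AU	UA	-1.1
stack	AU	UG	-1.4
stack	CG	AU	-2.1
stack	CG	CG	-3.3
stack	CG	GC	-2.4
stack	CG	GU	-1.4
stack	CG	UA	-2.1
stack	CG	UG	-2.1
stack	GC	AU	-2.4
stack	GC	CG	-3.4
stack	GC	GC	-3.3
stack	GC	GU	-1.5
stack	GC	UA	-2.2
stack	GC	UG	-2.5
stack	GU	AU	-1.3
stack	GU	CG	-2.5
stack	GU	GC	-2.1
stack	GU	GU	-0.5
stack	GU	UA	-1.4
stack	GU	UG	-0.4
stack	UA	AU	-1.3
stack	UA	CG	-2.4
stack	UA	GC	-2.1
stack	UA	GU	-1.0
stack	UA	UA	-0.9
stack	UA	UG	-1.3
stack	UG	AU	-1.0
stack	UG	CG	-1.5
stack	UG	GC	-1.4
stack	UG	GU	-0.2
stack	UG	UA	-0.6
stack	UG	UG	-0.5
hairpin	3	-	5.4
hairpin	4	-	5.6
hairpin	5	-	5.7
hairpin	6	-	5.4
hairpin	7	-	6.0
hairpin	8	-	5.5
hairpin	9	-	6.4
bulge	1	-	3.8
bulge	2	-	2.8
bulge	3	-	3.2
bulge	4	-	3.6
bulge	5	-	4.0
bulge	6	-	4.4
internal	2	-	1.0
internal	3	-	1.8
internal	4	-	2.0
internal	5	-	2.2
internal	6	-	2.4
multiloop	init	-	3.4
multiloop	branch	-	0.4
terminal	AU	-	0.5
terminal	UA	-	0.5
terminal	GC	-	0.0
terminal	CG	-	0.0
terminal	GU	-	0.5
terminal	UG	-	0.5
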