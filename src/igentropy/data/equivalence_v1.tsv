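# igentropy inter-scheme equivalence table, version v1
# one row per canonical column; approximate outside the documented anchor correspondences
chain	kabat	chothia	consensus_chothia	abm	imgt	aho
L	L1	L1	L1	L1	L1	L1
L	L2	L2	L2	L2	L2	L2
L	L3	L3	L3	L3	L3	L3
L	L4	L4	L4	L4	L4	L4
L	L5	L5	L5	L5	L5	L5
L	L6	L6	L6	L6	L6	L6
L	L7	L7	L7	L7	L7	L7
L	L8	L8	L8	L8	L8	L8
L	L9	L9	L9	L9	L9	L9
L	L10	L10	L10	L10	L10	L10
L	L11	L11	L11	L11	L11	L11
L	L12	L12	L12	L12	L12	L12
L	L13	L13	L13	L13	L13	L13
L	L14	L14	L14	L14	L14	L14
L	L15	L15	L15	L15	L15	L15
L	L16	L16	L16	L16	L16	L16
L	L17	L17	L17	L17	L17	L17
L	L18	L18	L18	L18	L18	L18
L	L19	L19	L19	L19	L19	L19
L	L20	L20	L20	L20	L20	L20
L	L21	L21	L21	L21	L21	L21
L	L22	L22	L22	L22	L22	L22
L	L23	L23	L23	L23	L23	L23
L	L24	L24	L24	L24	L24	L24
L	L25	L25	L25	L25	L25	L25
L	L26	L26	L26	L26	L26	L26
L	L27	L27	L27	L27	L27	L27
L	L27A	L28	L28	L28	L28	L28
L	L27B	L29	L29	L29	L29	L29
L	L28	L30	L30	L30	L30	L30
L	L29	L30A	L30A	L30A	L31	L31
L	L30	L30B	L30B	L30B	L32	L32
L	L31	L31	L31	L31	L33	L33
L	L32	L32	L32	L32	L34	L34
L	L33	L33	L33	L33	L35	L35
L	L34	L34	L34	L34	L36	L36
L	L35	L35	L35	L35	L39	L43
L	L36	L36	L36	L36	L40	L44
L	L37	L37	L37	L37	L41	L45
L	L38	L38	L38	L38	L42	L46
L	L39	L39	L39	L39	L43	L47
L	L40	L40	L40	L40	L44	L48
L	L41	L41	L41	L41	L45	L49
L	L42	L42	L42	L42	L46	L50
L	L43	L43	L43	L43	L47	L51
L	L44	L44	L44	L44	L48	L52
L	L45	L45	L45	L45	L49	L53
L	L46	L46	L46	L46	L50	L54
L	L47	L47	L47	L47	L51	L55
L	L48	L48	L48	L48	L52	L56
L	L49	L49	L49	L49	L53	L57
L	L50	L50	L50	L50	L56	L58
L	L51	L51	L51	L51	L57	L59
L	L52	L52	L52	L52	L58	L60
L	L53	L53	L53	L53	L59	L61
L	L54	L54	L54	L54	L60	L62
L	L55	L55	L55	L55	L61	L63
L	L56	L56	L56	L56	L62	L64
L	L57	L57	L57	L57	L66	L75
L	L58	L58	L58	L58	L67	L76
L	L59	L59	L59	L59	L68	L77
L	L60	L60	L60	L60	L69	L78
L	L61	L61	L61	L61	L75	L79
L	L62	L62	L62	L62	L76	L80
L	L63	L63	L63	L63	L77	L81
L	L64	L64	L64	L64	L78	L82
L	L65	L65	L65	L65	L79	L83
L	L66	L66	L66	L66	L80	L84
L	L67	L67	L67	L67	L81	L85
L	L68	L68	L68	L68	L82	L86
L	L69	L69	L69	L69	L85	L87
L	L70	L70	L70	L70	L86	L88
L	L71	L71	L71	L71	L87	L89
L	L72	L72	L72	L72	L88	L90
L	L73	L73	L73	L73	L89	L91
L	L74	L74	L74	L74	L90	L92
L	L75	L75	L75	L75	L91	L93
L	L76	L76	L76	L76	L92	L94
L	L77	L77	L77	L77	L93	L95
L	L78	L78	L78	L78	L94	L96
L	L79	L79	L79	L79	L95	L97
L	L80	L80	L80	L80	L96	L98
L	L81	L81	L81	L81	L97	L99
L	L82	L82	L82	L82	L98	L100
L	L83	L83	L83	L83	L99	L101
L	L84	L84	L84	L84	L100	L102
L	L85	L85	L85	L85	L101	L103
L	L86	L86	L86	L86	L102	L104
L	L87	L87	L87	L87	L103	L105
L	L88	L88	L88	L88	L104	L106
L	L89	L89	L89	L89	L105	L107
L	L90	L90	L90	L90	L106	L108
L	L91	L91	L91	L91	L107	L109
L	L92	L92	L92	L92	L108	L110
L	L93	L93	L93	L93	L109	L111
L	L94	L94	L94	L94	L114	L112
L	L95	L95	L95	L95	L115	L113
L	L96	L96	L96	L96	L116	L114
L	L97	L97	L97	L97	L117	L115
L	L98	L98	L98	L98	L118	L139
L	L99	L99	L99	L99	L119	L140
L	L100	L100	L100	L100	L120	L141
L	L101	L101	L101	L101	L121	L142
L	L102	L102	L102	L102	L122	L143
L	L103	L103	L103	L103	L123	L144
L	L104	L104	L104	L104	L124	L145
L	L105	L105	L105	L105	L125	L146
L	L106	L106	L106	L106	L126	L147
L	L107	L107	L107	L107	L127	L148
H	H1	H1	H1	H1	H1	H1
H	H2	H2	H2	H2	H2	H2
H	H3	H3	H3	H3	H3	H3
H	H4	H4	H4	H4	H4	H4
H	H5	H5	H5	H5	H5	H5
H	H6	H6	H6	H6	H6	H6
H	H7	H7	H7	H7	H7	H7
H	H8	H8	H8	H8	H8	H8
H	H9	H9	H9	H9	H9	H9
H	H10	H10	H10	H10	H11	H11
H	H11	H11	H11	H11	H12	H12
H	H12	H12	H12	H12	H13	H13
H	H13	H13	H13	H13	H14	H14
H	H14	H14	H14	H14	H15	H15
H	H15	H15	H15	H15	H16	H16
H	H16	H16	H16	H16	H17	H17
H	H17	H17	H17	H17	H18	H18
H	H18	H18	H18	H18	H19	H19
H	H19	H19	H19	H19	H20	H20
H	H20	H20	H20	H20	H21	H21
H	H21	H21	H21	H21	H22	H22
H	H22	H22	H22	H22	H23	H23
H	H23	H23	H23	H23	H24	H24
H	H24	H24	H24	H24	H25	H25
H	H25	H25	H25	H25	H26	H26
H	H26	H26	H26	H26	H27	H27
H	H27	H27	H27	H27	H28	H28
H	H28	H28	H28	H28	H29	H29
H	H29	H29	H29	H29	H30	H30
H	H30	H30	H30	H30	H31	H31
H	H31	H31	H31	H31	H32	H32
H	H32	H32	H32	H32	H33	H33
H	H33	H33	H33	H33	H34	H34
H	H34	H34	H34	H34	H35	H35
H	H35	H35	H35	H35	H36	H36
H	H36	H36	H36	H36	H39	H43
H	H37	H37	H37	H37	H40	H44
H	H38	H38	H38	H38	H41	H45
H	H39	H39	H39	H39	H42	H46
H	H40	H40	H40	H40	H43	H47
H	H41	H41	H41	H41	H44	H48
H	H42	H42	H42	H42	H45	H49
H	H43	H43	H43	H43	H46	H50
H	H44	H44	H44	H44	H47	H51
H	H45	H45	H45	H45	H48	H52
H	H46	H46	H46	H46	H49	H53
H	H47	H47	H47	H47	H50	H54
H	H48	H48	H48	H48	H51	H55
H	H49	H49	H49	H49	H52	H56
H	H50	H50	H50	H50	H53	H57
H	H51	H51	H51	H51	H54	H58
H	H52	H52	H52	H52	H55	H59
H	H53	H53	H53	H53	H56	H60
H	H54	H54	H54	H54	H57	H61
H	H55	H55	H55	H55	H58	H62
H	H56	H56	H56	H56	H59	H63
H	H57	H57	H57	H57	H60	H64
H	H58	H58	H58	H58	H60.1	H65
H	H59	H59	H59	H59	H60.2	H66
H	H60	H60	H60	H60	H60.3	H67
H	H61	H61	H61	H61	H61	H68
H	H62	H62	H62	H62	H62	H69
H	H63	H63	H63	H63	H63	H70
H	H64	H64	H64	H64	H64	H71
H	H65	H65	H65	H65	H65	H72
H	H66	H66	H66	H66	H66	H80
H	H67	H67	H67	H67	H67	H81
H	H68	H68	H68	H68	H68	H82
H	H69	H69	H69	H69	H69	H83
H	H70	H70	H70	H70	H70	H84
H	H71	H71	H71	H71	H71	H85
H	H72	H72	H72	H72	H84	H86
H	H73	H73	H73	H73	H85	H87
H	H74	H74	H74	H74	H86	H88
H	H75	H75	H75	H75	H87	H89
H	H76	H76	H76	H76	H88	H90
H	H77	H77	H77	H77	H89	H91
H	H78	H78	H78	H78	H90	H92
H	H79	H79	H79	H79	H91	H93
H	H80	H80	H80	H80	H92	H94
H	H81	H81	H81	H81	H93	H95
H	H82	H82	H82	H82	H94	H96
H	H83	H83	H83	H83	H95	H97
H	H84	H84	H84	H84	H96	H98
H	H85	H85	H85	H85	H97	H99
H	H86	H86	H86	H86	H98	H100
H	H87	H87	H87	H87	H99	H101
H	H88	H88	H88	H88	H100	H102
H	H89	H89	H89	H89	H101	H103
H	H90	H90	H90	H90	H102	H104
H	H91	H91	H91	H91	H103	H105
H	H92	H92	H92	H92	H104	H106
H	H93	H93	H93	H93	H105	H107
H	H94	H94	H94	H94	H106	H108
H	H95	H95	H95	H95	H107	H109
H	H96	H96	H96	H96	H108	H110
H	H97	H97	H97	H97	H109	H111
H	H98	H98	H98	H98	H110	H112
H	H99	H99	H99	H99	H114	H113
H	H100	H100	H100	H100	H115	H114
H	H101	H101	H101	H101	H116	H115
H	H102	H102	H102	H102	H117	H116
H	H103	H103	H103	H103	H118	H139
H	H104	H104	H104	H104	H119	H140
H	H105	H105	H105	H105	H120	H141
H	H106	H106	H106	H106	H121	H142
H	H107	H107	H107	H107	H122	H143
H	H108	H108	H108	H108	H123	H144
H	H109	H109	H109	H109	H124	H145
H	H110	H110	H110	H110	H125	H146
H	H111	H111	H111	H111	H126	H147
H	H112	H112	H112	H112	H127	H148
H	H113	H113	H113	H113	H128	H149
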