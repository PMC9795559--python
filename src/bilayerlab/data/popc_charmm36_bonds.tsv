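segment_label	carbon_name	hydrogen_name	stereo_label
γ	C13	H13A	none
γ	C13	H13B	none
γ	C13	H13C	none
γ	C14	H14A	none
γ	C14	H14B	none
γ	C14	H14C	none
γ	C15	H15A	none
γ	C15	H15B	none
γ	C15	H15C	none
β	C12	H12A	R
β	C12	H12B	S
α	C11	H11A	R
α	C11	H11B	S
g3	C1	HA	R
g3	C1	HB	S
g2	C2	HS	none
g1	C3	HX	R
g1	C3	HY	S
sn1-C2	C32	H2X	R
sn1-C2	C32	H2Y	S
sn1-C3	C33	H3X	R
sn1-C3	C33	H3Y	S
sn1-C4	C34	H4X	R
sn1-C4	C34	H4Y	S
sn1-C5	C35	H5X	R
sn1-C5	C35	H5Y	S
sn1-C6	C36	H6X	R
sn1-C6	C36	H6Y	S
sn1-C7	C37	H7X	R
sn1-C7	C37	H7Y	S
sn1-C8	C38	H8X	R
sn1-C8	C38	H8Y	S
sn1-C9	C39	H9X	R
sn1-C9	C39	H9Y	S
sn1-C10	C310	H10X	R
sn1-C10	C310	H10Y	S
sn1-C11	C311	H11X	R
sn1-C11	C311	H11Y	S
sn1-C12	C312	H12X	R
sn1-C12	C312	H12Y	S
sn1-C13	C313	H13X	R
sn1-C13	C313	H13Y	S
sn1-C14	C314	H14X	R
sn1-C14	C314	H14Y	S
sn1-C15	C315	H15X	R
sn1-C15	C315	H15Y	S
sn1-C16	C316	H16X	none
sn1-C16	C316	H16Y	none
sn1-C16	C316	H16Z	none
sn2-C2	C22	H2R	R
sn2-C2	C22	H2S	S
sn2-C3	C23	H3R	R
sn2-C3	C23	H3S	S
sn2-C4	C24	H4R	R
sn2-C4	C24	H4S	S
sn2-C5	C25	H5R	R
sn2-C5	C25	H5S	S
sn2-C6	C26	H6R	R
sn2-C6	C26	H6S	S
sn2-C7	C27	H7R	R
sn2-C7	C27	H7S	S
sn2-C8	C28	H8R	R
sn2-C8	C28	H8S	S
sn2-C9	C29	H91	none
sn2-C10	C210	H101	none
sn2-C11	C211	H11R	R
sn2-C11	C211	H11S	S
sn2-C12	C212	H12R	R
sn2-C12	C212	H12S	S
sn2-C13	C213	H13R	R
sn2-C13	C213	H13S	S
sn2-C14	C214	H14R	R
sn2-C14	C214	H14S	S
sn2-C15	C215	H15R	R
sn2-C15	C215	H15S	S
sn2-C16	C216	H16R	R
sn2-C16	C216	H16S	S
sn2-C17	C217	H17R	R
sn2-C17	C217	H17S	S
sn2-C18	C218	H18R	none
sn2-C18	C218	H18S	none
sn2-C18	C218	H18T	none
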