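bead	E	G	domain
P1	122-128,143-153,165-166	-	head
P2	110-120,154-164	-	head
P3	105,108-109,121,129-142	-	head
P4	92-104,106-107	120	head
P5	84-91,167-178	112-119	neck
P6	79-83,179-188	102-111	tail
P7	69-78	93-101	tail
P8	61-68	84-92	tail
P9	52-60	74-83	tail
P10	42-51	65-73	tail
P11	34-41	56-64	tail
P12	24-33	47-55	tail
P13	16-23	38-46	tail
P14	6-13	32-37	tail
P15	3-5	21-31	tail
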