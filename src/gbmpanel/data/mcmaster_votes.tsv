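sample_id	patient_id	sample_type	treated	classical	mesenchymal	proneural	reported_call
BT241-CL-1	BT241	Cell Line	0	1	99	0	mesenchymal
BT241-PDX-1	BT241	PDX	0	1	99	0	mesenchymal
BT428-CL-1	BT428	Cell Line	0	1	1	98	proneural
BT428-PDX-1	BT428	PDX	0	1	1	98	proneural
BT428-PDX-2	BT428	PDX	1	1	38	61	
BT428-PDX-3	BT428	PDX	0	1	1	98	proneural
BT428-PDX-4	BT428	PDX	0	0	1	99	proneural
BT428-PDX-5	BT428	PDX	1	0	0	100	proneural
BT594-CL-1	BT594	Cell Line	0	100	0	0	classical
BT618-CL-1	BT618	Cell Line	0	0	99	1	mesenchymal
BT618-PDX-1	BT618	PDX	0	0	99	1	mesenchymal
BT618-TIS-1	BT618	Patient Tissue	0	0	100	0	mesenchymal
BT667-CL-1	BT667	Cell Line	0	0	99	1	mesenchymal
BT667-PDX-1	BT667	PDX	0	0	0	100	proneural
BT667-PDX-2	BT667	PDX	0	0	99	1	mesenchymal
BT667-PDX-3	BT667	PDX	1	15	85	0	mesenchymal
BT667-TIS-1	BT667	Patient Tissue	0	0	100	0	mesenchymal
BT667-TIS-2	BT667	Patient Tissue	0	0	100	0	mesenchymal
BT667-PDX-4	BT667	PDX	0	11	89	0	mesenchymal
BT667-PDX-5	BT667	PDX	1	26	73	1	
BT698-CL-1	BT698	Cell Line	0	1	61	38	
BT698-TIS-1	BT698	Patient Tissue	0	0	23	77	
BT799-CL-1	BT799	Cell Line	0	0	0	100	proneural
BT799-PDX-1	BT799	PDX	0	0	0	100	proneural
BT799-PDX-2	BT799	PDX	1	0	0	100	proneural
BT799-PDX-3	BT799	PDX	0	0	0	100	proneural
BT799-TIS-1	BT799	Patient Tissue	0	0	0	100	proneural
BT935-CL-1	BT935	Cell Line	0	3	1	96	proneural
BT935-PDX-1	BT935	PDX	0	74	0	26	
BT935-PDX-2	BT935	PDX	0	87	0	13	classical
BT935-PDX-3	BT935	PDX	1	0	0	100	proneural
BT935-TIS-1	BT935	Patient Tissue	0	0	100	0	mesenchymal
BT935-PDX-4	BT935	PDX	0	3	2	95	proneural
BT935-PDX-5	BT935	PDX	1	7	0	93	proneural
BT954-CL-1	BT954	Cell Line	0	79	21	0	
BT954-PDX-1	BT954	PDX	0	80	5	15	classical
BT954-PDX-2	BT954	PDX	0	80	5	15	classical
BT954-PDX-3	BT954	PDX	1	80	5	15	classical
BT954-TIS-1	BT954	Patient Tissue	0	0	40	60	
BT954-PDX-4	BT954	PDX	0	80	5	15	classical
BT954-PDX-5	BT954	PDX	1	80	5	15	classical
BT956-CL-1	BT956	Cell Line	0	1	99	0	mesenchymal
BT956-TIS-1	BT956	Patient Tissue	0	0	99	1	mesenchymal
BT972-CL-1	BT972	Cell Line	0	94	6	0	classical
BT972-PDX-1	BT972	PDX	0	99	1	0	classical
BT972-TIS-1	BT972	Patient Tissue	0	0	80	20	mesenchymal
MBT06-CL-1	MBT06	Cell Line	0	0	100	0	mesenchymal
MBT06-PDX-1	MBT06	PDX	0	13	87	0	mesenchymal
MBT06-PDX-2	MBT06	PDX	0	1	99	0	mesenchymal
MBT06-PDX-3	MBT06	PDX	1	0	2	98	proneural
MBT06-PDX-4	MBT06	PDX	1	0	28	72	
MBT06-PDX-5	MBT06	PDX	0	0	2	98	proneural
MBT06-PDX-6	MBT06	PDX	1	1	97	2	mesenchymal
MBT06-PDX-7	MBT06	PDX	1	2	95	3	mesenchymal
MBT27-CL-1	MBT27	Cell Line	0	2	0	98	proneural
MBT27-TIS-1	MBT27	Patient Tissue	0	0	100	0	mesenchymal
MBT96-TIS-1	MBT96	Patient Tissue	0	0	94	6	mesenchymal
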