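protein_id	CELLO	LOCALIZER	iPSORT	TargetP
TdGLYI-1B-4.1	C/M	C	M	C
TdGLYI-1B-4.2	C/M	C	M	C
TdGLYI-1B-4.3	M/C	C	M	C
TdGLYI-1B-4.4	M/C	C	M	C
TdGLYI-1B-4.5	C	C	M	C
TdGLYI-1B-4.6	C	C	M	C
TdGLYI-1B-4.7	C	C	M	C
TdGLYI-2A-1.1	C/M	C/M	M	C/M
TdGLYI-2A-1.2	C/M	C/M	M	C/M
TdGLYI-2A-1.3	C/M	C/M	M	C/M
TdGLYI-2B-1.1	M/C	C/M	M	C
TdGLYI-2B-1.2	M/C	C/M	M	C
TdGLYI-5A-1.1	M/Cyt	C/M	-	M
TdGLYI-5A-2.1	C/M	C/M	-	C
TdGLYI-5A-2.3	C	C/M	-	C
TdGLYI-5A-2.4	C/M	C/M	-	C
TdGLYI-5B-1.1	C/M	C/M	-	C
TdGLYI-5B-1.2	C	C/M	-	C
TdGLYI-5B-1.3	C/Cyt	-	M	C
TdGLYI-6A-2.1	Cyt	-	M	-
TdGLYI-6A-2.2	Cyt	-	-	-
TdGLYI-7A-1.1	Cyt	-	-	-
TdGLYI-7A-1.2	Cyt	-	-	-
TdGLYI-7A-1.3	Cyt	-	-	-
TdGLYI-7A-1.4	Cyt	-	-	-
TdGLYI-7B-1.1	C/M/Cyt	C	M	-
TdGLYI-7B-1.2	Cyt	-	-	-
TdGLYI-7B-1.3	Cyt	-	-	-
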