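protein_id	metal_site	gsh_site	dimer	metal	active
TdGLYI-1A-1.2	Absent	Absent	Absent	Absent	Absent
TdGLYI-1A-2.1	Absent	Absent	Absent	Absent	Absent
TdGLYI-1B-1.2	Absent	Absent	Absent	Absent	Absent
TdGLYI-1B-2.1	Absent	Absent	Absent	Absent	Absent
TdGLYI-1B-3.1	Absent	Absent	Absent	Absent	Absent
TdGLYI-1B-4.1	Present	Present	Present	Ni	Present
TdGLYI-1B-4.2	Present	Present	Present	Ni	Present
TdGLYI-1B-4.3	Present	Present	Present	Ni	Present
TdGLYI-1B-4.4	Present	Present	Present	Ni	Present
TdGLYI-1B-4.5	Present	Present	Present	Ni	Present
TdGLYI-1B-4.6	Present	Present	Present	Ni	Present
TdGLYI-1B-4.7	Present	Present	Present	Ni	Present
TdGLYI-2A-1.1	Present	Present	Present	Zn	Present
TdGLYI-2A-1.2	Present	Present	Present	Zn	Present
TdGLYI-2A-1.3	Present	Present	Present	Zn	Present
TdGLYI-2A-2.1	Absent	Absent	Absent	Absent	Absent
TdGLYI-2B-1.1	Present	Present	Present	Zn	Present
TdGLYI-2B-1.2	Present	Present	Present	Zn	Present
TdGLYI-2B-2.1	Absent	Absent	Absent	Absent	Absent
TdGLYI-2B-3.1	Absent	Absent	Absent	Absent	Absent
TdGLYI-3A-1.1	Absent	Absent	Absent	Absent	Absent
TdGLYI-3A-1.2	Absent	Absent	Absent	Absent	Absent
TdGLYI-3B-1.1	Absent	Absent	Absent	Absent	Absent
TdGLYI-3B-2.1	Absent	Absent	Absent	Absent	Absent
TdGLYI-4A-1.1	Absent	Absent	Absent	Absent	Absent
TdGLYI-4A-2.1	Absent	Absent	Absent	Absent	Absent
TdGLYI-4A-2.2	Absent	Absent	Absent	Absent	Absent
TdGLYI-4B-1.1	Absent	Absent	Absent	Absent	Absent
TdGLYI-4B-1.2	Absent	Absent	Absent	Absent	Absent
TdGLYI-4B-2.1	Absent	Absent	Absent	Absent	Absent
TdGLYI-5A-1.1	Present	Present	Present	Ni	Present
TdGLYI-5A-2.1	Present	Present	Present	Ni	Present
TdGLYI-5A-2.3	Present	Present	Present	Ni	Present
TdGLYI-5A-2.4	Present	Present	Present	Ni	Present
TdGLYI-5B-1.1	Present	Present	Present	Ni	Present
TdGLYI-5B-1.2	Present	Present	Present	Ni	Present
TdGLYI-5B-1.3	Present	Present	Present	Ni	Present
TdGLYI-6A-1.1	Absent	Absent	Absent	Absent	Absent
TdGLYI-6A-1.2	Absent	Absent	Absent	Absent	Absent
TdGLYI-6A-1.3	Absent	Absent	Absent	Absent	Absent
TdGLYI-6A-1.4	Absent	Absent	Absent	Absent	Absent
TdGLYI-6A-2.1	Present	Present	Present	Ni	Present
TdGLYI-6A-2.2	Present	Present	Present	Ni	Present
TdGLYI-6B-1.1	Absent	Absent	Absent	Absent	Absent
TdGLYI-6B-1.2	Absent	Absent	Absent	Absent	Absent
TdGLYI-6B-1.3	Absent	Absent	Absent	Absent	Absent
TdGLYI-6B-1.4	Absent	Absent	Absent	Absent	Absent
TdGLYI-7A-1.1	Present	Present	Present	Ni	Present
TdGLYI-7A-1.2	Present	Present	Present	Ni	Present
TdGLYI-7A-1.3	Present	Present	Present	Ni	Present
TdGLYI-7A-1.4	Present	Present	Present	Ni	Present
TdGLYI-7B-1.1	Present	Present	Present	Ni	Present
TdGLYI-7B-1.2	Present	Present	Present	Ni	Present
TdGLYI-7B-1.3	Present	Present	Present	Ni	Present
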