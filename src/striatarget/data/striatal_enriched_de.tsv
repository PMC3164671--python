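gene_id	description	fold_change	p_value	fdr
Actn2	Alpha-actinin 2	1.933	0.001	0.064
Foxp1	Forkhead box P1	1.370	0.033	0.284
Pde1b	Phosphodiesterase 1B, Ca2+-calmodulin dependent	0.623	0.001	0.067
Rgs9	Regulator of G-protein signaling 9	1.478	0.043	0.476
Rin1	Ras and Rab interactor 1	0.654	0.001	0.047
Arpp19	cAMP-regulated phosphoprotein 19	0.751	0.012	0.190
Baiap2	BAI1-associated protein 2	0.601	0.001	0.071
Bcl11b	B-cell leukemia/lymphoma 11B	0.665	0.018	0.374
Ensa	Endosulfine alpha	1.374	0.003	0.105
Foxp2	Forkhead box P2	0.748	0.007	0.162
Kcnip2	Kv channel-interacting protein 2	0.657	0.036	0.296
Klf16	Kruppel-like factor 16	1.590	0.007	0.148
Ngef	Neuronal guanine nucleotide exchange factor	0.752	0.005	0.131
Osbpl9	Oxysterol sterol binding protein 8	0.793	0.013	0.197
Pde10a	Phosphodiesterase 10A	0.698	0.011	0.185
Rap1gap	Rap1 GTPase-activating protein	1.397	0.040	0.307
Rarb	RAR beta receptor 1	0.552	0.006	0.140
Zfp521	Zinc finger protein 521	0.704	0.003	0.108
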