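protein_change	cdna_change	group	patients	sources
p.Arg2Gly	c.4C>G	1	12	Hersheson et al. 2013; Lohmann et al. 2016
p.Ala271Thr	c.811G>A	1	1	Lohmann et al. 2016
p.Asp249Asn	c.745G>A	2	48	Hamilton et al. 2014; Simons et al.; Miyatake et al.; Ferreira et al.; Pizzino et al.; Erro et al.; Tonduti et al.; Delgado et al.
p.Arg156Leu	c.467G>T	3a	1	Purnell et al.
p.Val179Leu	c.535G>C	3a	1	Isakov et al.
p.Val180Gly	c.539T>G	3a	1	Vanderver et al.
p.Val180Met	c.538G>A	3a	1	Ji et al.
p.His190Tyr	c.568C>T	3a	6	Kancheva et al.; Nicita et al.
p.Val255Ile	c.763G>A	3a	1	Pizzino et al.
p.Arg262His	c.785G>A	3a	5	Miyatake et al.; Ferreira et al.; Ji et al.; Srivastava et al.; Shimojima et al.
p.Gln292Lys	c.874C>A	3a	1	Pizzino et al.
p.Met300Ile	c.900G>T	3a	3	Erro et al.; Pyle et al.
p.Ala364Asp	c.1091C>A	3a	1	Pyle et al.
p.Arg391His	c.1172G>A	3a	1	Pizzino et al.; Vanderver et al.
p.Gly96Arg	c.286G>A	3b	1	Lu et al.
p.Thr178Met	c.533C>T	3b	1	Tonduti et al.
p.Arg282Pro	c.845G>C	3b	2	Pizzino et al.
p.Val313Leu	c.937G>T	3b	1	Macaron et al.
p.Asp355Val	c.1064A>T	3b	1	Sagnelli et al.
p.Glu410Lys	c.1228G>A	3b	3	Blumkin et al.; Miyatake et al.; Sasaki et al.
p.Arg2Trp	c.4C>T	4	2	Hamilton et al. 2014
p.Arg2Gln	c.5G>A	4	2	Hamilton et al. 2014; Miyatake et al.
p.Thr178Arg	c.533C>G	4	2	Miyatake et al.; Joyal et al.
p.Pro182Thr	c.544C>A	4	1	Tonduti et al.
p.Cys239Phe	c.716G>T	4	2	Hamilton et al. 2014; Ferreira et al.
p.Gly244Ser	c.730G>A	4	4	Hamilton et al. 2014; Carvalho et al.
p.Gly244Val	c.731G>T	4	2	Hamilton et al. 2014; Tonduti et al.
p.Gly244Asp	c.731G>A	4	3	Tonduti et al.
p.Ala248Asp	c.743C>A	4	1	Arai-Ichinoi et al.
p.Ala314Val	c.941C>T	4	1	Erro et al.
p.Met323Arg	c.968T>G	4	1	Hamilton et al. 2014
p.Ala352Thr	c.1054G>A	4	2	Hamilton et al. 2014
p.Cys354Tyr	c.1061G>A	4	1	Hamilton et al. 2014
p.Phe367Leu	c.1099T>C	4	1	Hamilton et al. 2014
p.Phe367Ile	c.1099T>A	4	1	Hamilton et al. 2014
p.Met388Val	c.1162A>G	4	2	Hamilton et al. 2014; Miyatake et al.
p.Met388Thr	c.1163T>C	4	2	Hamilton et al. 2014; Tonduti et al.
p.Met388Ile	c.1164G>A	4	1	Hamilton et al. 2014
p.Phe394Cys	c.1181T>G	4	1	Carvalho et al.
p.Trp397Leu	c.1190G>T	4	1	Ji et al.
p.Asn414Lys	c.1242C>G	5	1	Duncan et al.
p.Pro80Ser	c.238C>T	0	0	ClinVar (benign)
p.Gly223Arg	c.667G>A	0	0	ClinVar (likely benign)
p.Gly277Ala	c.830G>C	0	0	GnomAD (most common missense, MAF 0.012%)
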