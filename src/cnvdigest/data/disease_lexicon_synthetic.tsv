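# Synthetic fixture disease lexicon (MEDIC-compatible column subset):
# concept_id<TAB>preferred_name<TAB>pipe-separated synonyms.
# Concept identifiers are synthetic stand-ins, not real MeSH/OMIM entries.
MESH:D000001	DiGeorge syndrome	velocardiofacial syndrome|VCFS|DGS
MESH:D000002	schizophrenia	schizophrenic disorder
MESH:D000003	autism spectrum disorder	autism|autistic disorder
MESH:D000004	Down syndrome
MESH:D000005	Klinefelter syndrome
MESH:D000006	intellectual disability	mental retardation
MESH:D000007	epilepsy	seizure disorder
MESH:D000008	congenital heart disease	congenital heart defect
MESH:D000009	cleft palate	palatoschisis
MESH:D000010	hypocalcemia
MESH:D000011	developmental delay
MESH:D000012	Prader-Willi syndrome	PWS
MESH:D000013	Angelman syndrome
MESH:D000014	Williams syndrome	Williams-Beuren syndrome
MESH:D000015	attention deficit hyperactivity disorder	ADHD
MESH:D000016	short stature
MESH:D000017	obesity
MESH:D000018	hypotonia	muscular hypotonia
OMIM:616165	microcephaly
OMIM:137920	renal agenesis
OMIM:300000	growth hormone deficiency
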