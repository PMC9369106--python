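# Custom validation CodeSet: the union of the three marker panels as target
# genes, plus the five reference genes found stably expressed in the
# screening cohort. Target genes are derived from panels.yaml at load time;
# only the reference genes are listed here.
reference_genes: [ACTB, B2M, GAPDH, RPL19, RPLP0]
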