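# Reference per-SNP instrument tables (not included)

The reference-reproduction acceptance tests and the data-dependent targets
of `scripts/acceptance.py` need the per-SNP instrument tables behind the
published bidirectional analysis. These come from the source study's
supplementary tables and are not redistributable here; fetch them yourself
and convert each direction to a harmonised TSV in this directory:

- `gord_to_ipf_instruments.tsv` — 59 instruments, forward direction
- `ipf_to_gord_instruments.tsv` — 19 instruments, reverse direction

Columns (tab-separated, one row per instrument, alleles already aligned so
both betas refer to the same effect allele):

```
variant_id	gx_beta	gx_se	gy_beta	gy_se
```

`gx_*` is the gene–exposure association (log odds ratio and SE) and `gy_*`
the gene–outcome association. Without these files the two
`TestReferenceReproduction` tests fail and `scripts/acceptance.py` reports
only the desk-scale targets.
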