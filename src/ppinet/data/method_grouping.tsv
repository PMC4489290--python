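# Default grouping of PSI-MI detection-method accessions into combined
# methods scored jointly. Methods that differ only slightly share a label
# so that sparse methods borrow statistical strength; accessions absent
# from this table score under their own accession. Override with
# --grouping to supply a custom table.
MI:0006	coimmunoprecipitation
MI:0007	coimmunoprecipitation
MI:0019	coimmunoprecipitation
MI:0018	two hybrid
MI:0397	two hybrid
MI:0398	two hybrid
MI:0399	two hybrid
MI:1112	two hybrid
MI:0004	affinity purification
MI:0676	affinity purification
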