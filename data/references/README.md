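# Reference sequences (not redistributed)

The published-genome reproduction checks in `tests/test_acceptance.py` and
the optional typing examples compare against GenBank records that are not
shipped with this repository. To run them, download the accessions into this
directory as plain FASTA:

```sh
fetch() {
  curl -s "https://eutils.ncbi.nlm.nih.gov/entrez/eutils/efetch.fcgi?db=nuccore&id=$1&rettype=fasta&retmode=text" > "$2"
}
fetch HQ625441 HQ625441.fasta          # R. norvegicus papillomavirus 2 genome
fetch <RnPV3 accession> RnPV3.fasta    # R. norvegicus papillomavirus 3 genome (7707 nt)
```

`RnPV3_L1.fasta` and `RnPV2_L1.fasta` should contain the L1 major capsid
gene nucleotide sequences extracted from the two genome records (the L1 CDS
coordinates are given in each GenBank feature table).

Without these files the two reproduction tests fail with a
`FileNotFoundError` pointing here; every other test is self-contained.
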