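#!/usr/bin/env bash
# Fetch the E. coli K-12 MG1655 reference (U00096.3, ~4.6 MB) into data/
# so the full-genome CG motif count can run.  Requires network access.
set -euo pipefail
mkdir -p data
curl -fsSL \
  "https://eutils.ncbi.nlm.nih.gov/entrez/eutils/efetch.fcgi?db=nuccore&id=U00096.3&rettype=fasta&retmode=text" \
  -o data/ecoli_k12_mg1655.fa
grep -c ">" data/ecoli_k12_mg1655.fa
echo "wrote data/ecoli_k12_mg1655.fa"
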