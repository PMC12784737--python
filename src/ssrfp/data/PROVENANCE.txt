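marker_summary.csv and discrimination_summary.csv transcribe published
per-locus summary statistics for a 19-locus sweetpotato (Ipomoea batatas,
hexaploid) SSR fingerprinting panel scored on 65 accessions (37 newly
collected Brazilian samples plus 28 matching genebank accessions).

marker_summary.csv columns: allele size range (bp), total allele count,
mean number of distinct alleles per individual (overall and per sample
group), Nei's gene diversity without and with the finite-sample
correction, and PIC computed from uniform-split ("simple") and
EM-corrected allele frequencies, with the published percent changes.

discrimination_summary.csv columns: allele count, number of distinct
banding patterns I, confusion probability C, discriminating power
D = 1 - C, and its large-sample limit DL = 1 - sum(p_i^2).

Marker name casing follows each published table (IBY60 vs IbY60); the
two spellings denote the same locus. The underlying 65 x 156 binary
genotype matrix is not publicly deposited; these summaries are the only
published numeric record and are shipped so the aggregation,
correlation, and discrimination-identity code paths can be exercised on
real values.
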