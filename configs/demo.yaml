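# Small end-to-end demo: simulate a 48-plex library on a 1 Mb genome, then
# demultiplex, call, filter, summarize and CNV-scan it.
#   gbskit run --config configs/demo.yaml
seed: 5
outdir: demo_out
enzyme: PstI
simulate:
  chrom_sizes: {chr1: 500000, chr2: 500000}
  mean_site_spacing: 2600
  size_window: [600, 1100]
  n_sites: 160
  n_paralog_loci: 8
  fst: 0.25
  inbreeding: 0.2
  maf_range: [0.25, 0.5]
  mean_reads_per_sample: 3000
  cv_reads: 0.39
  error_rate: 0.001
  cnv:
    chrom: chr2
    start: 150000
    end: 400000
    copy_gain: 2
    carrier_breeds: [Holstein, Angus]
cnv:
  min_tags: 5
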