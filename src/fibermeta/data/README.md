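# Bundled meta-analysis summary tables

These three TSV files encode the published per-study design facts and
per-intervention summary statistics of the 12-study / 21-intervention
dietary-fiber corpus that this package's reporting stage summarizes:

- `study_registry.tsv` — one row per study: fiber type, a representative
  dose (g/day; doses reported as ranges are collapsed to a single value),
  intervention duration, number of collection timepoints, subjects, and
  fecal samples.
- `intervention_summary.tsv` — one row per fiber intervention: sample and
  subject counts, the rarefaction depth used, the alpha-diversity outcome
  (direction, significance, and which of Shannon/Simpson showed it), and
  the PERMANOVA variance fractions (percent) for the subject and fiber
  terms with significance flags.  The heterogeneous free-text alpha
  annotations of the source table are normalized to
  (direction, significant, metrics) triples: `metrics` records which
  indices exhibited the direction (`both`, `shannon`, or `simpson`), and
  `significant` is True only when the change was significant for the
  indicated metrics at p < 0.05.
- `trait_depth_summary.tsv` — one row per V4-region study used in the
  phylogenetic analysis: OTU counts surviving the filters, significant and
  large-effect responder counts, and the consenTRAIT conservation depths
  (tau_D) for positively and negatively responding taxa with significance
  flags (permutation p < 0.05).

`fibermeta.meta_report` recomputes the corpus-level footer statistics
(medians, standard deviations, per-column means over all rows and over
significant-only rows, and significance counts) from these rows.
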