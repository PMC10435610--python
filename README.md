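# megplex

Multilayer MEG connectivity analysis: from multichannel region-level time
series to frequency-band phase-lag-index (PLI) connectivity, per-band
spanning-tree backbones, a six-layer multiplex supra-adjacency network,
nodal multilayer eigenvector centrality averaged over a frontoparietal
node set, and cohort-level statistics (impairment classification, paired
change tests, covariate screening, backward-elimination regressions with
Bonferroni correction). A seeded synthetic-data module generates coupled
oscillatory sources and two-timepoint cohorts with known ground truth, so
every stage is testable without any external data.

## Analysis protocol

- Recordings are cut into the first 60 non-overlapping epochs of 4096
  samples (3.28 s at 1250 Hz).
- Each epoch is FFT-mask filtered into six bands: delta (0.5–4 Hz), theta
  (4–8 Hz), lower alpha (8–10 Hz), upper alpha (10–13 Hz), beta
  (13–30 Hz), gamma (30–48 Hz). Bands are half-open `[f_lo, f_hi)`; a bin
  on a shared edge belongs to the higher band.
- PLI = |mean sign of the analytic-phase difference| per region pair, per
  epoch, averaged over epochs → one weighted network per band.
- Each band is binarized to its maximum-total-weight spanning tree
  (Kruskal; 77 links for 78 nodes), the trees become the diagonal blocks
  of a 468×468 supra-adjacency matrix with unit-weight interlayer links
  between node replicas only.
- Nodal multilayer eigenvector centrality is the leading eigenvector of
  the supra matrix, replicas averaged per node, max-normalized, then
  averaged over the frontoparietal node set.
- Cohort statistics: Z < −1.5 flags impairment; paired t / Wilcoxon tests
  for T2−T1 change; covariate screening at p < 0.05; backward elimination
  at removal p ≥ 0.10; Bonferroni threshold 0.05 / 3 = 0.0167.

## CLI

```sh
# simulate a recording with planted theta coupling, then run the chain
megplex --seed 1 simulate sources --n-regions 78 --n-samples 245760 \
    --coupling '{"theta": [[0, 1, 0.9, 0.7853981633974483]]}' --out ts.tsv
megplex --out-dir out connect ts.tsv
megplex --out-dir out backbone out/pli_*.tsv
megplex --out-dir out multiplex out/backbone_*.tsv
megplex --out-dir out centrality out/supra.tsv --subnet fpn.txt

# cohort statistics from a subject × timepoint CSV
megplex --config cfg.yaml --out-dir stats cohort-stats --cohort cohort.csv

# end to end (recordings.csv: subject_id, timepoint, path)
megplex --config cfg.yaml --out-dir run_out run \
    --recordings recordings.csv --cohort cohort.csv
```

Configuration is YAML (`fs_hz`, `epoch_length`, `max_epochs`, `bands`,
`interlayer_weight`, `aggregation`, `elimination_threshold`, `alpha`,
`m_tests`, `subnet_file`, `seed`, covariate declarations); all defaults
match the protocol above. A default, clearly stand-in frontoparietal node
set ships at `src/megplex/data/fpn_nodes.txt` and should be edited to
match your parcellation.

## File formats

Everything is plain text: matrices as full labelled TSV (6 significant
digits; 12 for supra/eigenvector artifacts), time series as TSV with a
header row of region labels plus a `.json` sidecar carrying `fs_hz`
(or a `.npy` container), node sets one label per line, cohorts as CSV,
statistics as JSON. Every `run` writes a manifest with the resolved
config, input digests, and per-stage record counts; reruns with identical
inputs are byte-identical (manifest timestamps aside).

## Notes

PLI carries a finite-sample positive bias for independent narrowband
signals (roughly `sqrt(2 / (π·B·T))` for bandwidth B and epoch length T —
about 0.3 in a 2 Hz band at 3.28 s epochs). Epoch averaging does not
remove it, because each epoch contributes an absolute value. Comparisons
between conditions are unaffected; absolute PLI levels in narrow bands
should be read with this floor in mind.
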