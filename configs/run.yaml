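# Default end-to-end run: two SPT conditions plus the profiling branch.
seed: 1
outdir: scratch/default_run
run_spt: true
run_ribo: true
relink: true
conditions:
  - label: control
    n_cells: 4
    sim: {n_frames: 500, n_chaperones: 8, n_clients: 8, k_on: 5.0}
  - label: puromycin_like
    n_cells: 4
    sim: {n_frames: 500, n_chaperones: 8, n_clients: 8, k_on: 1.25}
ribo:
  n_genes: 20
  gene_length: 300
  input_depth: 20.0
  windows: [[100, 150, 8.0]]
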