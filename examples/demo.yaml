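# Demo end-to-end run: simulate a planted-contact 4C experiment from the
# seed, count, estimate, call, intersect, and write a report + manifest.
#   loopcall4c run --config examples/demo.yaml --out runs/demo
seed: 5
n_reads: 20000
n_reps: 2
instances: 64
gamma: 0.5
q: 0.10
mask_radius: 1000000
bin_width: 1000000
scale: 1000000
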