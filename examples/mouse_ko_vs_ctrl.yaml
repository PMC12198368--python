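# Knockout vs control comparison on the built-in mouse-like annotation.
# Both samples are simulated: the control with efficient canonical cleavage,
# the knockout with cleavage failure at the methylation-sensitive canonical
# junctions (rRNA gene cluster, mtNd2 region, mtR-mtNd4/4l region).
#
#   mitopunct run --config examples/mouse_ko_vs_ctrl.yaml --seed 7 --out out/

genome:
  builtin: mouse_like

params:
  tol: 20                  # nt tolerance of the processed boundary rule
  pool_threshold: 0.02     # composition pooling into "other"
  delta_vis_threshold: 0.5 # pp threshold for flagging a junction
  abundance_cutoff: 0.0001 # min fraction of total reads for tRNA metrics
  contain_rule: centre

simulate:
  ctrl:
    condition: ctrl
    n_reads: 20000
  ko:
    condition: ko
    n_reads: 20000
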