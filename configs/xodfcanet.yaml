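# Documented X-ODFCANet configuration for the headline cost figures:
# 4.416M trainable parameters, 545.2M MACs at 3x224x224
# (targets: 4.45M parameters, 538.93M MACs).
num_classes: 3
in_channels: 3
input_size: 224
stem_channels: 32
stage_widths: [32, 64, 128, 256]
blocks_per_stage: [1, 2, 3, 3]
odconv:
  n: 1
  gamma: 0.0625
  kernel_attention: sigmoid
ca:
  r: 8
  bn_after_reduce: true
fca:
  fusion: sum
final_pool: avg
seed: 0
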