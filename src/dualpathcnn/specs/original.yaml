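# Original architecture: 64x64 input, 3x3 stride-1 stem, same dual-path body
# and 336-feature tail as the reductive variant.  The final normal modules see
# 8x8 feature maps.
name: original
input: {width: 64, height: 64, channels: 3}
modules:
  - {kind: simple_conv, kernel: 3, filters: 96, stride: 1, padding: 1, in_channels: 3, declared_output: [64, 64, 96]}
  - {kind: normal_dual, filters_1x1: 32, filters_3x3: 32, in_channels: 96, declared_output: [64, 64, 64]}
  - {kind: normal_dual, filters_1x1: 32, filters_3x3: 48, in_channels: 64, declared_output: [64, 64, 80]}
  - {kind: reduction_dual, filters: 80, in_channels: 80, declared_output: [32, 32, 160]}
  - {kind: normal_dual, filters_1x1: 112, filters_3x3: 48, in_channels: 160, declared_output: [32, 32, 160]}
  - {kind: normal_dual, filters_1x1: 96, filters_3x3: 64, in_channels: 160, declared_output: [32, 32, 160]}
  - {kind: normal_dual, filters_1x1: 80, filters_3x3: 80, in_channels: 160, declared_output: [32, 32, 160]}
  - {kind: normal_dual, filters_1x1: 48, filters_3x3: 96, in_channels: 160, declared_output: [32, 32, 144]}
  - {kind: reduction_dual, filters: 96, in_channels: 144, declared_output: [16, 16, 240]}
  - {kind: normal_dual, filters_1x1: 176, filters_3x3: 160, in_channels: 240, declared_output: [16, 16, 336]}
  - {kind: normal_dual, filters_1x1: 176, filters_3x3: 160, in_channels: 336, declared_output: [16, 16, 336]}
  - {kind: reduction_dual, filters: 96, in_channels: 336, declared_output: [8, 8, 432]}
  - {kind: normal_dual, filters_1x1: 176, filters_3x3: 160, in_channels: 432, declared_output: [8, 8, 336]}
  - {kind: normal_dual, filters_1x1: 176, filters_3x3: 160, in_channels: 336, declared_output: [8, 8, 336]}
  - {kind: global_pool, pool_kernel: 8, declared_output: [1, 1, 336]}
  - {kind: flatten, declared_output: [1, 1, 336]}
  - {kind: fully_connected, out_classes: 5, declared_output: [1, 1, 5]}
  - {kind: softmax, declared_output: [1, 1, 5]}
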