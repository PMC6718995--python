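# Revised deepened architecture: the deepened front (modules through normal
# dual module 10, ending at 28x28x336), with the six inserted modules slimmed
# back to 176/160-filter branches so every kernel sees enough spatial context.
# The tail pools 7x7x336 into a 336-feature vector.
name: revised_deepened
input: {width: 224, height: 224, channels: 3}
modules:
  - {kind: simple_conv, kernel: 3, filters: 96, stride: 1, padding: 1, in_channels: 3, declared_output: [224, 224, 96]}
  - {kind: normal_dual, filters_1x1: 32, filters_3x3: 32, in_channels: 96, declared_output: [224, 224, 64]}
  - {kind: normal_dual, filters_1x1: 32, filters_3x3: 48, in_channels: 64, declared_output: [224, 224, 80]}
  - {kind: reduction_dual, filters: 80, in_channels: 80, declared_output: [112, 112, 160]}
  - {kind: normal_dual, filters_1x1: 112, filters_3x3: 48, in_channels: 160, declared_output: [112, 112, 160]}
  - {kind: normal_dual, filters_1x1: 96, filters_3x3: 64, in_channels: 160, declared_output: [112, 112, 160]}
  - {kind: normal_dual, filters_1x1: 80, filters_3x3: 80, in_channels: 160, declared_output: [112, 112, 160]}
  - {kind: normal_dual, filters_1x1: 48, filters_3x3: 96, in_channels: 160, declared_output: [112, 112, 144]}
  - {kind: reduction_dual, filters: 96, in_channels: 144, declared_output: [56, 56, 240]}
  - {kind: normal_dual, filters_1x1: 176, filters_3x3: 160, in_channels: 240, declared_output: [56, 56, 336]}
  - {kind: normal_dual, filters_1x1: 176, filters_3x3: 160, in_channels: 336, declared_output: [56, 56, 336]}
  - {kind: reduction_dual, filters: 96, in_channels: 336, declared_output: [28, 28, 432]}
  - {kind: normal_dual, filters_1x1: 176, filters_3x3: 160, in_channels: 432, declared_output: [28, 28, 336]}
  - {kind: normal_dual, filters_1x1: 176, filters_3x3: 160, in_channels: 336, declared_output: [28, 28, 336]}
  - {kind: reduction_dual, filters: 96, in_channels: 336, declared_output: [14, 14, 432]}
  - {kind: normal_dual, filters_1x1: 176, filters_3x3: 160, in_channels: 432, declared_output: [14, 14, 336]}
  - {kind: normal_dual, filters_1x1: 176, filters_3x3: 160, in_channels: 336, declared_output: [14, 14, 336]}
  - {kind: reduction_dual, filters: 96, in_channels: 336, declared_output: [7, 7, 432]}
  - {kind: normal_dual, filters_1x1: 176, filters_3x3: 160, in_channels: 432, declared_output: [7, 7, 336]}
  - {kind: normal_dual, filters_1x1: 176, filters_3x3: 160, in_channels: 336, declared_output: [7, 7, 336]}
  - {kind: global_pool, pool_kernel: 7, declared_output: [1, 1, 336]}
  - {kind: flatten, declared_output: [1, 1, 336]}
  - {kind: fully_connected, out_classes: 5, declared_output: [1, 1, 5]}
  - {kind: softmax, declared_output: [1, 1, 5]}
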