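# Reductive architecture: 224x224 input with a 9x9 stride-3 stem convolution
# that aggressively subsamples the image before the dual-path body.
name: reductive
input: {width: 224, height: 224, channels: 3}
modules:
  - {kind: simple_conv, kernel: 9, filters: 96, stride: 3, padding: 2, in_channels: 3, declared_output: [74, 74, 96]}
  - {kind: normal_dual, filters_1x1: 32, filters_3x3: 32, in_channels: 96, declared_output: [74, 74, 64]}
  - {kind: normal_dual, filters_1x1: 32, filters_3x3: 48, in_channels: 64, declared_output: [74, 74, 80]}
  - {kind: reduction_dual, filters: 80, in_channels: 80, declared_output: [37, 37, 160]}
  - {kind: normal_dual, filters_1x1: 112, filters_3x3: 48, in_channels: 160, declared_output: [37, 37, 160]}
  - {kind: normal_dual, filters_1x1: 96, filters_3x3: 64, in_channels: 160, declared_output: [37, 37, 160]}
  - {kind: normal_dual, filters_1x1: 80, filters_3x3: 80, in_channels: 160, declared_output: [37, 37, 160]}
  - {kind: normal_dual, filters_1x1: 48, filters_3x3: 96, in_channels: 160, declared_output: [37, 37, 144]}
  - {kind: reduction_dual, filters: 96, in_channels: 144, declared_output: [19, 19, 240]}
  - {kind: normal_dual, filters_1x1: 176, filters_3x3: 160, in_channels: 240, declared_output: [19, 19, 336]}
  - {kind: normal_dual, filters_1x1: 176, filters_3x3: 160, in_channels: 336, declared_output: [19, 19, 336]}
  - {kind: reduction_dual, filters: 96, in_channels: 336, declared_output: [10, 10, 432]}
  - {kind: normal_dual, filters_1x1: 176, filters_3x3: 160, in_channels: 432, declared_output: [10, 10, 336]}
  - {kind: normal_dual, filters_1x1: 176, filters_3x3: 160, in_channels: 336, declared_output: [10, 10, 336]}
  - {kind: global_pool, pool_kernel: 10, declared_output: [1, 1, 336]}
  - {kind: flatten, declared_output: [1, 1, 336]}
  - {kind: fully_connected, out_classes: 5, declared_output: [1, 1, 5]}
  - {kind: softmax, declared_output: [1, 1, 5]}
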