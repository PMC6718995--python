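import numpy as np
import pytest

from dualpathcnn import archspec, network, sensor, synthetic
from dualpathcnn.archspec import (
    ArchitectureSpec,
    ConvKernelSpec,
    ModuleSpec,
    ShapeTriple,
)


@pytest.fixture(scope="session")
def specs():
    return archspec.builtin_specs()


@pytest.fixture(scope="session")
def tiny_spec():
    """A structurally valid miniature architecture for fast training tests."""
    modules = (
        ModuleSpec("simple_conv", (ConvKernelSpec(3, 3, 6, 1, 1),)),
        ModuleSpec("normal_dual", (ConvKernelSpec(1, 1, 4, 1, 0),
                                   ConvKernelSpec(3, 3, 4, 1, 1))),
        ModuleSpec("reduction_dual", (ConvKernelSpec(3, 3, 6, 2, 1),), pool_kernel=3),
        ModuleSpec("normal_dual", (ConvKernelSpec(1, 1, 6, 1, 0),
                                   ConvKernelSpec(3, 3, 6, 1, 1))),
        ModuleSpec("global_pool"),
        ModuleSpec("flatten"),
        ModuleSpec("fully_connected", out_classes=5),
        ModuleSpec("softmax"),
    )
    return ArchitectureSpec("tiny", ShapeTriple(16, 16, 3), modules)


@pytest.fixture(scope="session")
def sensor_images():
    """Encoded synthetic specimens: (images, labels), 60 samples, 5 classes."""
    cfg = synthetic.SensorGenConfig(n_specimens=60, seed=11)
    normalized = sensor.normalize_parameters(synthetic.gen_sensor_specimens(cfg))
    images = np.stack([sensor.encode_specimen(s) for s in normalized])
    labels = np.array([s.label for s in normalized])
    return images, labels


@pytest.fixture(scope="session")
def trained_tiny(tiny_spec, sensor_images):
    """A tiny network trained briefly on downscaled sensor images."""
    from dualpathcnn.imageprep import FundusPreprocessor

    images, labels = sensor_images
    small = FundusPreprocessor(size=16).transform(list(images))
    net = network.build_network(tiny_spec, n_classes=5, seed=3)
    cfg = network.TrainingConfig(epochs=4, batch_size=20, seed=3)
    model = network.train(net, (small[:50], labels[:50]), (small[50:], labels[50:]), cfg)
    return model, small, labels
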