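"""Declarative dual-path CNN architectures and an exact output-shape calculus.

A network in this family is an ordered list of modules: one simple (plain)
convolution up front, a body of *normal* dual-path modules (parallel 1x1 and
3x3 convolution branches concatenated along channels) interleaved with
*reduction* dual-path modules (a stride-2 3x3 convolution branch next to a
stride-2 3x3 max-pool branch, again concatenated), and a fixed tail of global
average pooling, flatten, one fully connected layer and softmax.

Every spatial size in the chain follows the standard convolution arithmetic

    W_out = floor((W_in - K + 2P) / S) + 1

with fixed padding conventions: 1x1 convolutions use P=0, 3x3 convolutions and
3x3 pools use P=1, and the 9x9 stride-3 stem convolution uses P=2.  Channel
counts concatenate: a normal module outputs the sum of its branch filter
counts; a reduction module outputs its conv-branch filters plus all incoming
channels (the pool branch passes every channel through).

The module doubles as an auditor: architecture files may declare the expected
output shape of each module, and :func:`audit_spec` checks the declared
values against the calculus.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

import yaml

__all__ = [
    "ShapeTriple",
    "ConvKernelSpec",
    "ModuleSpec",
    "ArchitectureSpec",
    "AuditEntry",
    "AuditReport",
    "InvalidGeometryError",
    "ChannelMismatchError",
    "SpecStructureError",
    "conv_output_size",
    "module_output",
    "infer_shapes",
    "audit_spec",
    "builtin_specs",
    "builtin_spec_names",
    "load_spec",
    "save_spec",
    "spec_to_yaml",
    "get_spec",
]

MODULE_KINDS = (
    "simple_conv",
    "normal_dual",
    "reduction_dual",
    "global_pool",
    "flatten",
    "fully_connected",
    "softmax",
)


class InvalidGeometryError(ValueError):
    """A convolution would produce a non-positive spatial size."""


class ChannelMismatchError(ValueError):
    """Declared kernel input depth disagrees with the incoming channel count."""


class SpecStructureError(ValueError):
    """An architecture spec violates the structural invariants."""


@dataclass(frozen=True)
class ShapeTriple:
    """Width x height x channels of the tensor flowing between modules."""

    width: int
    height: int
    channels: int

    def __post_init__(self) -> None:
        for name in ("width", "height", "channels"):
            v = getattr(self, name)
            if not isinstance(v, int) or v < 1:
                raise ValueError(f"ShapeTriple.{name} must be a positive integer, got {v!r}")

    def __str__(self) -> str:  # matches the (W x H x C) table style
        return f"({self.width} x {self.height} x {self.channels})"


@dataclass(frozen=True)
class ConvKernelSpec:
    """One convolution branch: square kernel, filter count, stride, padding.

    ``in_channels`` is optional declared input depth (the "x C" part of a
    kernel description such as 3x3x96); when present it is audited against
    the incoming channel count.
    """

    kernel_width: int
    kernel_height: int
    filters: int
    stride: int
    padding: int
    in_channels: Optional[int] = None

    def __post_init__(self) -> None:
        if self.kernel_width != self.kernel_height:
            raise ValueError("only square kernels are supported")
        if self.kernel_width not in (1, 3, 9):
            raise ValueError(f"kernel size {self.kernel_width} not in {{1, 3, 9}}")
        if self.stride not in (1, 2, 3):
            raise ValueError(f"stride {self.stride} not in {{1, 2, 3}}")
        if self.padding < 0:
            raise ValueError("padding must be >= 0")
        if self.filters < 1:
            raise ValueError("filters must be >= 1")


@dataclass(frozen=True)
class ModuleSpec:
    """One module in the chain.

    ``branches`` holds one :class:`ConvKernelSpec` for ``simple_conv`` and two
    for the dual kinds (1x1 branch first for ``normal_dual``; conv branch for
    ``reduction_dual``, whose second branch is the implicit max pool).
    """

    kind: str
    branches: tuple[ConvKernelSpec, ...] = ()
    pool_kernel: Optional[int] = None
    out_classes: Optional[int] = None
    declared_output: Optional[ShapeTriple] = None

    def __post_init__(self) -> None:
        if self.kind not in MODULE_KINDS:
            raise ValueError(f"unknown module kind {self.kind!r}")
        if self.kind == "simple_conv" and len(self.branches) != 1:
            raise ValueError("simple_conv takes exactly one kernel spec")
        if self.kind == "normal_dual":
            if len(self.branches) != 2:
                raise ValueError("normal_dual takes exactly two kernel specs")
            one, three = self.branches
            if one.kernel_width != 1 or three.kernel_width != 3:
                raise ValueError("normal_dual branches must be a 1x1 then a 3x3 kernel")
            if one.stride != 1 or three.stride != 1:
                raise ValueError("normal_dual branches must both use stride 1")
        if self.kind == "reduction_dual":
            if len(self.branches) != 1:
                raise ValueError("reduction_dual takes one conv kernel spec (pool branch is implicit)")
            conv = self.branches[0]
            if conv.kernel_width != 3 or conv.stride != 2:
                raise ValueError("reduction_dual conv branch must be 3x3 stride 2")
        if self.kind == "fully_connected" and (self.out_classes is None or self.out_classes < 2):
            raise ValueError("fully_connected requires out_classes >= 2")


@dataclass(frozen=True)
class ArchitectureSpec:
    """A named architecture: input shape plus the ordered module chain."""

    name: str
    input_shape: ShapeTriple
    modules: tuple[ModuleSpec, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "modules", tuple(self.modules))
        self.validate_structure()

    def validate_structure(self) -> None:
        kinds = [m.kind for m in self.modules]
        if not kinds or kinds[0] != "simple_conv":
            raise SpecStructureError(f"{self.name}: first module must be simple_conv")
        tail = ("global_pool", "flatten", "fully_connected", "softmax")
        if tuple(kinds[-4:]) != tail:
            raise SpecStructureError(
                f"{self.name}: tail must be global_pool, flatten, fully_connected, softmax in order"
            )
        for k in tail:
            if kinds.count(k) != 1:
                raise SpecStructureError(f"{self.name}: exactly one {k} module required")
        for k in kinds[1:-4]:
            if k not in ("normal_dual", "reduction_dual"):
                raise SpecStructureError(f"{self.name}: body modules must be dual-path, got {k}")

    @property
    def n_classes(self) -> int:
        (fc,) = [m for m in self.modules if m.kind == "fully_connected"]
        assert fc.out_classes is not None
        return fc.out_classes

    @property
    def flatten_length(self) -> int:
        shapes = infer_shapes(self)
        idx = [m.kind for m in self.modules].index("flatten")
        return shapes[idx].channels


def conv_output_size(win: int, k: int, p: int, s: int) -> int:
    """Spatial output size of a convolution: floor((win - k + 2p)/s) + 1.

    Raises :class:`InvalidGeometryError` when the result would not be a
    positive integer (kernel larger than the padded input).
    """
    if s < 1:
        raise ValueError(f"stride must be >= 1, got {s}")
    if win < 1:
        raise ValueError(f"input width must be >= 1, got {win}")
    wout = (win - k + 2 * p) // s + 1
    if wout < 1:
        raise InvalidGeometryError(
            f"convolution k={k}, p={p}, s={s} on input width {win} yields non-positive size {wout}"
        )
    return wout


def _check_depth(declared: Optional[int], incoming: int, where: str) -> None:
    if declared is not None and declared != incoming:
        raise ChannelMismatchError(
            f"{where}: kernel declares input depth {declared} but receives {incoming} channels"
        )


def module_output(input: ShapeTriple, m: ModuleSpec) -> ShapeTriple:
    """Output shape of one module applied to ``input``.

    Channel rule: normal modules concatenate the two branch outputs; reduction
    modules concatenate the conv branch with the max-pool branch, which passes
    every input channel through.
    """
    w, h, c = input.width, input.height, input.channels
    if m.kind == "simple_conv":
        k = m.branches[0]
        _check_depth(k.in_channels, c, "simple_conv")
        return ShapeTriple(
            conv_output_size(w, k.kernel_width, k.padding, k.stride),
            conv_output_size(h, k.kernel_height, k.padding, k.stride),
            k.filters,
        )
    if m.kind == "normal_dual":
        one, three = m.branches
        _check_depth(one.in_channels, c, "normal_dual 1x1 branch")
        _check_depth(three.in_channels, c, "normal_dual 3x3 branch")
        w1 = conv_output_size(w, 1, one.padding, 1)
        w3 = conv_output_size(w, 3, three.padding, 1)
        if w1 != w3:
            raise InvalidGeometryError("normal_dual branches disagree on spatial size")
        return ShapeTriple(w1, conv_output_size(h, 3, three.padding, 1), one.filters + three.filters)
    if m.kind == "reduction_dual":
        conv = m.branches[0]
        _check_depth(conv.in_channels, c, "reduction_dual conv branch")
        wo = conv_output_size(w, 3, conv.padding, 2)
        ho = conv_output_size(h, 3, conv.padding, 2)
        return ShapeTriple(wo, ho, conv.filters + c)
    if m.kind == "global_pool":
        return ShapeTriple(1, 1, c)
    if m.kind == "flatten":
        return ShapeTriple(1, 1, c)
    if m.kind == "fully_connected":
        assert m.out_classes is not None
        return ShapeTriple(1, 1, m.out_classes)
    if m.kind == "softmax":
        return ShapeTriple(1, 1, c)
    raise ValueError(f"unknown module kind {m.kind!r}")  # pragma: no cover


def infer_shapes(spec: ArchitectureSpec) -> list[ShapeTriple]:
    """Chain :func:`module_output` over the whole spec; one shape per module."""
    shapes: list[ShapeTriple] = []
    cur = spec.input_shape
    for i, m in enumerate(spec.modules):
        try:
            cur = module_output(cur, m)
        except (InvalidGeometryError, ChannelMismatchError) as e:
            raise type(e)(f"{spec.name} module {i} ({m.kind}): {e}") from e
        shapes.append(cur)
    return shapes


@dataclass(frozen=True)
class AuditEntry:
    index: int
    kind: str
    inferred: Optional[ShapeTriple]
    declared: Optional[ShapeTriple]
    error: Optional[str] = None

    @property
    def ok(self) -> bool:
        if self.error is not None:
            return False
        return self.declared is None or self.declared == self.inferred


@dataclass(frozen=True)
class AuditReport:
    spec_name: str
    entries: tuple[AuditEntry, ...]

    @property
    def mismatches(self) -> list[AuditEntry]:
        return [e for e in self.entries if not e.ok]

    @property
    def ok(self) -> bool:
        return not self.mismatches

    def __str__(self) -> str:
        lines = [f"audit of {self.spec_name}:"]
        for e in self.entries:
            if e.error is not None:
                mark = f"ERROR {e.error}"
            elif e.ok:
                mark = "ok"
            else:
                mark = f"MISMATCH declared {e.declared}"
            lines.append(f"  [{e.index:2d}] {e.kind:16s} {e.inferred}  {mark}")
        lines.append(f"{len(self.mismatches)} mismatch(es)")
        return "\n".join(lines)


def audit_spec(spec: ArchitectureSpec) -> AuditReport:
    """Compare inferred shapes against each module's declared output.

    Mismatches — including channel-depth disagreements and geometry errors,
    which end the chain at the offending module — are report entries, never
    exceptions.  Modules without a declared output are reported as passing.
    """
    entries: list[AuditEntry] = []
    cur = spec.input_shape
    for i, m in enumerate(spec.modules):
        try:
            cur = module_output(cur, m)
        except (InvalidGeometryError, ChannelMismatchError) as e:
            entries.append(AuditEntry(i, m.kind, None, m.declared_output, str(e)))
            break
        entries.append(AuditEntry(i, m.kind, cur, m.declared_output))
    return AuditReport(spec.name, tuple(entries))


# ---------------------------------------------------------------------------
# Architecture files (flat YAML, one mapping per module)

def _branch_conv(kernel: int, filters: int, stride: int, padding: int,
                 in_channels: Optional[int]) -> ConvKernelSpec:
    return ConvKernelSpec(kernel, kernel, filters, stride, padding, in_channels)


def _module_from_dict(d: dict) -> ModuleSpec:
    kind = d["kind"]
    declared = d.get("declared_output")
    if declared is not None:
        declared = ShapeTriple(*[int(x) for x in declared])
    if kind == "simple_conv":
        branches = (
            _branch_conv(int(d["kernel"]), int(d["filters"]), int(d["stride"]),
                         int(d["padding"]), d.get("in_channels")),
        )
        return ModuleSpec(kind, branches, declared_output=declared)
    if kind == "normal_dual":
        inc = d.get("in_channels")
        branches = (
            _branch_conv(1, int(d["filters_1x1"]), 1, 0, inc),
            _branch_conv(3, int(d["filters_3x3"]), 1, 1, inc),
        )
        return ModuleSpec(kind, branches, declared_output=declared)
    if kind == "reduction_dual":
        branches = (_branch_conv(3, int(d["filters"]), 2, 1, d.get("in_channels")),)
        return ModuleSpec(kind, branches, pool_kernel=3, declared_output=declared)
    if kind == "global_pool":
        pk = d.get("pool_kernel")
        return ModuleSpec(kind, pool_kernel=None if pk is None else int(pk),
                          declared_output=declared)
    if kind == "flatten":
        return ModuleSpec(kind, declared_output=declared)
    if kind == "fully_connected":
        return ModuleSpec(kind, out_classes=int(d["out_classes"]), declared_output=declared)
    if kind == "softmax":
        return ModuleSpec(kind, declared_output=declared)
    raise ValueError(f"unknown module kind {kind!r} in spec file")


def _module_to_dict(m: ModuleSpec) -> dict:
    d: dict = {"kind": m.kind}
    if m.kind == "simple_conv":
        k = m.branches[0]
        d.update(kernel=k.kernel_width, filters=k.filters, stride=k.stride, padding=k.padding)
        if k.in_channels is not None:
            d["in_channels"] = k.in_channels
    elif m.kind == "normal_dual":
        one, three = m.branches
        d.update(filters_1x1=one.filters, filters_3x3=three.filters)
        if one.in_channels is not None:
            d["in_channels"] = one.in_channels
    elif m.kind == "reduction_dual":
        conv = m.branches[0]
        d["filters"] = conv.filters
        if conv.in_channels is not None:
            d["in_channels"] = conv.in_channels
    elif m.kind == "global_pool":
        if m.pool_kernel is not None:
            d["pool_kernel"] = m.pool_kernel
    elif m.kind == "fully_connected":
        d["out_classes"] = m.out_classes
    if m.declared_output is not None:
        s = m.declared_output
        d["declared_output"] = [s.width, s.height, s.channels]
    return d


def load_spec(path_or_stream) -> ArchitectureSpec:
    """Read an architecture spec from a YAML file path or open stream."""
    if hasattr(path_or_stream, "read"):
        data = yaml.safe_load(path_or_stream)
    else:
        with open(path_or_stream, "r", encoding="utf-8") as fh:
            data = yaml.safe_load(fh)
    inp = data["input"]
    input_shape = ShapeTriple(int(inp["width"]), int(inp["height"]), int(inp["channels"]))
    modules = tuple(_module_from_dict(d) for d in data["modules"])
    return ArchitectureSpec(str(data["name"]), input_shape, modules)


def spec_to_yaml(spec: ArchitectureSpec) -> str:
    data = {
        "name": spec.name,
        "input": {"width": spec.input_shape.width, "height": spec.input_shape.height,
                  "channels": spec.input_shape.channels},
        "modules": [_module_to_dict(m) for m in spec.modules],
    }
    return yaml.safe_dump(data, sort_keys=False)


def save_spec(spec: ArchitectureSpec, path) -> None:
    Path(path).write_text(spec_to_yaml(spec), encoding="utf-8")


_BUILTIN_FILES = {
    "original": "original.yaml",
    "reductive": "reductive.yaml",
    "deepened": "deepened.yaml",
    "revised_deepened": "revised_deepened.yaml",
}


def builtin_spec_names() -> list[str]:
    return list(_BUILTIN_FILES)


def builtin_specs() -> dict[str, ArchitectureSpec]:
    """The four bundled architectures.

    * ``original`` — 64x64 input, 3x3 stride-1 stem, 10 normal + 3 reduction
      dual modules, 336-feature tail.
    * ``reductive`` — 224x224 input with an aggressive 9x9 stride-3 stem;
      same body and tail as the original.
    * ``deepened`` — 224x224 input, 3x3 stride-1 stem, six extra dual modules
      inserted before the tail; 416-feature tail.
    * ``revised_deepened`` — the deepened front with the six inserted modules
      slimmed back to 176/160-filter branches; 336-feature tail.
    """
    out: dict[str, ArchitectureSpec] = {}
    pkg = importlib.resources.files("dualpathcnn") / "specs"
    for name, fname in _BUILTIN_FILES.items():
        with (pkg / fname).open("r", encoding="utf-8") as fh:
            out[name] = load_spec(fh)
    return out


def get_spec(name_or_path: str) -> ArchitectureSpec:
    """Resolve a builtin spec name or a path to a spec file."""
    if name_or_path in _BUILTIN_FILES:
        return builtin_specs()[name_or_path]
    if Path(name_or_path).exists():
        return load_spec(name_or_path)
    raise FileNotFoundError(
        f"{name_or_path!r} is neither a builtin architecture "
        f"({', '.join(_BUILTIN_FILES)}) nor an existing file"
    )
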