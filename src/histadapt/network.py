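"""The three-path 2.5D patch CNN with a spatial-prior branch.

Every voxel is classified from three orthogonal 32×32 patches, each processed
by its own convolutional path (five convolutions then a fully connected
layer), concatenated with the K atlas probabilities at the voxel, and mined
by fully connected head layers ending in a softmax classifier.  Activations
of selected layers ("taps") can be captured during the forward pass for the
feature-histogram alignment loss; by default the taps are the last three
convolutions of every path, the per-path fully connected layers and the head
fully connected layers — never the classifier.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor

__all__ = ["NetworkSpec", "Network", "build_network", "forward_with_activations",
           "tiny_spec", "save_checkpoint", "load_checkpoint"]

_PATH_NAMES = ("axial", "sagittal", "coronal")


@dataclass(frozen=True)
class NetworkSpec:
    """Architecture hyper-parameters.

    The channel counts and kernel size below are the package defaults for the
    full-scale configuration; the desk-scale experiments use :func:`tiny_spec`.
    ``out_classes`` is 15 for the structure task (14 structures + background)
    and 2 for the lesion task (lesion vs. background); ``prior_units`` is 15
    and 3 respectively.
    """

    patch_size: int = 32
    conv_channels: tuple[int, ...] = (32, 32, 64, 64, 128)
    kernel_size: int = 3
    path_fc_units: int = 256
    prior_units: int = 15
    head_fc_units: tuple[int, ...] = (512, 256)
    out_classes: int = 15
    tap_conv_count: int = 3
    tap_layers: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        if self.patch_size < 3:
            raise ValueError("patch size must be at least 3")
        if not self.conv_channels:
            raise ValueError("need at least one convolution per path")
        if self.kernel_size % 2 != 1:
            raise ValueError("kernel size must be odd (same padding)")
        if self.out_classes < 2 or self.prior_units < 1:
            raise ValueError("invalid class/prior configuration")
        if self.tap_layers is not None:
            bad = set(self.tap_layers) - set(self.layer_names())
            if bad:
                raise ValueError(f"unknown tap layers: {sorted(bad)}")
            if "classifier" in self.tap_layers:
                raise ValueError("the classifier layer is never tapped")

    def layer_names(self) -> list[str]:
        names = []
        for p in _PATH_NAMES:
            names += [f"{p}_conv{i}" for i in range(len(self.conv_channels))]
            names.append(f"{p}_fc")
        names += [f"head_fc{i}" for i in range(len(self.head_fc_units))]
        names.append("classifier")
        return names

    def default_taps(self) -> tuple[str, ...]:
        """Last ``tap_conv_count`` convolutions per path + all FCs except classifier."""
        n_conv = len(self.conv_channels)
        k = min(self.tap_conv_count, n_conv)
        taps = []
        for p in _PATH_NAMES:
            taps += [f"{p}_conv{i}" for i in range(n_conv - k, n_conv)]
            taps.append(f"{p}_fc")
        taps += [f"head_fc{i}" for i in range(len(self.head_fc_units))]
        return tuple(taps)

    @property
    def taps(self) -> tuple[str, ...]:
        return self.tap_layers if self.tap_layers is not None else self.default_taps()


def tiny_spec(prior_units: int, out_classes: int, patch_size: int = 11) -> NetworkSpec:
    """A small configuration for CPU-scale phantom experiments."""
    return NetworkSpec(
        patch_size=patch_size,
        conv_channels=(8, 12, 16),
        kernel_size=3,
        path_fc_units=32,
        prior_units=prior_units,
        head_fc_units=(48, 32),
        out_classes=out_classes,
        tap_conv_count=2,
    )


class Network:
    """Parameterised three-path patch classifier (see module docstring)."""

    def __init__(self, spec: NetworkSpec, seed: int = 0):
        self.spec = spec
        self.seed = int(seed)
        rng = np.random.default_rng(seed)
        self.params: dict[str, Tensor] = {}
        k = spec.kernel_size
        for p in _PATH_NAMES:
            in_c = 1
            for i, out_c in enumerate(spec.conv_channels):
                self._add_conv(rng, f"{p}_conv{i}", in_c, out_c, k)
                in_c = out_c
            flat = spec.conv_channels[-1] * spec.patch_size * spec.patch_size
            self._add_dense(rng, f"{p}_fc", flat, spec.path_fc_units)
        in_f = 3 * spec.path_fc_units + spec.prior_units
        for i, units in enumerate(spec.head_fc_units):
            self._add_dense(rng, f"head_fc{i}", in_f, units)
            in_f = units
        self._add_dense(rng, "classifier", in_f, spec.out_classes)

    def _add_conv(self, rng, name, in_c, out_c, k):
        fan_in = in_c * k * k
        w = rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(out_c, in_c, k, k))
        self.params[f"{name}.w"] = Tensor(w.astype(np.float32), requires_grad=True)
        self.params[f"{name}.b"] = Tensor(np.zeros(out_c, dtype=np.float32), requires_grad=True)

    def _add_dense(self, rng, name, in_f, out_f):
        w = rng.normal(0.0, np.sqrt(2.0 / in_f), size=(in_f, out_f))
        self.params[f"{name}.w"] = Tensor(w.astype(np.float32), requires_grad=True)
        self.params[f"{name}.b"] = Tensor(np.zeros(out_f, dtype=np.float32), requires_grad=True)

    def parameters(self) -> list[Tensor]:
        return list(self.params.values())

    def forward(self, patches: np.ndarray, priors: np.ndarray,
                capture: bool = False) -> tuple[Tensor, dict[str, Tensor]]:
        """Forward a batch; optionally capture tap-layer activations.

        ``patches``: (N, 3, S, S) float32 in path order (axial, sagittal,
        coronal); ``priors``: (N, K).  Returns logits and an ordered mapping
        from tap-layer name to its post-nonlinearity activation Tensor.
        Capturing never alters the forward computation.
        """
        patches = np.asarray(patches, dtype=np.float32)
        priors = np.asarray(priors, dtype=np.float32)
        if patches.ndim != 4 or patches.shape[1] != 3:
            raise ValueError("patches must have shape (N, 3, S, S)")
        if patches.shape[0] == 0:
            raise ValueError("empty batch")
        s = self.spec.patch_size
        if patches.shape[2:] != (s, s):
            raise ValueError(f"expected {s}x{s} patches, got {patches.shape[2:]}")
        if priors.shape != (patches.shape[0], self.spec.prior_units):
            raise ValueError("prior vector batch has the wrong shape")

        taps = self.spec.taps
        acts: dict[str, Tensor] = {}

        def record(name: str, t: Tensor) -> Tensor:
            if capture and name in taps:
                acts[name] = t
            return t

        path_outputs = []
        for pi, p in enumerate(_PATH_NAMES):
            x = Tensor(np.ascontiguousarray(patches[:, pi:pi + 1]))
            for i in range(len(self.spec.conv_channels)):
                x = ad.relu(ad.conv2d(x, self.params[f"{p}_conv{i}.w"],
                                      self.params[f"{p}_conv{i}.b"]))
                record(f"{p}_conv{i}", x)
            x = ad.relu(ad.dense(ad.flatten(x), self.params[f"{p}_fc.w"],
                                 self.params[f"{p}_fc.b"]))
            record(f"{p}_fc", x)
            path_outputs.append(x)
        h = ad.concat(path_outputs + [Tensor(priors)])
        for i in range(len(self.spec.head_fc_units)):
            h = ad.relu(ad.dense(h, self.params[f"head_fc{i}.w"],
                                 self.params[f"head_fc{i}.b"]))
            record(f"head_fc{i}", h)
        logits = ad.dense(h, self.params["classifier.w"], self.params["classifier.b"])
        ordered = {name: acts[name] for name in taps if name in acts}
        return logits, ordered

    def predict_proba(self, patches: np.ndarray, priors: np.ndarray,
                      batch_size: int = 1024) -> np.ndarray:
        """Class probabilities for many samples, batched, without gradients."""
        out = []
        for i in range(0, len(patches), batch_size):
            logits, _ = self.forward(patches[i:i + batch_size], priors[i:i + batch_size])
            out.append(ad.softmax(logits.data.astype(np.float64)))
        return np.concatenate(out, axis=0)

    def state_dict(self) -> dict[str, np.ndarray]:
        return {k: v.data.copy() for k, v in self.params.items()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for k, v in self.params.items():
            if k not in state:
                raise KeyError(f"missing parameter {k} in checkpoint")
            if state[k].shape != v.data.shape:
                raise ValueError(f"shape mismatch for {k}")
            v.data = np.asarray(state[k], dtype=v.data.dtype).copy()


def build_network(spec: NetworkSpec, seed: int = 0) -> Network:
    """Construct a network with seeded He-normal weight initialisation."""
    return Network(spec, seed=seed)


def forward_with_activations(network: Network, patches: np.ndarray,
                             priors: np.ndarray) -> tuple[np.ndarray, dict[str, Tensor]]:
    """Probabilities plus tapped activations for one batch."""
    logits, acts = network.forward(patches, priors, capture=True)
    return ad.softmax(logits.data.astype(np.float64)), acts


def save_checkpoint(network: Network, path) -> None:
    """Weights as .npz with a JSON sidecar holding the spec and seed."""
    path = Path(path)
    np.savez(path, **network.state_dict())
    spec = asdict(network.spec)
    sidecar = path.with_suffix(path.suffix + ".json")
    sidecar.write_text(json.dumps({"spec": spec, "seed": network.seed}, indent=2))


def load_checkpoint(path) -> Network:
    path = Path(path)
    sidecar = path.with_suffix(path.suffix + ".json")
    meta = json.loads(sidecar.read_text())
    spec_dict = meta["spec"]
    for key in ("conv_channels", "head_fc_units"):
        spec_dict[key] = tuple(spec_dict[key])
    if spec_dict.get("tap_layers") is not None:
        spec_dict["tap_layers"] = tuple(spec_dict["tap_layers"])
    net = Network(NetworkSpec(**spec_dict), seed=meta["seed"])
    with np.load(path) as data:
        net.load_state_dict({k: data[k] for k in data.files})
    return net
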