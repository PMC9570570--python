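"""Network suite: shared feature extractor, heads and generator.

The classifier architecture is a four-layer fully connected feature
extractor (256, 128, 64, 32 units, ReLU) whose 32-unit output feeds three
single-layer logistic heads: the five-class allergen classifier, a domain
discriminator (source vs target) and a real/fake discriminator for
adversarial training against the generator.  The generator maps a latent
normal vector through layers of 32, 64, 128, 256 units to a full spectrum
(401, 451 or 852 points depending on the active sensor grid).  Generated
spectra are judged through the same shared feature extractor as real ones.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from ._nn import MLP, softmax

__all__ = ["NetworkSuite", "build_network_suite", "save_suite", "load_suite"]

_VALID_INPUT_DIMS = (401, 451, 852)

_COMPONENTS = (
    "feature_extractor",
    "classifier_head",
    "domain_discriminator",
    "realfake_discriminator",
    "generator",
)


@dataclass
class NetworkSuite:
    """All five trainable components plus the dimensions that define them."""

    feature_extractor: MLP  # input_dim -> 256 -> 128 -> 64 -> 32
    classifier_head: MLP  # 32 -> n_classes (logistic)
    domain_discriminator: MLP  # 32 -> 2 (source vs target)
    realfake_discriminator: MLP  # 32 -> 2 (real vs generated)
    generator: MLP  # latent_dim -> 32 -> 64 -> 128 -> 256 -> input_dim
    input_dim: int
    n_classes: int
    latent_dim: int
    seed: int

    def features(self, x: np.ndarray) -> np.ndarray:
        return self.feature_extractor.forward(x)[0]

    def class_probabilities(self, x: np.ndarray) -> np.ndarray:
        """Softmax class scores for a batch of spectra (rows sum to 1)."""
        logits, _ = self.classifier_head.forward(self.features(x))
        return softmax(logits)

    def domain_probabilities(self, x: np.ndarray) -> np.ndarray:
        logits, _ = self.domain_discriminator.forward(self.features(x))
        return softmax(logits)

    def realfake_probabilities(self, x: np.ndarray) -> np.ndarray:
        logits, _ = self.realfake_discriminator.forward(self.features(x))
        return softmax(logits)

    def generate(self, n: int, rng: np.random.Generator) -> np.ndarray:
        """Draw ``n`` spectra from latent standard-normal noise."""
        z = rng.normal(0.0, 1.0, size=(n, self.latent_dim)).astype(np.float32)
        return self.generator.forward(z)[0]

    def copy(self) -> "NetworkSuite":
        return NetworkSuite(
            **{name: getattr(self, name).copy() for name in _COMPONENTS},
            input_dim=self.input_dim,
            n_classes=self.n_classes,
            latent_dim=self.latent_dim,
            seed=self.seed,
        )


def build_network_suite(
    input_dim: int, n_classes: int = 5, latent_dim: int = 16, seed: int = 0
) -> NetworkSuite:
    """Build a suite with independently initialized, seed-deterministic
    weights.

    ``input_dim`` must match one of the sensor grids (401, 451 or 852
    wavelengths).  Initialization is He-scaled Gaussian per layer; each
    component draws from its own child stream of ``seed`` so, e.g., the
    extractor's initial weights do not depend on whether a generator is
    ever used.
    """
    if input_dim not in _VALID_INPUT_DIMS:
        raise ValueError(
            f"input_dim must be one of {_VALID_INPUT_DIMS}, got {input_dim}"
        )
    if n_classes <= 0 or latent_dim <= 0:
        raise ValueError("n_classes and latent_dim must be positive")
    streams = [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(5)]
    return NetworkSuite(
        feature_extractor=MLP.init((input_dim, 256, 128, 64, 32), streams[0]),
        classifier_head=MLP.init((32, n_classes), streams[1]),
        domain_discriminator=MLP.init((32, 2), streams[2]),
        realfake_discriminator=MLP.init((32, 2), streams[3]),
        generator=MLP.init((latent_dim, 32, 64, 128, 256, input_dim), streams[4]),
        input_dim=input_dim,
        n_classes=n_classes,
        latent_dim=latent_dim,
        seed=seed,
    )


def save_suite(suite: NetworkSuite, path) -> Path:
    """Serialize the suite (weights + architecture + seed) to one ``.npz``
    checkpoint."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    arrays = {}
    arch = {
        "input_dim": suite.input_dim,
        "n_classes": suite.n_classes,
        "latent_dim": suite.latent_dim,
        "seed": suite.seed,
        "dims": {},
    }
    for name in _COMPONENTS:
        mlp: MLP = getattr(suite, name)
        arch["dims"][name] = list(mlp.dims)
        for i, p in enumerate(mlp.params):
            arrays[f"{name}/{i}"] = p
    arrays["architecture"] = np.frombuffer(
        json.dumps(arch).encode(), dtype=np.uint8
    )
    np.savez(path, **arrays)
    return path


def load_suite(path) -> NetworkSuite:
    with np.load(Path(path)) as data:
        arch = json.loads(bytes(data["architecture"].tobytes()).decode())
        parts = {}
        for name in _COMPONENTS:
            dims = tuple(arch["dims"][name])
            n_params = 2 * (len(dims) - 1)
            parts[name] = MLP(dims, [data[f"{name}/{i}"] for i in range(n_params)])
    return NetworkSuite(
        **parts,
        input_dim=arch["input_dim"],
        n_classes=arch["n_classes"],
        latent_dim=arch["latent_dim"],
        seed=arch["seed"],
    )
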