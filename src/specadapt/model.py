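"""Domain-adaptation model and results objects.

:class:`DomainAdaptationModel` is built from a :class:`~specadapt.spectra_io.DomainSplit`
and a :class:`TrainConfig`; ``fit()`` runs one of four training procedures
and returns a :class:`DomainAdaptationResults` carrying the trained network
suite, the per-iteration loss history, and prediction/summary methods.

Methods
-------
``TL``
    Transfer-learning baseline: cross-entropy on all labelled spectra
    (static source plus any labelled target instances); unlabelled target
    data are ignored.
``DANN``
    Domain-adversarial training.  Each iteration runs three sequential
    steps: (1) feature extractor + classifier minimize classification
    cross-entropy on a labelled batch; (2) the domain discriminator is
    trained to classify the domain of that labelled batch while the feature
    extractor is updated to confuse it; (3) the same adversarial pair of
    updates on a batch of unlabelled target spectra.
``SGAN``
    Semisupervised GAN training.  Each iteration runs the classification
    step and then three sequential real/fake steps: (1) extractor +
    discriminator learn that labelled spectra are real; (2) they learn that
    generator output is fake while the generator is updated to confuse
    them; (3) they learn that unlabelled target spectra are real.
``SGAN+DANN``
    Both adversarial schedules around a single classification step.

Confusion updates use the "negative inverse" transform of the adversary's
loss: the feature extractor (or generator) ascends ``-1/(L + eps)``, so its
step size scales as ``1/(L + eps)^2`` — large when the discriminator is
accurate (small ``L``), vanishing once the adversary is already confused.
A plain loss-negation mode (classic gradient reversal) is kept for
ablation.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np

from ._nn import Adam, MLP, softmax, softmax_cross_entropy
from .networks import NetworkSuite, build_network_suite, _COMPONENTS
from .spectra_io import ALLERGEN_CLASSES, DomainSplit, SpectralDataset

__all__ = [
    "TrainConfig",
    "DomainAdaptationModel",
    "DomainAdaptationResults",
    "adversarial_transform",
]

logger = logging.getLogger(__name__)

METHODS = ("TL", "DANN", "SGAN", "SGAN+DANN")

_DOMAIN_SOURCE, _DOMAIN_TARGET = 0, 1
_REAL, _FAKE = 0, 1


@dataclass
class TrainConfig:
    """Training hyperparameters.

    Defaults follow the study protocol: batch size 32, learning rate 0.001,
    Adam, 10,000 epochs (one epoch = one pass over the labelled pool in
    mini-batches; unlabelled and generated batches are drawn cyclically to
    pair with each labelled batch).  ``adversarial_mode`` selects the
    confusion objective: ``"reciprocal"`` for the negative-inverse
    transform, ``"negation"`` for plain gradient reversal.
    ``enable_adversarial=False`` switches every adversarial branch off, so
    all four methods collapse onto the TL baseline.
    """

    batch_size: int = 32
    learning_rate: float = 0.001
    optimizer: str = "adam"
    epochs: int = 10_000
    adversarial_eps: float = 1e-6
    adversarial_mode: str = "reciprocal"
    enable_adversarial: bool = True
    latent_dim: int = 16
    standardize: bool = True
    seed: int = 0

    def __post_init__(self):
        if self.batch_size < 1 or self.epochs < 1:
            raise ValueError("batch_size and epochs must be >= 1")
        if self.adversarial_eps <= 0:
            raise ValueError("adversarial_eps must be positive")
        if self.adversarial_mode not in ("reciprocal", "negation"):
            raise ValueError(f"unknown adversarial_mode {self.adversarial_mode!r}")
        if self.optimizer.lower() != "adam":
            raise ValueError("only the Adam optimizer is supported")


def adversarial_transform(
    loss_value: float, eps: float = 1e-6, mode: str = "reciprocal"
) -> float:
    """Transform an adversary's loss into the confusion objective value.

    ``reciprocal`` returns ``-1/(loss + eps)``: monotone increasing in the
    loss, with gradient magnitude ``1/(loss + eps)^2`` that explodes as the
    adversary gets accurate.  ``negation`` returns ``-loss``.
    """
    if loss_value < 0:
        raise ValueError(f"loss must be nonnegative, got {loss_value}")
    if mode == "reciprocal":
        return -1.0 / (loss_value + eps)
    if mode == "negation":
        return -float(loss_value)
    raise ValueError(f"unknown adversarial mode {mode!r}")


def _confusion_gradient_scale(loss_value: float, eps: float, mode: str) -> float:
    """Multiplier ``s`` such that a descent step on ``s * dL/dtheta``
    ascends the adversary's loss with the magnitude profile of
    :func:`adversarial_transform` (``1/(L+eps)^2`` for reciprocal, 1 for
    negation)."""
    if mode == "reciprocal":
        return -1.0 / (loss_value + eps) ** 2
    return -1.0


class _CyclicBatcher:
    """Endless mini-batches over a fixed matrix, reshuffled each pass."""

    def __init__(self, x: np.ndarray, batch_size: int, rng: np.random.Generator):
        self.x = x
        self.batch_size = batch_size
        self.rng = rng
        self._order = rng.permutation(len(x))
        self._pos = 0

    def next(self) -> np.ndarray:
        take = []
        need = self.batch_size
        while need > 0:
            chunk = self._order[self._pos : self._pos + need]
            take.append(chunk)
            self._pos += len(chunk)
            need -= len(chunk)
            if self._pos >= len(self._order):
                self._order = self.rng.permutation(len(self.x))
                self._pos = 0
        return self.x[np.concatenate(take)]


class DomainAdaptationModel:
    """A classifier transferred from stationary to moving spectra.

    Parameters
    ----------
    split : DomainSplit
        Labelled source (static), optional labelled target, unlabelled
        target and test subsets.
    method : str
        One of ``"TL"``, ``"DANN"``, ``"SGAN"``, ``"SGAN+DANN"``.
    config : TrainConfig, optional
    """

    def __init__(
        self,
        split: DomainSplit,
        method: str = "SGAN+DANN",
        config: TrainConfig | None = None,
    ):
        if method not in METHODS:
            raise ValueError(f"method must be one of {METHODS}, got {method!r}")
        self.split = split
        self.method = method
        self.config = config or TrainConfig()

        if len(split.source_labelled) == 0:
            raise ValueError("source_labelled must be non-empty")
        if method != "TL" and len(split.target_unlabelled) == 0:
            raise ValueError(
                f"{method} requires unlabelled target spectra; with none "
                "available, train the transfer baseline (method='TL') instead"
            )

        parts = [split.source_labelled]
        if len(split.target_labelled):
            parts.append(split.target_labelled)
        pool = SpectralDataset.concat(parts)
        self._x_lab = pool.intensities
        self._y_lab = pool.labels
        self._d_lab = np.concatenate(
            [
                np.full(len(split.source_labelled), _DOMAIN_SOURCE),
                np.full(len(split.target_labelled), _DOMAIN_TARGET),
            ]
        ).astype(int)
        self._x_unlab = split.target_unlabelled.intensities
        self.input_dim = len(split.source_labelled.grid)

    # ------------------------------------------------------------------
    def fit(self) -> "DomainAdaptationResults":
        cfg = self.config
        children = np.random.SeedSequence(cfg.seed).spawn(4)
        net_seed = int(children[0].generate_state(1)[0] & 0x7FFFFFFF)
        rng_lab = np.random.default_rng(children[1])
        rng_unlab = np.random.default_rng(children[2])
        rng_latent = np.random.default_rng(children[3])

        suite = build_network_suite(
            self.input_dim, n_classes=len(ALLERGEN_CLASSES),
            latent_dim=cfg.latent_dim, seed=net_seed,
        )

        if cfg.standardize:
            mu = self._x_lab.mean(axis=0)
            sd = np.maximum(self._x_lab.std(axis=0), 1e-8)
        else:
            mu = np.zeros(self.input_dim)
            sd = np.ones(self.input_dim)
        x_lab = ((self._x_lab - mu) / sd).astype(np.float32)
        x_unlab = (
            ((self._x_unlab - mu) / sd).astype(np.float32)
            if len(self._x_unlab)
            else self._x_unlab.astype(np.float32)
        )

        ext, cls = suite.feature_extractor, suite.classifier_head
        dom, rf, gen = (
            suite.domain_discriminator,
            suite.realfake_discriminator,
            suite.generator,
        )
        lr = cfg.learning_rate
        opt = {
            "ext": Adam(ext.params, lr),
            "cls": Adam(cls.params, lr),
            "dom": Adam(dom.params, lr),
            "rf": Adam(rf.params, lr),
            "gen": Adam(gen.params, lr),
        }

        use_dann = cfg.enable_adversarial and self.method in ("DANN", "SGAN+DANN")
        use_sgan = cfg.enable_adversarial and self.method in ("SGAN", "SGAN+DANN")
        if use_dann and not np.any(self._d_lab == _DOMAIN_TARGET):
            logger.info(
                "DANN labelled-domain step is degenerate: no labelled target "
                "spectra, step 2 batches contain a single domain class"
            )
        unlab_batcher = (
            _CyclicBatcher(x_unlab, cfg.batch_size, rng_unlab)
            if (use_dann or use_sgan)
            else None
        )

        def classification_step(xb, yb):
            f, cf = ext.forward(xb)
            logits, cc = cls.forward(f)
            loss, dlog = softmax_cross_entropy(logits, yb)
            dfeat, g_cls = cls.backward(dlog, cc)
            _, g_ext = ext.backward(dfeat, cf)
            opt["cls"].step(g_cls)
            opt["ext"].step(g_ext)
            return loss

        def discriminate_step(xb, labels, disc, disc_key, train_extractor):
            """Adversary minimizes CE; optionally the extractor co-trains
            (SGAN steps) instead of opposing."""
            f, cf = ext.forward(xb)
            logits, cd = disc.forward(f)
            loss, dlog = softmax_cross_entropy(logits, labels)
            dfeat, g_disc = disc.backward(dlog, cd)
            opt[disc_key].step(g_disc)
            if train_extractor:  # cooperative update (SGAN real/fake steps)
                _, g_ext = ext.backward(dfeat, cf)
                opt["ext"].step(g_ext)
            return loss

        def confuse_extractor(xb, labels, disc, disc_key):
            """Two-pass adversarial step: adversary update, then extractor
            ascends the transformed loss against the updated adversary."""
            loss_disc = discriminate_step(xb, labels, disc, disc_key, False)
            f, cf = ext.forward(xb)
            logits, cd = disc.forward(f)
            loss2, dlog = softmax_cross_entropy(logits, labels)
            scale = _confusion_gradient_scale(
                loss2, cfg.adversarial_eps, cfg.adversarial_mode
            )
            dfeat, _ = disc.backward(dlog, cd)
            _, g_ext = ext.backward(scale * dfeat, cf)
            opt["ext"].step(g_ext)
            return loss_disc, adversarial_transform(
                loss2, cfg.adversarial_eps, cfg.adversarial_mode
            )

        def sgan_generator_step():
            # 2a: extractor + discriminator learn generated batch is fake
            z = rng_latent.normal(
                0.0, 1.0, size=(cfg.batch_size, cfg.latent_dim)
            ).astype(np.float32)
            xg, cg = gen.forward(z)
            fake = np.full(cfg.batch_size, _FAKE)
            loss_disc = discriminate_step(xg, fake, rf, "rf", True)
            # 2b: generator ascends the transformed fake-detection loss
            xg, cg = gen.forward(z)
            f, cf = ext.forward(xg)
            logits, cd = rf.forward(f)
            loss2, dlog = softmax_cross_entropy(logits, fake)
            scale = _confusion_gradient_scale(
                loss2, cfg.adversarial_eps, cfg.adversarial_mode
            )
            dfeat, _ = rf.backward(dlog, cd)
            dx, _ = ext.backward(dfeat, cf)
            _, g_gen = gen.backward(scale * dx, cg)
            opt["gen"].step(g_gen)
            return loss_disc, adversarial_transform(
                loss2, cfg.adversarial_eps, cfg.adversarial_mode
            )

        loss_history: list[dict] = []
        n_lab = len(x_lab)
        for _epoch in range(cfg.epochs):
            order = rng_lab.permutation(n_lab)
            for start in range(0, n_lab, cfg.batch_size):
                idx = order[start : start + cfg.batch_size]
                xb, yb, db = x_lab[idx], self._y_lab[idx], self._d_lab[idx]
                record: dict[str, float] = {}
                # step 1 everywhere: supervised classification
                record["classification"] = classification_step(xb, yb)
                if use_dann:
                    # step 2: domain of the labelled batch, adversarially
                    d_loss, d_adv = confuse_extractor(xb, db, dom, "dom")
                    record["domain_disc_labelled"] = d_loss
                    record["domain_confusion_labelled"] = d_adv
                    # step 3: domain of an unlabelled target batch
                    xu = unlab_batcher.next()
                    du = np.full(len(xu), _DOMAIN_TARGET)
                    d_loss, d_adv = confuse_extractor(xu, du, dom, "dom")
                    record["domain_disc_unlabelled"] = d_loss
                    record["domain_confusion_unlabelled"] = d_adv
                if use_sgan:
                    # real/fake step 1: labelled data are real
                    record["realfake_labelled"] = discriminate_step(
                        xb, np.full(len(xb), _REAL), rf, "rf", True
                    )
                    # step 2: generated data are fake; generator confuses
                    g_loss, g_adv = sgan_generator_step()
                    record["realfake_generated"] = g_loss
                    record["generator_confusion"] = g_adv
                    # step 3: unlabelled target data are real
                    xu = unlab_batcher.next()
                    record["realfake_unlabelled"] = discriminate_step(
                        xu, np.full(len(xu), _REAL), rf, "rf", True
                    )
                loss_history.append(record)

        return DomainAdaptationResults(
            suite=suite,
            method_tag=self.method,
            config=cfg,
            loss_history=loss_history,
            mu=mu,
            sd=sd,
            model=self,
        )


@dataclass
class DomainAdaptationResults:
    """Fitted weights plus everything needed to predict and report."""

    suite: NetworkSuite
    method_tag: str
    config: TrainConfig
    loss_history: list[dict]
    mu: np.ndarray
    sd: np.ndarray
    model: DomainAdaptationModel | None = None

    def _check_grid(self, x: np.ndarray) -> None:
        if x.shape[1] != self.suite.input_dim:
            raise ValueError(
                f"dataset has {x.shape[1]} wavelengths but the model expects "
                f"{self.suite.input_dim}"
            )

    def predict_proba(self, ds: SpectralDataset | np.ndarray) -> np.ndarray:
        x = ds.intensities if isinstance(ds, SpectralDataset) else np.asarray(ds)
        self._check_grid(x)
        return self.suite.class_probabilities(
            ((x - self.mu) / self.sd).astype(np.float32)
        )

    def predict(
        self, ds: SpectralDataset | np.ndarray
    ) -> tuple[np.ndarray, np.ndarray]:
        """Predicted class names and class-probability rows (sum to 1)."""
        proba = self.predict_proba(ds)
        labels = np.array(ALLERGEN_CLASSES, dtype=object)[proba.argmax(axis=1)]
        return labels, proba

    def accuracy(self, ds: SpectralDataset) -> float:
        """Percentage of correctly classified allergen categories."""
        labels, _ = self.predict(ds)
        truth = ds.meta["allergen_class"].to_numpy()
        return round(100.0 * float(np.mean(labels == truth)), 2)

    def summary(self) -> str:
        """Plain-text fit report in the spirit of a regression summary."""
        lines = [
            "Domain adaptation results",
            "=" * 58,
            f"{'Method:':<28}{self.method_tag}",
            f"{'Input wavelengths:':<28}{self.suite.input_dim}",
            f"{'Epochs:':<28}{self.config.epochs}",
            f"{'Optimization steps:':<28}{len(self.loss_history)}",
            f"{'Batch size / lr:':<28}{self.config.batch_size} / "
            f"{self.config.learning_rate}",
            f"{'Adversarial mode:':<28}{self.config.adversarial_mode}"
            f"{'' if self.config.enable_adversarial else ' (disabled)'}",
            f"{'Seed:':<28}{self.config.seed}",
            "-" * 58,
        ]
        if self.loss_history:
            last = self.loss_history[-1]
            lines.append("Final losses:")
            for name, value in last.items():
                lines.append(f"  {name:<26}{value: .6f}")
        if self.model is not None:
            split = self.model.split
            lines.append("-" * 58)
            lines.append(
                f"{'Training accuracy (%):':<28}"
                f"{self.accuracy(_labelled_pool(split)):.2f}"
            )
            if len(split.target_test):
                lines.append(
                    f"{'Target test accuracy (%):':<28}"
                    f"{self.accuracy(split.target_test):.2f}"
                )
        return "\n".join(lines)

    # -- checkpointing -------------------------------------------------
    def save(self, path) -> Path:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        arrays = {"mu": self.mu, "sd": self.sd}
        meta = {
            "method_tag": self.method_tag,
            "config": asdict(self.config),
            "loss_history": self.loss_history,
            "architecture": {
                "input_dim": self.suite.input_dim,
                "n_classes": self.suite.n_classes,
                "latent_dim": self.suite.latent_dim,
                "seed": self.suite.seed,
                "dims": {
                    name: list(getattr(self.suite, name).dims)
                    for name in _COMPONENTS
                },
            },
        }
        for name in _COMPONENTS:
            for i, p in enumerate(getattr(self.suite, name).params):
                arrays[f"{name}/{i}"] = p
        arrays["meta"] = np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8)
        np.savez(path, **arrays)
        return path

    @classmethod
    def load(cls, path) -> "DomainAdaptationResults":
        with np.load(Path(path)) as data:
            meta = json.loads(bytes(data["meta"].tobytes()).decode())
            arch = meta["architecture"]
            parts = {}
            for name in _COMPONENTS:
                dims = tuple(arch["dims"][name])
                parts[name] = MLP(
                    dims, [data[f"{name}/{i}"] for i in range(2 * (len(dims) - 1))]
                )
            mu, sd = data["mu"], data["sd"]
        suite = NetworkSuite(
            **parts,
            input_dim=arch["input_dim"],
            n_classes=arch["n_classes"],
            latent_dim=arch["latent_dim"],
            seed=arch["seed"],
        )
        return cls(
            suite=suite,
            method_tag=meta["method_tag"],
            config=TrainConfig(**meta["config"]),
            loss_history=meta["loss_history"],
            mu=mu,
            sd=sd,
        )


def _labelled_pool(split: DomainSplit) -> SpectralDataset:
    parts = [split.source_labelled]
    if len(split.target_labelled):
        parts.append(split.target_labelled)
    return SpectralDataset.concat(parts)
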