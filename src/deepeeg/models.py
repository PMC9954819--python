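"""Model architectures: convolutional autoencoder and classifier heads.

The detector couples a deep convolutional autoencoder (DCAE) with a
recurrent classification head.  The encoder alternates four 3x3
convolutions (32, 32, 64, 64 filters, ReLU, same padding) with four
max-pooling stages; the decoder mirrors it with four convolutions
(64, 32, 32, 1 filters) and four upsampling stages, ending in a sigmoid so
reconstructions live in the [0, 1] range of the min-max-scaled inputs.
The bottleneck (latent representation) feeds one of three heads:

* ``mlp``    — flatten, dense(50, ReLU), dropout, softmax(2)
* ``lstm``   — bottleneck read as a sequence along the reduced time axis,
  LSTM(80), temporal average pooling, dense(50, ReLU), dropout, softmax(2)
* ``bilstm`` — as above with a bidirectional LSTM (80 units per direction)

A "DCNN" baseline is the same encoder + head without the decoder (single
output, no reconstruction objective).

Pooling convention: inputs are electrode-by-time planes.  The time (width)
axis pools by strict floor division and must stay >= 1 through all four
stages (otherwise a :class:`~deepeeg.errors.ShapeError` is raised at build
time); the electrode (height) axis pools by floor but passes through
unchanged once it reaches 1, so montages with fewer electrodes than
``pool**4`` remain usable.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field

import numpy as np

from . import nn
from .errors import ConfigurationError, ShapeError

__all__ = [
    "ModelConfig",
    "MODEL_ROSTER",
    "roster_config",
    "encoder_stage_shapes",
    "build_encoder",
    "build_decoder",
    "build_head",
    "build_model",
    "ArchitectureDescriptor",
    "JointModel",
    "instantiate",
]

HEADS = ("mlp", "lstm", "bilstm")

#: The four model variants evaluated against each other.
MODEL_ROSTER = ("dcae-mlp", "dcae-lstm", "dcnn-mlp", "dcae-bilstm")


@dataclass(frozen=True)
class ModelConfig:
    """Architecture hyperparameters.

    Defaults follow the reference configuration: encoder filters
    (32, 32, 64, 64), decoder filters (64, 32, 32, 1), 3x3 kernels, 2x2
    pooling, Bi-LSTM head with 80 units per direction, dense layer of 50,
    dropout 0.75, two classes.  ``autoencoder=False`` selects the DCNN
    baseline (no decoder).  ``avg_pool_after_dense`` switches the head to
    the literal layer order (per-step dense before temporal averaging).
    """

    encoder_filters: tuple[int, ...] = (32, 32, 64, 64)
    decoder_filters: tuple[int, ...] = (64, 32, 32, 1)
    kernel: int = 3
    pool: int = 2
    head: str = "bilstm"
    bilstm_units: int = 80
    dense_units: int = 50
    dropout_rate: float = 0.75
    n_classes: int = 2
    autoencoder: bool = True
    avg_pool_after_dense: bool = False
    seed: int = 0
    dtype: str = "float32"

    def __post_init__(self):
        if len(self.encoder_filters) != 4 or len(self.decoder_filters) != 4:
            raise ConfigurationError(
                "encoder and decoder must each have exactly 4 conv stages"
            )
        if self.decoder_filters[-1] != 1:
            raise ConfigurationError("decoder's final conv must have 1 filter")
        if not 0 <= self.dropout_rate < 1:
            raise ConfigurationError("dropout_rate must be in [0, 1)")
        if self.head not in HEADS:
            raise ConfigurationError(
                f"unknown head {self.head!r}; choose from {HEADS}"
            )
        if self.kernel % 2 != 1 or self.kernel < 1:
            raise ConfigurationError("kernel must be an odd positive integer")
        if self.pool < 2:
            raise ConfigurationError("pool factor must be >= 2")


def roster_config(name: str, **overrides) -> ModelConfig:
    """ModelConfig for one of the four standard variants."""
    table = {
        "dcae-mlp": dict(head="mlp", autoencoder=True),
        "dcae-lstm": dict(head="lstm", autoencoder=True),
        "dcnn-mlp": dict(head="mlp", autoencoder=False),
        "dcae-bilstm": dict(head="bilstm", autoencoder=True),
    }
    try:
        base = table[name]
    except KeyError:
        raise ConfigurationError(
            f"unknown model {name!r}; choose from {MODEL_ROSTER}"
        ) from None
    base.update(overrides)
    return ModelConfig(**base)


def _pool_hw(h: int, w: int, pool: int) -> tuple[int, int]:
    h2 = max(h // pool, 1) if h >= 1 else 0
    w2 = w // pool
    return h2, w2


def encoder_stage_shapes(
    input_hw: tuple[int, int], config: ModelConfig
) -> list[tuple[int, int]]:
    """Spatial shape after each of the four pooling stages.

    Raises :class:`ShapeError` if the time axis collapses to zero.
    """
    h, w = input_hw
    shapes = []
    for stage in range(4):
        h, w = _pool_hw(h, w, config.pool)
        if w < 1:
            raise ShapeError(
                f"input plane {input_hw} too narrow: time axis reaches 0 "
                f"at pooling stage {stage + 1} (pool={config.pool})"
            )
        shapes.append((h, w))
    return shapes


def bottleneck_shape(
    input_hw: tuple[int, int], config: ModelConfig
) -> tuple[int, int, int]:
    """(reduced_height, reduced_width, feature_maps) of the latent space."""
    h, w = encoder_stage_shapes(input_hw, config)[-1]
    return h, w, config.encoder_filters[-1]


@dataclass
class ArchitectureDescriptor:
    """Serializable architecture manifest: ordered layer specs with shapes."""

    name: str
    input_shape: tuple
    output_shape: tuple
    layers: list[dict] = field(default_factory=list)

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2)

    @classmethod
    def from_json(cls, text: str) -> "ArchitectureDescriptor":
        d = json.loads(text)
        return cls(
            name=d["name"],
            input_shape=tuple(d["input_shape"]),
            output_shape=tuple(d["output_shape"]),
            layers=d["layers"],
        )


def build_encoder(
    config: ModelConfig, input_hw: tuple[int, int]
) -> ArchitectureDescriptor:
    """Descriptor of the 8-stage (conv/pool alternating) encoder."""
    shapes = encoder_stage_shapes(input_hw, config)
    h, w = input_hw
    layers = []
    in_ch = 1
    for stage, f in enumerate(config.encoder_filters):
        layers.append(
            dict(kind="conv2d", filters=f, kernel=config.kernel,
                 activation="relu", in_channels=in_ch,
                 skip_input_grad=(stage == 0),
                 output_shape=[h, w, f])
        )
        h, w = shapes[stage]
        ph = config.pool if layers[-1]["output_shape"][0] >= config.pool else 1
        layers.append(
            dict(kind="maxpool2d", pool=[ph, config.pool],
                 output_shape=[h, w, f])
        )
        in_ch = f
    return ArchitectureDescriptor(
        name="encoder",
        input_shape=(input_hw[0], input_hw[1], 1),
        output_shape=(h, w, config.encoder_filters[-1]),
        layers=layers,
    )


def build_decoder(
    config: ModelConfig, input_hw: tuple[int, int]
) -> ArchitectureDescriptor:
    """Descriptor of the mirrored decoder; output shape equals the input.

    Each upsampling stage is fitted (crop / edge-pad) to the matching
    encoder stage's pre-pooling shape, undoing floor losses, and the final
    activation is a sigmoid.
    """
    if not config.autoencoder:
        raise ConfigurationError(
            "decoder requested for a DCNN baseline (autoencoder=False)"
        )
    enc_shapes = encoder_stage_shapes(input_hw, config)
    # targets after each upsampling = encoder shapes in reverse, ending at input
    targets = [enc_shapes[2], enc_shapes[1], enc_shapes[0], input_hw]
    h, w = enc_shapes[-1]
    in_ch = config.encoder_filters[-1]
    layers = []
    for stage, f in enumerate(config.decoder_filters):
        layers.append(
            dict(kind="conv2d", filters=f, kernel=config.kernel,
                 activation="relu" if stage < 3 else "linear",
                 in_channels=in_ch, output_shape=[h, w, f])
        )
        th, tw = targets[stage]
        layers.append(
            dict(kind="upsample2d", factor=[config.pool, config.pool],
                 target=[th, tw], output_shape=[th, tw, f])
        )
        h, w = th, tw
        in_ch = f
    layers.append(dict(kind="sigmoid", output_shape=[h, w, 1]))
    return ArchitectureDescriptor(
        name="decoder",
        input_shape=(enc_shapes[-1][0], enc_shapes[-1][1],
                     config.encoder_filters[-1]),
        output_shape=(input_hw[0], input_hw[1], 1),
        layers=layers,
    )


def build_head(
    config: ModelConfig, bottleneck: tuple[int, int, int]
) -> ArchitectureDescriptor:
    """Descriptor of the classification head on a (h, w, c) bottleneck."""
    h, w, c = bottleneck
    layers = []
    if config.head == "mlp":
        feats = h * w * c
        layers.append(dict(kind="flatten", output_shape=[feats]))
        layers.append(dict(kind="dense", units=config.dense_units,
                           activation="relu", in_features=feats,
                           output_shape=[config.dense_units]))
        layers.append(dict(kind="dropout", rate=config.dropout_rate,
                           output_shape=[config.dense_units]))
        layers.append(dict(kind="dense", units=config.n_classes,
                           activation="softmax",
                           in_features=config.dense_units,
                           output_shape=[config.n_classes]))
    else:
        feats = h * c  # per-step features; sequence runs along reduced time
        rec_out = (2 if config.head == "bilstm" else 1) * config.bilstm_units
        layers.append(dict(kind="to_sequence", output_shape=[w, feats]))
        layers.append(dict(
            kind=config.head, units=config.bilstm_units, in_features=feats,
            output_shape=[w, rec_out]))
        if config.avg_pool_after_dense:
            # literal order: per-step dense, then temporal averaging
            layers.append(dict(kind="dense", units=config.dense_units,
                               activation="relu", in_features=rec_out,
                               output_shape=[w, config.dense_units]))
            layers.append(dict(kind="temporal_mean",
                               output_shape=[config.dense_units]))
        else:
            layers.append(dict(kind="temporal_mean", output_shape=[rec_out]))
            layers.append(dict(kind="dense", units=config.dense_units,
                               activation="relu", in_features=rec_out,
                               output_shape=[config.dense_units]))
        layers.append(dict(kind="dropout", rate=config.dropout_rate,
                           output_shape=[config.dense_units]))
        layers.append(dict(kind="dense", units=config.n_classes,
                           activation="softmax",
                           in_features=config.dense_units,
                           output_shape=[config.n_classes]))
    return ArchitectureDescriptor(
        name=f"head-{config.head}",
        input_shape=bottleneck,
        output_shape=(config.n_classes,),
        layers=layers,
    )


@dataclass
class ModelDescriptor:
    """Full model manifest: encoder (+ decoder) + head."""

    config: ModelConfig
    input_hw: tuple[int, int]
    encoder: ArchitectureDescriptor
    head: ArchitectureDescriptor
    decoder: ArchitectureDescriptor | None = None

    @property
    def n_outputs(self) -> int:
        return 2 if self.decoder is not None else 1

    def to_json(self) -> str:
        return json.dumps(
            dict(
                config=asdict(self.config),
                input_hw=list(self.input_hw),
                encoder=asdict(self.encoder),
                head=asdict(self.head),
                decoder=asdict(self.decoder) if self.decoder else None,
            ),
            indent=2,
        )


def build_model(
    config: ModelConfig, input_hw: tuple[int, int]
) -> ModelDescriptor:
    """Build the full architecture descriptor for an electrode-by-time plane.

    DCAE variants (``config.autoencoder``) expose two outputs — class
    probabilities and reconstruction; the DCNN baseline exposes one.
    """
    enc = build_encoder(config, input_hw)
    bott = bottleneck_shape(input_hw, config)
    head = build_head(config, bott)
    dec = build_decoder(config, input_hw) if config.autoencoder else None
    return ModelDescriptor(
        config=config, input_hw=input_hw, encoder=enc, head=head, decoder=dec
    )


# ---------------------------------------------------------------------------
# instantiation: descriptors -> numpy layers


def _make_layer(spec: dict, rng, dropout_rng, dtype):
    kind = spec["kind"]
    if kind == "conv2d":
        conv = nn.Conv2D(
            spec["in_channels"], spec["filters"], kernel=spec["kernel"],
            rng=rng, dtype=dtype,
            skip_input_grad=spec.get("skip_input_grad", False),
        )
        return [conv] + ([nn.ReLU()] if spec["activation"] == "relu" else [])
    if kind == "maxpool2d":
        ph, pw = spec["pool"]
        return [nn.MaxPool2D(ph, pw)]
    if kind == "upsample2d":
        fh, fw = spec["factor"]
        return [nn.Upsample2D(fh, fw, target_hw=tuple(spec["target"]))]
    if kind == "sigmoid":
        return [nn.Sigmoid()]
    if kind == "flatten":
        return [nn.Flatten()]
    if kind == "to_sequence":
        return [nn.ToSequence()]
    if kind == "temporal_mean":
        return [nn.TemporalMeanPool()]
    if kind == "dropout":
        return [nn.Dropout(spec["rate"], rng=dropout_rng)]
    if kind == "dense":
        layer = nn.Dense(spec["in_features"], spec["units"], rng=rng, dtype=dtype)
        return [layer] + ([nn.ReLU()] if spec["activation"] == "relu" else [])
    if kind == "lstm":
        return [nn.LSTM(spec["in_features"], spec["units"], rng=rng, dtype=dtype)]
    if kind == "bilstm":
        return [nn.Bidirectional(
            nn.LSTM(spec["in_features"], spec["units"], rng=rng, dtype=dtype),
            nn.LSTM(spec["in_features"], spec["units"], rng=rng, dtype=dtype),
        )]
    raise ConfigurationError(f"unknown layer kind {kind!r}")


def _make_sequential(desc: ArchitectureDescriptor, rng, dropout_rng, dtype):
    layers = []
    for spec in desc.layers:
        layers.extend(_make_layer(spec, rng, dropout_rng, dtype))
    return nn.Sequential(layers)


class JointModel:
    """Instantiated network: encoder (+ decoder) + head with shared trunk.

    ``forward`` returns ``(logits, reconstruction)`` (reconstruction is
    ``None`` for the DCNN baseline); ``backward`` merges the gradients of
    both objectives at the bottleneck.
    """

    def __init__(self, descriptor: ModelDescriptor):
        self.descriptor = descriptor
        cfg = descriptor.config
        dtype = np.dtype(cfg.dtype).type
        rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 0]))
        dropout_rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 1]))
        self.encoder = _make_sequential(descriptor.encoder, rng, dropout_rng, dtype)
        self.head = _make_sequential(descriptor.head, rng, dropout_rng, dtype)
        self.decoder = (
            _make_sequential(descriptor.decoder, rng, dropout_rng, dtype)
            if descriptor.decoder is not None
            else None
        )
        self.dtype = dtype

    @property
    def params(self):
        p = self.encoder.params + self.head.params
        if self.decoder is not None:
            p += self.decoder.params
        return p

    @property
    def grads(self):
        g = self.encoder.grads + self.head.grads
        if self.decoder is not None:
            g += self.decoder.grads
        return g

    def n_parameters(self) -> int:
        return int(sum(p.size for p in self.params))

    def forward(self, x, train=False):
        x = np.asarray(x, dtype=self.dtype)
        z = self.encoder.forward(x, train=train)
        logits = self.head.forward(z, train=train)
        recon = (
            self.decoder.forward(z, train=train)
            if self.decoder is not None
            else None
        )
        return logits, recon

    def backward(self, dlogits, drecon=None):
        dz = self.head.backward(dlogits.astype(self.dtype))
        if self.decoder is not None and drecon is not None:
            dz = dz + self.decoder.backward(drecon.astype(self.dtype))
        return self.encoder.backward(dz)

    def predict_proba(self, x, batch_size=128):
        """Class probabilities, evaluated without dropout."""
        x = np.asarray(x, dtype=self.dtype)
        out = []
        for i in range(0, len(x), batch_size):
            logits, _ = self.forward(x[i : i + batch_size], train=False)
            out.append(nn.softmax(logits))
        return np.concatenate(out) if out else np.empty((0, 2))

    def reconstruct(self, x, batch_size=128):
        if self.decoder is None:
            raise ConfigurationError("DCNN baseline has no decoder")
        x = np.asarray(x, dtype=self.dtype)
        out = []
        for i in range(0, len(x), batch_size):
            z = self.encoder.forward(x[i : i + batch_size], train=False)
            out.append(self.decoder.forward(z, train=False))
        return np.concatenate(out)

    def get_weights(self) -> list[np.ndarray]:
        return [p.copy() for p in self.params]

    def set_weights(self, weights) -> None:
        for p, w in zip(self.params, weights, strict=True):
            p[...] = w


def instantiate(descriptor: ModelDescriptor) -> JointModel:
    return JointModel(descriptor)
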