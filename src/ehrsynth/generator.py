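"""Latent-space generative model for mixed static + event-sequence records.

The model has two parts, trained in sequence:

1. an **encoder-decoder**: the encoder compresses each patient's static one-hot /
   min-max features, masked padded sequence tensor and validity mask into a
   fixed-length latent code; the decoder reconstructs the static block, every
   sequence position and an explicit sequence-length head. The reconstruction
   loss is cross-entropy on categorical groups (softmax per variable, per
   position), squared error on numeric channels, both masked by row validity,
   plus cross-entropy on the length head.
2. a **Wasserstein GAN with gradient penalty** on the (standardized) latent
   codes: the critic loss is E[f(fake)] - E[f(real)] + gp_weight * E[(||grad f at
   uniform interpolates|| - 1)^2]; the critic takes ``critic_steps_per_gen``
   updates per generator step.

Sampling draws standard-normal noise, maps it through the latent generator,
de-standardizes, and decodes: categorical groups by argmax (so every sampled
level is schema-valid), numeric channels clipped into [0, 1] before inverse
scaling, sequence length from the length head clipped to [1, max_seq_len], and
timestamps reconstructed as cumulative sums of non-negative decoded gaps.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np

from .dataset import ConsolidatedDataset, Schema
from .encoding import EncodedData, FeatureEncoder
from .nn import MLP, Adam, Critic, softmax

# squared error on [0,1]-scaled numerics is numerically much smaller than
# cross-entropy on categoricals; upweighting keeps the decoder from neglecting
# the numeric channels
NUMERIC_LOSS_WEIGHT = 5.0


@dataclass
class GenConfig:
    latent_dim: int = 32
    hidden_dim: int = 256
    ae_epochs: int = 250
    gan_epochs: int = 60
    batch_size: int = 128
    gp_weight: float = 10.0
    critic_steps_per_gen: int = 5
    lr_ae: float = 1e-3
    lr_gan: float = 5e-5
    lr_critic: float = 3e-3
    critic_hidden: int = 256
    critic_reset_every: int = 50
    critic_reset_burst: int = 80
    seed: int = 0
    max_seq_len: int | None = None

    def __post_init__(self) -> None:
        if self.latent_dim < 1 or self.hidden_dim < 1 or self.batch_size < 1:
            raise ValueError("latent_dim, hidden_dim, batch_size must be positive")
        if self.gp_weight <= 0:
            raise ValueError("gp_weight must be positive")
        if self.ae_epochs < 1 or self.gan_epochs < 1 or self.critic_steps_per_gen < 1:
            raise ValueError("epoch/step counts must be positive")


class Synthesizer:
    """Encoder-decoder + latent WGAN-GP; see module docstring."""

    def __init__(self, config: GenConfig):
        self.config = config
        self.encoder_net: MLP | None = None
        self.decoder_net: MLP | None = None
        self.gen_net: MLP | None = None
        self.feature_encoder: FeatureEncoder | None = None
        self.latent_mu: np.ndarray | None = None
        self.whiten: np.ndarray | None = None
        self.unwhiten: np.ndarray | None = None
        self.ae_loss_history: list[float] = []
        self.critic_loss_history: list[float] = []

    # ---- layout ------------------------------------------------------------
    def _encoder_input(self, enc: EncodedData) -> np.ndarray:
        n = len(enc.static)
        seq = (enc.seq * enc.mask[:, :, None]).reshape(n, -1)
        return np.concatenate([enc.static, seq, enc.mask], axis=1)

    def _out_dim(self) -> int:
        fe = self.feature_encoder
        L = fe.max_seq_len
        return fe.static_dim + L * fe.dyn_dim + (L + 1)

    def _decoder_slices(self):
        """Yield (kind, out_slice, target) descriptors for loss assembly."""
        fe = self.feature_encoder
        L = fe.max_seq_len
        yield "static", slice(0, fe.static_dim), None
        base = fe.static_dim
        yield "seq", slice(base, base + L * fe.dyn_dim), None
        base += L * fe.dyn_dim
        yield "length", slice(base, base + L + 1), None

    # ---- reconstruction loss -----------------------------------------------
    def _loss_and_grad(self, y: np.ndarray, enc: EncodedData):
        fe = self.feature_encoder
        n, L = len(enc.static), fe.max_seq_len
        dy = np.zeros_like(y)
        loss = 0.0
        w_rows = float(enc.mask.sum()) or 1.0

        # static block
        for spec, sl in fe.static_slices:
            block = y[:, sl]
            target = enc.static[:, sl]
            if spec.kind == "categorical":
                p = softmax(block)
                loss += -np.sum(target * np.log(p + 1e-12)) / n
                dy[:, sl] = (p - target) / n
            else:
                diff = block - target
                loss += NUMERIC_LOSS_WEIGHT * float((diff * diff).sum()) / n
                dy[:, sl] = 2.0 * NUMERIC_LOSS_WEIGHT * diff / n

        # sequence block, masked by row validity
        base = fe.static_dim
        seq_out = y[:, base : base + L * fe.dyn_dim].reshape(n, L, fe.dyn_dim)
        dseq = np.zeros_like(seq_out)
        m = enc.mask[:, :, None]
        for spec, sl in fe.dyn_slices:
            block = seq_out[:, :, sl]
            target = enc.seq[:, :, sl]
            if spec.kind == "categorical":
                p = softmax(block, axis=2)
                loss += -np.sum(m * target * np.log(p + 1e-12)) / w_rows
                dseq[:, :, sl] = m * (p - target) / w_rows
            else:
                diff = (block - target) * m
                loss += NUMERIC_LOSS_WEIGHT * float((diff * diff).sum()) / w_rows
                dseq[:, :, sl] = 2.0 * NUMERIC_LOSS_WEIGHT * diff / w_rows
        dy[:, base : base + L * fe.dyn_dim] = dseq.reshape(n, -1)

        # length head
        sl = slice(base + L * fe.dyn_dim, base + L * fe.dyn_dim + L + 1)
        p = softmax(y[:, sl])
        onehot = np.zeros((n, L + 1))
        onehot[np.arange(n), np.clip(enc.lengths, 0, L)] = 1.0
        loss += -np.sum(onehot * np.log(p + 1e-12)) / n
        dy[:, sl] = (p - onehot) / n
        return loss, dy

    # ---- training ----------------------------------------------------------
    def fit_autoencoder(self, train: ConsolidatedDataset) -> None:
        cfg = self.config
        self.schema: Schema = train.schema
        self.feature_encoder = FeatureEncoder(train.schema, max_seq_len=cfg.max_seq_len)
        enc = self.feature_encoder.encode(train)
        x = self._encoder_input(enc)
        rng = np.random.default_rng(cfg.seed)
        d_in, d_out = x.shape[1], self._out_dim()
        self.encoder_net = MLP(
            [d_in, cfg.hidden_dim, cfg.hidden_dim, cfg.latent_dim],
            ["relu", "tanh", "linear"],
            rng,
        )
        self.decoder_net = MLP(
            [cfg.latent_dim, cfg.hidden_dim, cfg.hidden_dim, d_out],
            ["tanh", "relu", "linear"],
            rng,
        )
        params = self.encoder_net.params + self.decoder_net.params
        opt = Adam(params, lr=cfg.lr_ae, beta1=0.9, beta2=0.999)
        n = len(x)
        self.ae_loss_history = []
        for _epoch in range(cfg.ae_epochs):
            order = rng.permutation(n)
            epoch_loss = 0.0
            for start in range(0, n, cfg.batch_size):
                idx = order[start : start + cfg.batch_size]
                batch = EncodedData(
                    enc.static[idx], enc.seq[idx], enc.mask[idx], enc.lengths[idx], enc.patient_ids[idx]
                )
                cache_e, cache_d = [], []
                z = self.encoder_net.forward(x[idx], cache_e)
                y = self.decoder_net.forward(z, cache_d)
                loss, dy = self._loss_and_grad(y, batch)
                if not np.isfinite(loss):
                    raise RuntimeError("non-finite autoencoder loss; reduce lr_ae")
                g_dec, dz = self.decoder_net.backward(dy, cache_d)
                g_enc, _ = self.encoder_net.backward(dz, cache_e)
                opt.step(g_enc + g_dec)
                epoch_loss += loss * len(idx)
            self.ae_loss_history.append(epoch_loss / n)
        # latent whitening for GAN training: with zero-mean, identity-covariance
        # codes the identity-initialized generator starts at the first-two-moment
        # equilibrium and adversarial training only has to refine higher structure
        codes = self.encoder_net.forward(x)
        self.latent_mu = codes.mean(axis=0)
        centred = codes - self.latent_mu
        cov = centred.T @ centred / max(len(codes) - 1, 1)
        evals, evecs = np.linalg.eigh(cov)
        evals = np.maximum(evals, 1e-8)
        self.whiten = evecs @ np.diag(evals**-0.5) @ evecs.T  # ZCA
        self.unwhiten = evecs @ np.diag(evals**0.5) @ evecs.T
        self._train_codes_white = centred @ self.whiten

    def fit_latent_gan(self, codes: np.ndarray | None = None) -> None:
        """Adversarially fit the latent distribution of ``codes`` (whitened
        training codes by default).

        The generator is an identity-plus-residual map on whitened codes; the
        critic keeps a frozen random hidden layer and a trained head, and the
        head is re-initialized on a fixed schedule with a burst of critic
        updates. Both choices address basin-trapping of the gradient-penalty
        term with a shallow critic (see module docstring / methods note).
        """
        cfg = self.config
        if codes is None:
            if not hasattr(self, "_train_codes_white"):
                raise RuntimeError("fit_autoencoder must run first")
            codes = self._train_codes_white
        n = len(codes)
        bs = min(cfg.batch_size, max(n // 2, 1))
        if bs < 4:
            raise ValueError("need at least 2 batches (>= 8 latent codes) for adversarial training")
        rng = np.random.default_rng(cfg.seed + 1)
        d = codes.shape[1]
        self.gen_net = MLP(
            [d, cfg.hidden_dim, cfg.hidden_dim, d], ["relu", "relu", "linear"], rng
        )
        for w in self.gen_net.weights:  # small-init residual branch
            w *= 0.02
        nh = cfg.critic_hidden
        critic = Critic(d, nh, rng)
        critic.W1 = rng.normal(0.0, 1.0, (nh, d)) * rng.uniform(0.2, 2.0, (nh, 1))
        critic.b1 = rng.uniform(-2.0, 2.0, nh)
        opt_g = Adam(self.gen_net.params, lr=cfg.lr_gan, beta1=0.5, beta2=0.9)
        opt_c = Adam([critic.w2], lr=cfg.lr_critic, beta1=0.0, beta2=0.9)
        self.critic_loss_history = []
        steps_per_epoch = max(n // bs, 1)

        def fake_batch(cache=None):
            z = rng.standard_normal((bs, d))
            return z + self.gen_net.forward(z, cache)

        def critic_updates(k: int) -> float:
            total = 0.0
            for _ in range(k):
                real = codes[rng.integers(0, n, bs)]
                fake = fake_batch()
                eps = rng.random((bs, 1))
                gp, g_pen = critic.penalty_grads(eps * real + (1.0 - eps) * fake)
                closs = float(critic.value(fake).mean() - critic.value(real).mean())
                if not np.isfinite(closs + gp):
                    raise RuntimeError("non-finite critic loss; reduce learning rates")
                g_fake = critic.mean_value_grads(fake, +1.0)
                g_real = critic.mean_value_grads(real, -1.0)
                opt_c.step([g_fake[2] + g_real[2] + cfg.gp_weight * g_pen[2]])
                total += closs + cfg.gp_weight * gp
            return total

        gen_step = 0
        for _epoch in range(cfg.gan_epochs):
            epoch_closs = 0.0
            for _step in range(steps_per_epoch):
                if gen_step % cfg.critic_reset_every == 0:
                    critic.w2 = rng.normal(0.0, 1.0 / np.sqrt(nh), nh)
                    opt_c = Adam([critic.w2], lr=cfg.lr_critic, beta1=0.0, beta2=0.9)
                    critic_updates(cfg.critic_reset_burst)
                epoch_closs += critic_updates(cfg.critic_steps_per_gen)
                cache: list = []
                fake = fake_batch(cache)
                dfake = -critic.input_grad(fake) / bs
                g_gen, _ = self.gen_net.backward(dfake, cache)
                opt_g.step(g_gen)
                gen_step += 1
            self.critic_loss_history.append(
                epoch_closs / (steps_per_epoch * cfg.critic_steps_per_gen)
            )
        self._critic = critic

    def fit(self, train: ConsolidatedDataset) -> "Synthesizer":
        self.fit_autoencoder(train)
        self.fit_latent_gan()
        return self

    # ---- inference ---------------------------------------------------------
    def latent_codes(self, dataset: ConsolidatedDataset) -> np.ndarray:
        if self.encoder_net is None:
            raise RuntimeError("model not trained")
        enc = self.feature_encoder.encode(dataset)
        return self.encoder_net.forward(self._encoder_input(enc))

    def _decode_outputs(self, y: np.ndarray) -> ConsolidatedDataset:
        fe = self.feature_encoder
        n, L = len(y), fe.max_seq_len
        static = y[:, : fe.static_dim]
        seq = y[:, fe.static_dim : fe.static_dim + L * fe.dyn_dim].reshape(n, L, fe.dyn_dim)
        len_logits = y[:, fe.static_dim + L * fe.dyn_dim :]
        lengths = np.clip(len_logits.argmax(axis=1), 1, L) if n else np.zeros(0, dtype=int)
        return fe.decode(static, seq, lengths)

    def sample(self, n: int, seed: int = 0) -> ConsolidatedDataset:
        """Generate ``n`` schema-valid synthetic patients (deterministic per seed)."""
        if self.gen_net is None or self.decoder_net is None:
            raise RuntimeError("sample() called before training")
        if n < 0:
            raise ValueError("n must be >= 0")
        fe = self.feature_encoder
        if n == 0:
            return self._decode_outputs(np.zeros((0, self._out_dim())))
        rng = np.random.default_rng(seed)
        z = rng.standard_normal((n, self.config.latent_dim))
        white = z + self.gen_net.forward(z)
        codes = white @ self.unwhiten + self.latent_mu
        y = self.decoder_net.forward(codes)
        return self._decode_outputs(y)

    def reconstruct(self, dataset: ConsolidatedDataset) -> ConsolidatedDataset:
        """Autoencode a dataset (diagnostic: how much the bottleneck loses)."""
        enc = self.feature_encoder.encode(dataset)
        z = self.encoder_net.forward(self._encoder_input(enc))
        return self._decode_outputs(self.decoder_net.forward(z))

    # ---- persistence -------------------------------------------------------
    def save(self, path: str | Path) -> None:
        path = Path(path)
        arrays = {}
        for name, net in (
            ("enc", self.encoder_net),
            ("dec", self.decoder_net),
            ("gen", self.gen_net),
        ):
            for i, (w, b) in enumerate(zip(net.weights, net.biases)):
                arrays[f"{name}_w{i}"] = w
                arrays[f"{name}_b{i}"] = b
        arrays["latent_mu"] = self.latent_mu
        arrays["whiten"] = self.whiten
        arrays["unwhiten"] = self.unwhiten
        np.savez(path.with_suffix(".npz"), **arrays)
        sidecar = {
            "config": asdict(self.config),
            "schema": json.loads(self.schema.to_json()),
            "max_seq_len": self.feature_encoder.max_seq_len,
        }
        path.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))

    @classmethod
    def load(cls, path: str | Path) -> "Synthesizer":
        path = Path(path)
        sidecar = json.loads(path.with_suffix(".json").read_text())
        cfg = GenConfig(**sidecar["config"])
        model = cls(cfg)
        model.schema = Schema.from_json(json.dumps(sidecar["schema"]))
        model.feature_encoder = FeatureEncoder(model.schema, sidecar["max_seq_len"])
        data = np.load(path.with_suffix(".npz"))
        rng = np.random.default_rng(0)

        def rebuild(name: str, acts: list[str]) -> MLP:
            ws = [data[f"{name}_w{i}"] for i in range(len(acts))]
            net = MLP([w.shape[0] for w in ws] + [ws[-1].shape[1]], acts, rng)
            net.weights = ws
            net.biases = [data[f"{name}_b{i}"] for i in range(len(acts))]
            return net

        model.encoder_net = rebuild("enc", ["relu", "tanh", "linear"])
        model.decoder_net = rebuild("dec", ["tanh", "relu", "linear"])
        model.gen_net = rebuild("gen", ["relu", "relu", "linear"])
        model.latent_mu = data["latent_mu"]
        model.whiten = data["whiten"]
        model.unwhiten = data["unwhiten"]
        return model
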