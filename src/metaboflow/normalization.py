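"""Batch-effect removal anchored on pooled-reference QC injections.

Three normalizers are provided:

* **TIC scaling** — each injection divided by its total ion count;
* **median scaling** — each injection divided by its feature-intensity median;
* **adversarial autoencoder** (NormAE-style) — a nonlinear autoencoder whose
  latent space is adversarially stripped of batch structure.  Two
  discriminators are trained against the encoder: a classifier predicting the
  acquisition batch and a regressor predicting within-batch injection order
  from the latent codes; the encoder is simultaneously pushed to make both
  uninformative (bounded confusion objectives), so latent codes that still
  carry inter-batch offsets or injection-order drift are penalized.  The
  decoder is conditioned on the batch one-hot and injection order, letting it
  model the technical structure explicitly instead of hiding it in the
  latent; decoding every injection at a batch-neutral reference (uniform
  batch weights, mid-batch order) yields the corrected table.  The identical
  pooled reference plasma injected in every batch (QC_NIST) anchors the
  method: its replicate coefficient of variation is the early-stopping
  criterion, since any residual spread across those injections is purely
  technical.

The scaler operates on log2 intensities (per-feature centre/scale); corrected
tables are mapped back to the intensity scale.  All injection types are
transformed identically.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import FeatureTable
from .nn import MLP, Adam, clip_grads, confusion_loss, cross_entropy

__all__ = [
    "NormAEConfig",
    "NormalizationModel",
    "NormalizationAssessment",
    "normalize_tic",
    "normalize_median",
    "fit_normae",
    "apply_normalization",
    "assess",
    "save_model",
    "load_model",
]

CHECKPOINT_VERSION = 1


def _column_scale(table: FeatureTable, stat) -> FeatureTable:
    M = table.matrix
    if M.isna().any().any():
        raise ValueError("normalization requires an imputed (complete) table")
    col = stat(M)
    if (col <= 0).any():
        bad = col.index[col <= 0].tolist()[:5]
        raise ValueError(f"non-positive column statistic for injections {bad}")
    out = table.copy()
    out.matrix = M.div(col, axis=1) * float(col.mean())
    return out


def normalize_tic(table: FeatureTable) -> FeatureTable:
    """Scale each injection to a common total ion count (the grand mean)."""
    return _column_scale(table, lambda M: M.sum(axis=0))


def normalize_median(table: FeatureTable) -> FeatureTable:
    """Scale each injection to a common feature-intensity median."""
    return _column_scale(table, lambda M: M.median(axis=0))


@dataclass
class NormAEConfig:
    """Architecture and training settings for the adversarial autoencoder."""

    latent_dim: int = 8
    hidden: tuple[int, int] = (64, 32)
    disc_hidden: int = 64
    epochs: int = 1000
    lr: float = 3e-3
    disc_lr: float = 3e-3
    lambda_batch: float = 5.0   # adversarial weight on the batch classifier
    lambda_order: float = 1.0   # adversarial weight on the order regressor
    latent_l2: float = 1e-3     # keeps latent codes bounded
    grad_clip: float = 5.0      # global gradient-norm clip
    disc_steps: int = 2         # discriminator updates per autoencoder update
    warmup_epochs: int = 200    # reconstruction-only epochs before adversary
    eval_every: int = 10        # epochs between QC-CV early-stopping checks
    patience: int = 15          # evaluations without improvement before stop


@dataclass
class NormalizationModel:
    encoder: MLP
    decoder: MLP             # conditional: input = [latent, batch one-hot, order]
    batch_disc: MLP
    order_disc: MLP
    center: np.ndarray       # per-feature mean of log2 intensities
    scale: np.ndarray        # per-feature sd of log2 intensities
    n_batches: int
    feature_index: pd.Index
    config: NormAEConfig
    seed: int
    history: pd.DataFrame = field(default_factory=pd.DataFrame)

    def encode(self, X: np.ndarray) -> np.ndarray:
        return self.encoder.forward(X)

    def decode(self, Z: np.ndarray, batch_onehot: np.ndarray,
               order: np.ndarray) -> np.ndarray:
        return self.decoder.forward(np.hstack([Z, batch_onehot, order]))

    def reconstruct(self, X: np.ndarray) -> np.ndarray:
        """Decode at the batch-neutral reference (uniform batch weights,
        mid-batch injection order) — the corrected output."""
        Z = self.encoder.forward(X)
        ref_b = np.full((len(Z), self.n_batches), 1.0 / self.n_batches)
        ref_o = np.zeros((len(Z), 1))
        return self.decode(Z, ref_b, ref_o)


@dataclass
class NormalizationAssessment:
    cv_before: pd.Series
    cv_after: pd.Series
    pca_before: pd.DataFrame
    pca_after: pd.DataFrame
    qc_dispersion_ratio: float


def _log2_matrix(table: FeatureTable) -> np.ndarray:
    """Injections × features log2 matrix; intensities floored at 1 so that
    zero-imputed cells stay finite."""
    M = table.matrix.to_numpy(dtype=float).T
    if np.isnan(M).any():
        raise ValueError("table has missing cells; impute first")
    return np.log2(np.maximum(M, 1.0))


def qc_nist_cv(table: FeatureTable) -> pd.Series:
    """Per-feature CV (%) across the pooled-reference QC_NIST injections."""
    cols = table.columns_of_type("QC_NIST")
    if len(cols) < 3:
        raise ValueError("need at least 3 QC_NIST injections")
    sub = table.matrix[cols]
    return (sub.std(axis=1, ddof=1) / sub.mean(axis=1) * 100.0)


def fit_normae(
    table: FeatureTable,
    batch_labels: pd.Series | None = None,
    injection_order: pd.Series | None = None,
    config: NormAEConfig | None = None,
    seed: int = 0,
) -> NormalizationModel:
    """Train the adversarial autoencoder on an imputed feature table.

    Training rows are the biological, QC_bio, and QC_NIST injections (blanks
    and standards mixtures carry no metabolome).  Alternates discriminator
    updates (batch classifier + within-batch order regressor on the latent
    codes) with autoencoder updates on reconstruction plus λ-weighted
    confusion terms; deterministic given ``seed``.  Early stopping halts when
    the median QC_NIST CV of the corrected output stops improving, keeping
    the final parameters.
    """
    cfg = config or NormAEConfig()
    meta = table.sample_meta
    if batch_labels is None:
        batch_labels = meta["batch"]
    if injection_order is None:
        injection_order = meta.groupby("batch").cumcount() \
            if "injection_index" not in meta else meta["injection_index"]
    if batch_labels.nunique() < 2:
        raise ValueError("need at least 2 batches to correct batch effects")

    train_cols = table.columns_of_type("bio", "QC_bio", "QC_NIST")
    col_pos = table.matrix.columns.get_indexer(train_cols)
    X_all = _log2_matrix(table)
    # centre/scale on the metabolome-carrying rows only: solvent blanks and
    # standards mixtures sit far below the biology and would crush its
    # variance into a corner of the standardized space
    center = X_all[col_pos].mean(axis=0)
    scale = X_all[col_pos].std(axis=0)
    scale[scale < 1e-8] = 1.0
    X = (X_all[col_pos] - center) / scale

    codes, uniq = pd.factorize(batch_labels.loc[train_cols])
    n_batches = len(uniq)
    # within-batch order normalized to [-1, 1] per batch
    ord_raw = injection_order.loc[train_cols].to_numpy(dtype=float)
    order = np.empty_like(ord_raw)
    for b in range(n_batches):
        m = codes == b
        o = ord_raw[m]
        span = o.max() - o.min()
        order[m] = 0.0 if span == 0 else (o - o.min()) / span * 2.0 - 1.0
    order = order[:, None]

    d = X.shape[1]
    rng = np.random.default_rng(np.random.SeedSequence((seed, 97)))
    enc = MLP([d, *cfg.hidden, cfg.latent_dim], rng)
    # the decoder is conditioned on batch one-hot + injection order, so
    # technical structure is modelled explicitly instead of hiding in z
    dec = MLP([cfg.latent_dim + n_batches + 1, *cfg.hidden[::-1], d], rng)
    bdisc = MLP([cfg.latent_dim, cfg.disc_hidden, n_batches], rng)
    odisc = MLP([cfg.latent_dim, cfg.disc_hidden, 1], rng)
    B1h = np.zeros((len(X), n_batches))
    B1h[np.arange(len(X)), codes] = 1.0
    ref_b = np.full((len(X), n_batches), 1.0 / n_batches)
    ref_o = np.zeros((len(X), 1))
    opt_ae = Adam(enc.params + dec.params, lr=cfg.lr)
    opt_d = Adam(bdisc.params + odisc.params, lr=cfg.disc_lr)

    nist_mask = (meta.loc[train_cols, "sample_type"] == "QC_NIST").to_numpy()
    n = len(X)
    hist = []
    best_cv = np.inf
    stale = 0

    def recon_cv(model_out: np.ndarray) -> float:
        rec = np.exp2(model_out[nist_mask] * scale + center)
        sd = rec.std(axis=0, ddof=1)
        mean = rec.mean(axis=0)
        return float(np.median(sd / mean * 100.0))

    for epoch in range(cfg.epochs):
        adversarial = epoch >= cfg.warmup_epochs
        Z = enc.forward(X)
        if adversarial:
            for _ in range(cfg.disc_steps):
                logits = bdisc.forward(Z, train=True)
                ce, dlogits = cross_entropy(logits, codes)
                _, g_b = bdisc.backward(dlogits)
                pred = odisc.forward(Z, train=True)
                dmse = 2.0 * (pred - order) / n
                _, g_o = odisc.backward(dmse)
                opt_d.step(clip_grads(g_b + g_o, cfg.grad_clip))

        # autoencoder phase: reconstruction plus bounded adversarial terms —
        # the encoder is pushed to make the batch classifier uniform and the
        # order regressor uninformative, not to maximize their losses
        Z = enc.forward(X, train=True)
        Xhat = dec.forward(np.hstack([Z, B1h, order]), train=True)
        resid = Xhat - X
        recon = float((resid**2).mean())
        # per-sample normalization (sum over features) keeps the
        # reconstruction and adversarial gradients on the same scale
        dXhat = 2.0 * resid / n
        dDecIn, g_dec = dec.backward(dXhat)
        dZ = dDecIn[:, :cfg.latent_dim] + cfg.latent_l2 * 2.0 * Z / n
        conf_val = conf_ord = 0.0
        if adversarial:
            logits = bdisc.forward(Z, train=True)
            conf_val, dlogits = confusion_loss(logits)
            dZ_b, _ = bdisc.backward(dlogits)
            pred = odisc.forward(Z, train=True)
            conf_ord = float((pred**2).mean())
            dZ_o, _ = odisc.backward(2.0 * pred / n)
            dZ = dZ + cfg.lambda_batch * dZ_b + cfg.lambda_order * dZ_o
        _, g_enc = enc.backward(dZ)
        opt_ae.step(clip_grads(g_enc + g_dec, cfg.grad_clip))

        loss = recon + cfg.lambda_batch * conf_val + cfg.lambda_order * conf_ord
        if not np.isfinite(loss):
            raise RuntimeError(
                f"non-finite loss at epoch {epoch}: recon={recon}, "
                f"confusion={conf_val}, order={conf_ord}")
        hist.append({"epoch": epoch, "recon": recon, "batch_confusion": conf_val,
                     "order_confusion": conf_ord, "loss": loss})

        if adversarial and (epoch + 1) % cfg.eval_every == 0:
            cv = recon_cv(dec.forward(
                np.hstack([enc.forward(X), ref_b, ref_o])))
            hist[-1]["qc_nist_cv"] = cv
            if cv < best_cv - 1e-3:
                best_cv = cv
                stale = 0
            else:
                stale += 1
                if stale >= cfg.patience:
                    break

    return NormalizationModel(
        encoder=enc, decoder=dec, batch_disc=bdisc, order_disc=odisc,
        center=center, scale=scale, n_batches=n_batches,
        feature_index=table.matrix.index,
        config=cfg, seed=seed, history=pd.DataFrame(hist),
    )


def apply_normalization(model: NormalizationModel, table: FeatureTable) -> FeatureTable:
    """Reconstruct a table through the trained autoencoder.

    Every injection (biological and QC alike) is encoded and decoded with the
    same fitted parameters, then mapped back to the intensity scale.
    """
    if not table.matrix.index.equals(model.feature_index):
        raise ValueError("feature set differs from the fitted model")
    Xs = (_log2_matrix(table) - model.center) / model.scale
    Xhat = model.reconstruct(Xs)
    # clamp decoded log2 intensities to a physical range before exponentiating
    log2_out = np.clip(Xhat * model.scale + model.center, 0.0, 40.0)
    out = table.copy()
    out.matrix = pd.DataFrame(
        np.exp2(log2_out).T,
        index=table.matrix.index, columns=table.matrix.columns,
    )
    return out


def batch_classification_accuracy(
    model: NormalizationModel, table: FeatureTable
) -> float:
    """How well the trained discriminator still predicts batch from latent
    codes (chance level ≈ 1/n_batches once batch structure is stripped)."""
    meta = table.sample_meta
    cols = table.columns_of_type("bio", "QC_bio", "QC_NIST")
    pos = table.matrix.columns.get_indexer(cols)
    Xs = (_log2_matrix(table) - model.center) / model.scale
    Z = model.encode(Xs[pos])
    codes, _ = pd.factorize(meta.loc[cols, "batch"])
    pred = model.batch_disc.forward(Z).argmax(axis=1)
    return float((pred == codes).mean())


def assess(
    table_before: FeatureTable,
    table_after: FeatureTable,
    n_components: int = 2,
) -> NormalizationAssessment:
    """Evaluate a correction by pooled-reference tightness.

    Computes per-feature QC_NIST CVs before/after, a PCA of the
    unit-variance-scaled log2 matrices (biological + QC_NIST injections),
    and the ratio of mean pairwise QC_NIST distance in the leading
    components after vs before.
    """
    from sklearn.decomposition import PCA

    cols = table_before.columns_of_type("bio", "QC_NIST")
    nist = table_before.sample_meta.loc[cols, "sample_type"] == "QC_NIST"
    if int(nist.sum()) < 3:
        raise ValueError("need at least 3 QC_NIST injections to assess")

    def project(table: FeatureTable) -> pd.DataFrame:
        pos = table.matrix.columns.get_indexer(cols)
        X = _log2_matrix(table)[pos]
        sd = X.std(axis=0)
        sd[sd < 1e-12] = 1.0
        Xs = (X - X.mean(axis=0)) / sd
        pcs = PCA(n_components=n_components, random_state=0).fit_transform(Xs)
        return pd.DataFrame(pcs, index=cols,
                            columns=[f"PC{i + 1}" for i in range(n_components)])

    def dispersion(pcs: pd.DataFrame) -> float:
        P = pcs[nist.to_numpy()].to_numpy()
        diffs = P[:, None, :] - P[None, :, :]
        dist = np.sqrt((diffs**2).sum(-1))
        iu = np.triu_indices(len(P), 1)
        return float(dist[iu].mean())

    pca_b, pca_a = project(table_before), project(table_after)
    ratio = dispersion(pca_a) / dispersion(pca_b)
    return NormalizationAssessment(
        cv_before=qc_nist_cv(table_before),
        cv_after=qc_nist_cv(table_after),
        pca_before=pca_b,
        pca_after=pca_a,
        qc_dispersion_ratio=ratio,
    )


def save_model(model: NormalizationModel, path) -> None:
    """Write a fitted model to a single checkpoint file (npz container with
    a versioned JSON header)."""
    import dataclasses
    import json

    arrays: dict[str, np.ndarray] = {
        "center": model.center, "scale": model.scale}
    for name, mlp in (("enc", model.encoder), ("dec", model.decoder),
                      ("bdisc", model.batch_disc), ("odisc", model.order_disc)):
        for i, (W, b) in enumerate(zip(mlp.W, mlp.b)):
            arrays[f"{name}_W{i}"] = W
            arrays[f"{name}_b{i}"] = b
    header = {
        "format": "metaboflow-normalization-model",
        "version": CHECKPOINT_VERSION,
        "n_batches": model.n_batches,
        "seed": model.seed,
        "config": dataclasses.asdict(model.config),
        "features": [str(f) for f in model.feature_index],
    }
    arrays["header"] = np.frombuffer(
        json.dumps(header).encode("utf-8"), dtype=np.uint8)
    np.savez_compressed(path, **arrays)


def load_model(path) -> NormalizationModel:
    """Inverse of :func:`save_model`."""
    import json

    with np.load(path) as data:
        header = json.loads(bytes(data["header"].tobytes()).decode("utf-8"))
        if header.get("format") != "metaboflow-normalization-model":
            raise ValueError("not a normalization model checkpoint")
        if header["version"] != CHECKPOINT_VERSION:
            raise ValueError(
                f"unsupported checkpoint version {header['version']}")

        def unpack(name: str) -> MLP:
            mlp = MLP.__new__(MLP)
            mlp.W, mlp.b, mlp._cache = [], [], None
            i = 0
            while f"{name}_W{i}" in data.files:
                mlp.W.append(np.array(data[f"{name}_W{i}"]))
                mlp.b.append(np.array(data[f"{name}_b{i}"]))
                i += 1
            return mlp

        cfg_d = dict(header["config"])
        cfg_d["hidden"] = tuple(cfg_d["hidden"])
        return NormalizationModel(
            encoder=unpack("enc"), decoder=unpack("dec"),
            batch_disc=unpack("bdisc"), order_disc=unpack("odisc"),
            center=np.array(data["center"]), scale=np.array(data["scale"]),
            n_batches=int(header["n_batches"]),
            feature_index=pd.Index(header["features"], name="feature_id"),
            config=NormAEConfig(**cfg_d), seed=int(header["seed"]),
        )
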